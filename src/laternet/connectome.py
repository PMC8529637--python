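"""Labelled, weighted, undirected brain connectomes.

A connectome here is a square nonnegative weight matrix (e.g. streamline
counts between atlas regions) together with an atlas that assigns every
node a label, a hemisphere (``L`` or ``R``) and a homologous-pair id that
links each left-hemisphere region to its right-hemisphere counterpart.
The pair structure is what makes hemisphere extraction and mirroring —
the building blocks of laterality analysis — well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")
SCOPE_WHOLE = "whole"
SCOPES = ("L", "R", SCOPE_WHOLE)

#: tolerance under which an asymmetric input matrix is silently symmetrized
SYMMETRY_ATOL = 1e-8


@dataclass(frozen=True)
class AtlasNode:
    """One atlas region: label, hemisphere and homologous-pair membership."""

    node_id: int
    label: str
    hemisphere: str
    pair_id: int


def _validate_atlas(nodes: list[AtlasNode], require_paired: bool = True) -> None:
    """Check atlas invariants.

    ``require_paired`` demands every pair_id map to exactly one L and one
    R node (a full bihemispheric atlas); hemisphere-extracted subgraphs
    relax this to one node per (pair_id, hemisphere).
    """
    labels = [n.label for n in nodes]
    if len(set(labels)) != len(labels):
        raise ValueError("atlas labels must be unique")
    for n in nodes:
        if n.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere code {n.hemisphere!r} for node {n.label!r}"
            )
    by_pair: dict[int, list[str]] = {}
    for n in nodes:
        by_pair.setdefault(n.pair_id, []).append(n.hemisphere)
    if require_paired:
        if len(nodes) % 2 != 0:
            raise ValueError("node count must be even (left/right pairing)")
        for pid, hemis in by_pair.items():
            if sorted(hemis) != ["L", "R"]:
                raise ValueError(
                    f"pair_id {pid} must map to exactly one L and one R node, "
                    f"got hemispheres {hemis}"
                )
    else:
        for pid, hemis in by_pair.items():
            if len(hemis) != len(set(hemis)):
                raise ValueError(f"pair_id {pid} duplicated within a hemisphere")


class Connectome:
    """A validated weighted undirected graph on an annotated atlas.

    Parameters
    ----------
    nodes
        Ordered atlas nodes; ``node_id`` is re-assigned to positional order.
    weights
        Square matrix of nonnegative finite weights.  Matrices that are
        asymmetric by at most ``atol`` (numerical noise from upstream
        tooling) are symmetrized as ``(A + A.T) / 2``; larger asymmetry is
        rejected.  The diagonal must be zero up to ``atol``.
    """

    __slots__ = ("nodes", "weights")

    def __init__(self, nodes: list[AtlasNode], weights, *, atol: float = SYMMETRY_ATOL,
                 require_paired: bool = True):
        weights = np.array(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {weights.shape}")
        if len(nodes) != weights.shape[0]:
            raise ValueError(
                f"dimension mismatch: {len(nodes)} atlas nodes vs "
                f"{weights.shape[0]}x{weights.shape[1]} matrix"
            )
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        asym = np.max(np.abs(weights - weights.T)) if weights.size else 0.0
        if asym > atol:
            raise ValueError(
                f"matrix asymmetric beyond tolerance (max |A - A.T| = {asym:g})"
            )
        weights = (weights + weights.T) / 2.0
        diag = np.abs(np.diag(weights))
        if diag.size and diag.max() > atol:
            raise ValueError("diagonal must be zero (no self-connections)")
        np.fill_diagonal(weights, 0.0)
        if np.any(weights < 0):
            raise ValueError("negative weight")
        nodes = [
            AtlasNode(i, n.label, n.hemisphere, n.pair_id) for i, n in enumerate(nodes)
        ]
        _validate_atlas(nodes, require_paired=require_paired)
        self.nodes = nodes
        self.weights = weights

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def hemisphere_index(self, side: str) -> np.ndarray:
        """Positional indices of the nodes on ``side`` (original order)."""
        if side not in HEMISPHERES:
            raise ValueError(f"side must be one of {HEMISPHERES}, got {side!r}")
        return np.array([n.node_id for n in self.nodes if n.hemisphere == side])

    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(np.triu(self.weights, 1).sum())

    # -- structural operations -------------------------------------------

    def extract_hemisphere(self, side: str) -> "Connectome":
        """Induced subgraph on one hemisphere.

        All inter-hemispheric edges are discarded; node order and pair ids
        are preserved so homologous regions can still be matched across the
        two extracted halves.
        """
        if side == SCOPE_WHOLE:
            raise ValueError("side must be 'L' or 'R'; the whole graph is the connectome itself")
        idx = self.hemisphere_index(side)
        sub_nodes = [self.nodes[i] for i in idx]
        return Connectome(sub_nodes, self.weights[np.ix_(idx, idx)],
                          require_paired=False)

    def mirror(self) -> "Connectome":
        """Swap every node with its homologue, permuting weights accordingly.

        The atlas is unchanged; only the weights move.  Mirroring twice is
        the identity, and a hemispherically symmetric connectome is a fixed
        point — both properties are exercised by the test-suite because the
        asymmetry index of a mirrored connectome must be the exact negation
        of the original's.
        """
        homologue = {}
        by_pair: dict[int, dict[str, int]] = {}
        for n in self.nodes:
            by_pair.setdefault(n.pair_id, {})[n.hemisphere] = n.node_id
        for sides in by_pair.values():
            homologue[sides["L"]] = sides["R"]
            homologue[sides["R"]] = sides["L"]
        perm = np.array([homologue[i] for i in range(self.n_nodes)])
        return Connectome(self.nodes, self.weights[np.ix_(perm, perm)])

    def threshold(self, min_weight: float) -> "Connectome":
        """Zero out edges with weight strictly below ``min_weight``."""
        w = self.weights.copy()
        w[w < min_weight] = 0.0
        return Connectome(self.nodes, w)

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        # full-precision floats so load -> write -> load round-trips exactly
        self.to_frame().to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Connectome)
            and self.nodes == other.nodes
            and np.array_equal(self.weights, other.weights)
        )


def load_atlas(path) -> list[AtlasNode]:
    """Read an atlas table (TSV with columns label, hemisphere, pair_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "hemisphere": str})
    required = {"label", "hemisphere", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas table missing columns {sorted(missing)}")
    nodes = [
        AtlasNode(i, row.label, row.hemisphere, int(row.pair_id))
        for i, row in enumerate(df.itertuples(index=False))
    ]
    _validate_atlas(nodes)
    return nodes


def write_atlas(nodes: list[AtlasNode], path) -> None:
    pd.DataFrame(
        {
            "label": [n.label for n in nodes],
            "hemisphere": [n.hemisphere for n in nodes],
            "pair_id": [n.pair_id for n in nodes],
        }
    ).to_csv(path, sep="\t", index=False)


def load_connectome(matrix_path, atlas_path, *, min_weight: float = 0.0) -> Connectome:
    """Load a connectome matrix and its atlas.

    The matrix file is TSV/CSV with a header row and header column of node
    labels.  Row/column order is label-driven: the matrix is re-indexed to
    the atlas order, so files may store nodes in any order as long as the
    label sets agree.

    Parameters
    ----------
    min_weight
        Optional construction threshold; edges lighter than this are
        dropped (default 0, keep everything).
    """
    nodes = load_atlas(atlas_path)
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(matrix_path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    labels = [n.label for n in nodes]
    if set(df.index) != set(labels) or set(df.columns) != set(labels):
        raise ValueError("matrix labels do not match atlas labels")
    df = df.loc[labels, labels]
    c = Connectome(nodes, df.to_numpy(dtype=float))
    if min_weight > 0:
        c = c.threshold(min_weight)
    return c
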