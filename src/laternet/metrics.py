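"""Weighted-graph topology metrics: degree and efficiency.

Edge weights are connection strengths; the travel "length" of an edge with
weight ``w > 0`` is ``1 / w`` (the standard convention for efficiency
metrics on weighted connectomes), and a zero weight means no edge.  Four
metrics are provided:

* nodal degree ``D_nodal`` — count of incident edges (or their weight sum
  in ``"strength"`` mode);
* nodal efficiency ``E_nodal(i) = (1/(N-1)) * sum_{j != i} 1/d_ij``;
* global efficiency ``E_glob`` — the mean of ``E_nodal``, equivalently the
  average inverse shortest-path length over ordered node pairs;
* local efficiency ``E_loc`` — the average over nodes of the global
  efficiency of each node's neighbour-induced subgraph (node excluded),
  with subgraphs of fewer than two nodes contributing 0.

Unreachable pairs contribute ``1/inf = 0`` rather than being dropped.

Two computational routes exist on purpose.  The per-graph functions route
shortest paths through :func:`scipy.sparse.csgraph.shortest_path`
(Dijkstra).  The ``batch_*`` functions run a vectorised Floyd–Warshall
over a stack of graphs, which is what makes simulation studies with
hundreds of thousands of small graphs tractable; the two routes are held
to agree exactly in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import Connectome, SCOPE_WHOLE, SCOPES

DEGREE_MODES = ("binary", "strength")

#: edge length for weight w is LENGTH_OF_WEIGHT(w) = 1 / w
def length_of_weight(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)


@dataclass
class MetricTable:
    """All four topology metrics for one graph scope (L, R or whole)."""

    scope: str
    labels: list[str]
    pair_ids: np.ndarray
    d_nodal: np.ndarray
    e_nodal: np.ndarray
    e_glob: float
    e_loc: float
    degree_mode: str = "binary"

    def to_frame(self, participant_id: str | None = None) -> pd.DataFrame:
        """Tidy long form: one row per (metric, node) plus global rows."""
        rows = []
        for lab, d, e in zip(self.labels, self.d_nodal, self.e_nodal):
            rows.append(("d_nodal", lab, d))
            rows.append(("e_nodal", lab, e))
        rows.append(("e_glob", "", self.e_glob))
        rows.append(("e_loc", "", self.e_loc))
        df = pd.DataFrame(rows, columns=["metric", "node_label", "value"])
        df.insert(0, "scope", self.scope)
        if participant_id is not None:
            df.insert(0, "participant_id", participant_id)
        return df


# ---------------------------------------------------------------------------
# per-graph route (scipy Dijkstra)
# ---------------------------------------------------------------------------

def path_lengths(c: Connectome) -> np.ndarray:
    """All-pairs shortest-path lengths under edge length 1/weight.

    Returns a symmetric matrix with zero diagonal and ``inf`` for
    disconnected pairs.
    """
    return _path_lengths_weights(c.weights)


def _path_lengths_weights(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def nodal_degree(c: Connectome, mode: str = "binary") -> np.ndarray:
    """Per-node degree: edge count (``binary``) or weight sum (``strength``)."""
    if mode not in DEGREE_MODES:
        raise ValueError(f"unknown degree mode {mode!r}; use one of {DEGREE_MODES}")
    if mode == "binary":
        return (c.weights > 0).sum(axis=1).astype(float)
    return c.weights.sum(axis=1)


def _nodal_efficiency_from_d(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(c: Connectome) -> np.ndarray:
    """``E_nodal(i)``: mean inverse distance from node i to every other node."""
    if c.n_nodes < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    return _nodal_efficiency_from_d(path_lengths(c))


def global_efficiency(c: Connectome) -> float:
    """``E_glob``: mean inverse shortest-path length over all node pairs."""
    if c.n_nodes < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return float(nodal_efficiency(c).mean())


def _global_efficiency_weights(w: np.ndarray) -> float:
    if w.shape[0] < 2:
        return 0.0
    return float(_nodal_efficiency_from_d(_path_lengths_weights(w)).mean())


def local_efficiency(c: Connectome) -> float:
    """``E_loc``: mean over nodes of E_glob of the neighbour subgraph."""
    return _local_efficiency_weights(c.weights)


def _local_efficiency_weights(w: np.ndarray) -> float:
    n = w.shape[0]
    if n == 0:
        raise ValueError("local efficiency requires at least 1 node")
    acc = 0.0
    for i in range(n):
        nbr = np.flatnonzero(w[i] > 0)
        nbr = nbr[nbr != i]
        if nbr.size < 2:
            continue
        acc += _global_efficiency_weights(w[np.ix_(nbr, nbr)])
    return acc / n


def metric_table(
    c: Connectome, scope: str = SCOPE_WHOLE, degree_mode: str = "binary"
) -> MetricTable:
    """Compute all four metrics on the whole graph or one hemisphere."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    g = c if scope == SCOPE_WHOLE else c.extract_hemisphere(scope)
    return MetricTable(
        scope=scope,
        labels=g.labels,
        pair_ids=np.array([n.pair_id for n in g.nodes]),
        d_nodal=nodal_degree(g, degree_mode),
        e_nodal=nodal_efficiency(g),
        e_glob=global_efficiency(g),
        e_loc=local_efficiency(g),
        degree_mode=degree_mode,
    )


# ---------------------------------------------------------------------------
# batched route (vectorised Floyd–Warshall over a stack of graphs)
# ---------------------------------------------------------------------------

def _batch_floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """In-place Floyd–Warshall over a (batch, n, n) stack of length matrices."""
    d = lengths
    n = d.shape[-1]
    for k in range(n):
        np.minimum(d, d[:, :, k, None] + d[:, k, None, :], out=d)
    return d


def batch_path_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths for a (batch, n, n) stack of weight matrices."""
    w = np.asarray(w, dtype=float)
    d = length_of_weight(w)
    idx = np.arange(w.shape[-1])
    d[:, idx, idx] = 0.0
    return _batch_floyd_warshall(d)


def _batch_inverse_d(d: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    idx = np.arange(d.shape[-1])
    inv[..., idx, idx] = 0.0
    return inv


def batch_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    """``E_nodal`` for each graph in a stack; shape (batch, n)."""
    n = w.shape[-1]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    return _batch_inverse_d(batch_path_lengths(w)).sum(axis=-1) / (n - 1)


def batch_global_efficiency(w: np.ndarray) -> np.ndarray:
    """``E_glob`` for each graph in a stack; shape (batch,)."""
    return batch_nodal_efficiency(w).mean(axis=-1)


def batch_local_efficiency(w: np.ndarray) -> np.ndarray:
    """``E_loc`` for each graph in a stack; shape (batch,).

    Implemented by padding every neighbour subgraph to full size with
    unreachable (infinite-length) rows so a single Floyd–Warshall sweep
    covers all batch * n subgraphs at once.
    """
    w = np.asarray(w, dtype=float)
    b, n, _ = w.shape
    adj = w > 0
    lengths = length_of_weight(w)
    # masked[g, i, j, l]: length of edge j-l inside the neighbour subgraph of i
    pair_ok = adj[:, :, :, None] & adj[:, :, None, :]
    masked = np.where(pair_ok, lengths[:, None, :, :], np.inf)
    idx = np.arange(n)
    masked[..., idx, idx] = 0.0
    d = _batch_floyd_warshall(masked.reshape(b * n, n, n)).reshape(b, n, n, n)
    inv = _batch_inverse_d(d.reshape(b * n, n, n)).reshape(b, n, n, n)
    inv = np.where(pair_ok, inv, 0.0)
    m = adj.sum(axis=-1)  # neighbour counts, (b, n)
    sums = inv.sum(axis=(-1, -2))
    denom = m * (m - 1)
    e_sub = np.where(denom >= 2, sums / np.where(denom > 0, denom, 1), 0.0)
    return e_sub.mean(axis=-1)
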