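"""Hemispheric asymmetry index for network topology metrics.

For a metric X computed separately on the left and right hemispheres,

    AI(X) = 100 * (X(L) - X(R)) / (X(L) + X(R))

in percent; positive values mean leftward lateralisation.  AI is applied
per homologous region pair for the nodal metrics (D_nodal, E_nodal) and
as a single scalar for the global metrics (E_glob, E_loc).  When both
hemisphere values are zero the index is undefined and reported as
missing (NaN) rather than 0 — a degenerate hemisphere carries no
laterality information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import AtlasNode
from .metrics import MetricTable


def asymmetry_index(x_left, x_right):
    """100 * (L - R) / (L + R); NaN when L + R == 0.

    Accepts scalars or arrays of nonnegative finite metric values.
    Antisymmetric in its arguments, invariant to common rescaling, and
    bounded in [-100, 100] with equality only when one side is exactly 0.
    """
    left = np.asarray(x_left, dtype=float)
    right = np.asarray(x_right, dtype=float)
    if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
        raise ValueError("metric values must be finite")
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("metric values must be nonnegative")
    denom = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (left - right) / np.where(denom > 0, denom, 1.0)
        ai = np.where(denom > 0, 100.0 * ratio, np.nan)
    if ai.ndim == 0:
        return float(ai)
    return ai


@dataclass
class AsymmetryProfile:
    """AI values per homologous pair (nodal metrics) and per graph (global)."""

    pair_ids: np.ndarray
    pair_labels: list[str]
    ai_d_nodal: np.ndarray
    ai_e_nodal: np.ndarray
    ai_e_glob: float
    ai_e_loc: float

    def to_frame(self, participant_id: str | None = None) -> pd.DataFrame:
        rows = []
        for lab, d, e in zip(self.pair_labels, self.ai_d_nodal, self.ai_e_nodal):
            rows.append(("ai_d_nodal", lab, d))
            rows.append(("ai_e_nodal", lab, e))
        rows.append(("ai_e_glob", "", self.ai_e_glob))
        rows.append(("ai_e_loc", "", self.ai_e_loc))
        df = pd.DataFrame(rows, columns=["metric", "pair_label", "ai_percent"])
        if participant_id is not None:
            df.insert(0, "participant_id", participant_id)
        return df


def asymmetry_profile(
    left: MetricTable, right: MetricTable, atlas: list[AtlasNode]
) -> AsymmetryProfile:
    """Pairwise AI profile from hemisphere-extracted metric tables.

    Nodal values are aligned across hemispheres by ``pair_id``; the two
    tables must come from the L and R extractions of the same connectome.
    Pair labels are taken from the left-hemisphere node of each pair.
    """
    if left.scope != "L" or right.scope != "R":
        raise ValueError(
            f"expected scopes ('L', 'R'), got ({left.scope!r}, {right.scope!r})"
        )
    if sorted(left.pair_ids) != sorted(right.pair_ids):
        raise ValueError("pair mismatch between left and right metric tables")
    order = np.argsort(left.pair_ids)
    pair_ids = np.asarray(left.pair_ids)[order]
    right_pos = {pid: i for i, pid in enumerate(right.pair_ids)}
    ridx = np.array([right_pos[pid] for pid in pair_ids])
    label_of_left = {n.pair_id: n.label for n in atlas if n.hemisphere == "L"}
    return AsymmetryProfile(
        pair_ids=pair_ids,
        pair_labels=[label_of_left.get(pid, str(pid)) for pid in pair_ids],
        ai_d_nodal=asymmetry_index(left.d_nodal[order], right.d_nodal[ridx]),
        ai_e_nodal=asymmetry_index(left.e_nodal[order], right.e_nodal[ridx]),
        ai_e_glob=asymmetry_index(left.e_glob, right.e_glob),
        ai_e_loc=asymmetry_index(left.e_loc, right.e_loc),
    )
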