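"""Covariate-adjusted group and correlation statistics.

The analyses here mirror the standard toolkit for case/control imaging
genetics: ANCOVA (a linear model with group dummies plus covariates,
tested by the partial F on the group terms), Fisher's LSD pairwise post
hoc contrasts on the adjusted group means, Bonferroni correction over an
explicit test family, partial correlation by joint residualisation, and
Pearson chi-square tests of independence for categorical demographics.

Cohort tables are plain :class:`pandas.DataFrame` objects with at least
``participant_id``, ``group``, ``age`` and ``gender`` columns (gender is
a 0/1 code used as a single covariate column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("SZ", "GHR", "HC")
COHORT_COLUMNS = ["participant_id", "group", "age", "gender"]


@dataclass
class AssociationResult:
    """One statistical test: statistic, dof, raw and adjusted p-values."""

    outcome: str
    test: str  # ancova | partial_correlation | chi_square | anova
    statistic: float
    df: tuple
    p_raw: float
    n_used: int
    p_bonferroni: float | None = None
    family_size: int | None = None
    post_hoc: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "test": self.test,
            "statistic": self.statistic,
            "df1": self.df[0] if len(self.df) > 0 else np.nan,
            "df2": self.df[1] if len(self.df) > 1 else np.nan,
            "p_raw": self.p_raw,
            "p_bonferroni": np.nan if self.p_bonferroni is None else self.p_bonferroni,
            "family_size": np.nan if self.family_size is None else self.family_size,
            "n_used": self.n_used,
        }


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "group": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return df


def _design_columns(X: np.ndarray, names: list[str]) -> None:
    """Raise with the offending column names if the design is rank-deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    bad = []
    cols: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, cols + [j]]
        if np.linalg.matrix_rank(trial) == len(cols) + 1:
            cols.append(j)
        else:
            bad.append(names[j])
    raise ValueError(f"rank-deficient design; collinear columns: {bad}")


@dataclass
class AncovaFit:
    """Fitted ANCOVA context; feeds :func:`lsd_posthoc`."""

    outcome: str
    groups: list[str]
    covariates: list[str]
    model: object  # statsmodels OLS results for the full model
    f_statistic: float
    df: tuple
    p_raw: float
    n_used: int
    n_dropped: int
    param_names: list[str] = field(default_factory=list)

    def to_result(
        self, family_size: int | None = None, post_hoc: pd.DataFrame | None = None
    ) -> AssociationResult:
        p_adj = None
        if family_size is not None:
            p_adj = float(bonferroni([self.p_raw], family_size)[0])
        return AssociationResult(
            outcome=self.outcome,
            test="ancova" if self.covariates else "anova",
            statistic=self.f_statistic,
            df=self.df,
            p_raw=self.p_raw,
            n_used=self.n_used,
            p_bonferroni=p_adj,
            family_size=family_size,
            post_hoc=post_hoc,
        )


def ancova_group_test(
    outcome,
    cohort: pd.DataFrame,
    covariates=("age", "gender"),
    group_col: str = "group",
    outcome_name: str = "outcome",
) -> AncovaFit:
    """Group-effect F-test adjusting for covariates.

    Fits ``outcome ~ 1 + group dummies + covariates`` by OLS and tests the
    group dummies with the partial F comparing the full model against the
    covariates-only model.  With no covariates this is exactly one-way
    ANOVA.  Rows with a missing outcome or covariate are dropped listwise.

    Parameters
    ----------
    outcome
        Per-participant values aligned with ``cohort`` rows (array or
        Series).
    cohort
        Cohort frame with ``group_col`` and the covariate columns.

    Returns an :class:`AncovaFit`; call :func:`lsd_posthoc` on it for the
    pairwise contrasts and ``.to_result()`` for a flat record.
    """
    covariates = list(covariates)
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(cohort):
        raise ValueError("outcome length does not match cohort")
    groups = cohort[group_col].astype(str).to_numpy()
    C = cohort[covariates].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("ancova %s: dropped %d rows with missing data", outcome_name, n_dropped)
    y, groups, C = y[ok], groups[ok], C[ok]

    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if (counts < 3).any():
        raise ValueError(f"need >= 3 participants per group, got {counts.to_dict()}")
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    names = ["const"] + [f"group[{g}]" for g in levels[1:]] + covariates
    X_full = np.column_stack([np.ones(len(y)), dummies, C])
    _design_columns(X_full, names)
    X_red = np.column_stack([np.ones(len(y)), C])

    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = len(levels) - 1
    df_den = len(y) - X_full.shape[1]
    delta = max(red.ssr - full.ssr, 0.0)
    # guard the exact-fit corner (outcome fully explained by covariates):
    # both residual sums vanish and the F ratio is pure rounding noise
    tiny = np.finfo(float).eps * max(1.0, float(y @ y)) * len(y)
    if full.ssr <= tiny:
        f = 0.0 if delta <= tiny else np.inf
    else:
        f = (delta / df_num) / (full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return AncovaFit(
        outcome=outcome_name,
        groups=levels,
        covariates=covariates,
        model=full,
        f_statistic=float(f),
        df=(df_num, df_den),
        p_raw=p,
        n_used=len(y),
        n_dropped=n_dropped,
        param_names=names,
    )


def lsd_posthoc(fit: AncovaFit) -> pd.DataFrame:
    """Fisher's LSD pairwise contrasts on the covariate-adjusted means.

    Each contrast is a t-test on the difference of group coefficients
    using the pooled residual variance and residual dof of the full
    model.  Per LSD convention the p-values are unadjusted — family-level
    control is the Bonferroni gate on the omnibus tests.
    """
    if len(fit.groups) < 2:
        raise ValueError("post hoc needs at least 2 groups")
    res = fit.model
    k = len(fit.param_names)
    coef_of = {fit.groups[0]: None}
    for g in fit.groups[1:]:
        coef_of[g] = fit.param_names.index(f"group[{g}]")
    cov = np.asarray(res.cov_params())
    rows = []
    for i, g1 in enumerate(fit.groups):
        for g2 in fit.groups[i + 1:]:
            c = np.zeros(k)
            if coef_of[g1] is not None:
                c[coef_of[g1]] = 1.0
            if coef_of[g2] is not None:
                c[coef_of[g2]] -= 1.0
            est = float(c @ res.params)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else 0.0
            dof = fit.df[1]
            p = float(2 * sps.t.sf(abs(t), dof)) if se > 0 else 1.0
            rows.append(
                {"group1": g1, "group2": g2, "estimate": est, "se": se,
                 "t": t, "df": dof, "p": p}
            )
    return pd.DataFrame(rows)


def bonferroni(p_values, family_size: int) -> np.ndarray:
    """``min(1, p * family_size)`` for each p.

    ``family_size`` may exceed the number of p-values supplied (the family
    can include tests reported elsewhere) but never be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size < p.size:
        raise ValueError(
            f"family_size {family_size} smaller than number of tests {p.size}"
        )
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * family_size)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates plus an intercept
    by least squares; ``r`` is the Pearson correlation of the residuals
    and the two-tailed p comes from ``t = r * sqrt((n - 2 - k)/(1 - r^2))``
    on ``n - 2 - k`` degrees of freedom.  With no covariates this reduces
    exactly to the plain Pearson correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if len(x) != len(y) or len(x) != len(C):
        raise ValueError("x, y and covariates must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if (~ok).any():
        logger.info("partial_correlation: dropped %d incomplete rows", int((~ok).sum()))
        x, y, C = x[ok], y[ok], C[ok]
    n, k = len(x), C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations, got n={n}, k={k}")
    X = np.column_stack([np.ones(n), C])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if rx.std() <= 1e-12 * max(1.0, x.std()) or ry.std() <= 1e-12 * max(1.0, y.std()):
        raise ValueError("degenerate residuals (constant after residualisation)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), dof))
    return r, p


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (chi2, dof, p).  All expected counts must be positive, which
    rules out zero marginals.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("need a two-way count table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    return float(chi2), int(dof), float(p)
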