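"""Clumping + thresholding polygenic risk scores.

Given GWAS discovery summary statistics and a target-sample genotype
dosage matrix, scores are built in three steps:

1. :func:`harmonize` — drop strand-ambiguous (A/T, C/G) variants, align
   effect alleles between the discovery and target panels (flipping the
   effect-size sign where the allele labels are swapped), and drop
   variants absent from the target panel.
2. :func:`clump` — p-value-informed greedy LD clumping: repeatedly take
   the most significant remaining variant as an index and remove every
   other variant within ``window_bp`` on the same chromosome whose
   in-sample LD with the index reaches ``r2 >= r2_cut``.
3. :func:`score_thresholds` — for each p-value threshold of the grid,
   sum effect-weighted dosages over the retained variants at or below
   that threshold.

LD is computed in-sample from the target dosages (squared Pearson
correlation).  The default threshold grid is the twelve-point grid
0.0001 … 0.5 commonly used for schizophrenia scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]
VARIANT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2"]
DEFAULT_THRESHOLDS = (
    0.0001, 0.001, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
)
DEFAULT_R2_CUT = 0.1
DEFAULT_WINDOW_BP = 250_000

_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# containers and I/O
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Participants x variants dosage matrix (count of the A1 allele).

    Dosages lie in [0, 2]; missing genotypes are NaN.  ``variants`` is a
    metadata frame with columns SNP, CHR, BP, A1, A2 in column order of
    ``dosages``.
    """

    participants: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.participants), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.participants)} participants x {len(self.variants)} variants"
            )
        _validate_variants(self.variants)
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] or be missing")

    def column_of(self, snp: str) -> int:
        hits = np.flatnonzero((self.variants["SNP"] == snp).to_numpy())
        if hits.size != 1:
            raise KeyError(f"variant {snp!r} not uniquely present in panel")
        return int(hits[0])


@dataclass
class HarmonizeReport:
    """Book-keeping from allele harmonisation; all counts are variants."""

    n_input: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0
    n_allele_mismatch: int = 0
    n_flipped: int = 0
    n_retained: int = 0


@dataclass
class PRSSet:
    """Scores per participant per p-value threshold, plus retained variants."""

    thresholds: list[float]
    scores: pd.DataFrame  # index participant_id, one column per threshold
    retained: dict[float, list[str]] = field(default_factory=dict)
    mode: str = "sum"

    def write(self, scores_path, ledger_path) -> None:
        self.scores.to_csv(scores_path, sep="\t")
        rows = [
            {"threshold": t, "SNP": snp}
            for t in self.thresholds
            for snp in self.retained[t]
        ]
        pd.DataFrame(rows, columns=["threshold", "SNP"]).to_csv(
            ledger_path, sep="\t", index=False
        )


def _validate_variants(df: pd.DataFrame) -> None:
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    for col in ("A1", "A2"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            raise ValueError(f"invalid alleles in column {col}: {df.loc[bad, col].unique()[:5]}")
    if (df["A1"] == df["A2"]).any():
        raise ValueError("effect and other allele must differ")
    if (df["BP"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")


def read_sumstats(path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV.

    Requires SNP, CHR, BP, A1, A2, P and either BETA (log-odds scale) or
    OR; odds ratios are log-transformed on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    if "BETA" not in df.columns:
        if "OR" not in df.columns:
            raise ValueError("summary statistics need a BETA or OR column")
        df["BETA"] = np.log(df["OR"].astype(float))
    return validate_sumstats(df)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns {sorted(missing)}")
    df = df[SUMSTATS_COLUMNS].copy()
    df["CHR"] = df["CHR"].astype(str)
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise ValueError(f"duplicate variant id in summary statistics: {dup!r}")
    _validate_variants(df)
    p = df["P"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    # one physical site, two conflicting allele annotations -> unusable
    dup = df.duplicated(subset=["CHR", "BP"], keep=False)
    if dup.any():
        sub = df.loc[dup].copy()
        sub["allele_key"] = [
            "/".join(sorted((a1, a2))) for a1, a2 in zip(sub["A1"], sub["A2"])
        ]
        n_keys = sub.groupby(["CHR", "BP"])["allele_key"].nunique()
        if (n_keys > 1).any():
            chrom, bp = n_keys[n_keys > 1].index[0]
            raise ValueError(f"conflicting alleles at duplicated position {chrom}:{bp}")
    return df


def read_genotypes(dosage_path, variants_path) -> GenotypeMatrix:
    """Read a wide dosage TSV (participant rows) and variant metadata TSV."""
    variants = pd.read_csv(
        variants_path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str}
    )
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dos.columns = dos.columns.astype(str)
    order = [snp for snp in variants["SNP"]]
    if set(order) != set(dos.columns):
        raise ValueError("dosage columns do not match variant metadata")
    dos = dos[order]
    return GenotypeMatrix(
        participants=[str(p) for p in dos.index],
        variants=variants,
        dosages=dos.to_numpy(dtype=float),
    )


def write_genotypes(geno: GenotypeMatrix, dosage_path, variants_path) -> None:
    pd.DataFrame(
        geno.dosages, index=pd.Index(geno.participants, name="participant_id"),
        columns=geno.variants["SNP"],
    ).to_csv(dosage_path, sep="\t")
    geno.variants.to_csv(variants_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """Strand-ambiguous allele pairs (A/T or C/G)."""
    pair = [frozenset((x, y)) for x, y in zip(a1, a2)]
    return pd.Series([p in _AMBIGUOUS_PAIRS for p in pair], index=a1.index)


def harmonize(
    sumstats: pd.DataFrame, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Align discovery summary statistics to the target genotype panel.

    Strand-ambiguous variants are excluded outright.  Variants whose
    alleles match the panel after swapping A1/A2 are realigned by negating
    the effect size (equivalent to reading the dosage as ``2 - g``, up to
    a per-participant constant that cancels in any correlation or
    group-contrast analysis).  Variants absent from the panel, or present
    with irreconcilable alleles, are dropped and counted.

    Returns the harmonised summary statistics (allele coding and
    coordinates of the target panel) and a :class:`HarmonizeReport`.
    """
    ss = validate_sumstats(sumstats)
    report = HarmonizeReport(n_input=len(ss))

    ambiguous = is_ambiguous(ss["A1"], ss["A2"])
    report.n_ambiguous = int(ambiguous.sum())
    ss = ss[~ambiguous]

    panel = genotypes.variants
    merged = ss.merge(
        panel, on="SNP", how="left", suffixes=("", "_panel"), indicator=True
    )
    unmatched = merged["_merge"] == "left_only"
    report.n_unmatched = int(unmatched.sum())
    merged = merged[~unmatched]

    same = (merged["A1"] == merged["A1_panel"]) & (merged["A2"] == merged["A2_panel"])
    swapped = (merged["A1"] == merged["A2_panel"]) & (merged["A2"] == merged["A1_panel"])
    mismatch = ~(same | swapped)
    report.n_allele_mismatch = int(mismatch.sum())
    report.n_flipped = int(swapped.sum())
    merged = merged[~mismatch].copy()

    beta = merged["BETA"].to_numpy(float)
    beta[swapped[~mismatch].to_numpy()] *= -1.0
    out = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "CHR": merged["CHR_panel"].astype(str),
            "BP": merged["BP_panel"].astype(int),
            "A1": merged["A1_panel"],
            "A2": merged["A2_panel"],
            "BETA": beta,
            "P": merged["P"].to_numpy(float),
        }
    ).reset_index(drop=True)
    report.n_retained = len(out)
    logger.info(
        "harmonize: %d input, %d ambiguous, %d unmatched, %d allele-mismatch, "
        "%d flipped, %d retained",
        report.n_input, report.n_ambiguous, report.n_unmatched,
        report.n_allele_mismatch, report.n_flipped, report.n_retained,
    )
    return out, report


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

def ld_r2(genotypes: GenotypeMatrix, snp1: str, snp2: str) -> float:
    """Squared Pearson correlation of two dosage vectors (in-sample LD).

    Missing genotypes are excluded pairwise; a variant with zero variance
    in the complete pairs has undefined correlation, reported as 0.
    """
    x = genotypes.dosages[:, genotypes.column_of(snp1)]
    y = genotypes.dosages[:, genotypes.column_of(snp2)]
    return float(_r2_vector(x, y[:, None])[0])


def _r2_vector(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """r^2 of ``x`` against each column of ``ys``, pairwise-complete."""
    if x.shape[0] < 2:
        raise ValueError("need >= 2 participants with complete dosages")
    if np.all(np.isfinite(x)) and np.all(np.isfinite(ys)):
        # complete-data fast path: one matrix product for all columns
        xc = x - x.mean()
        yc = ys - ys.mean(axis=0)
        sx = np.sqrt((xc ** 2).sum())
        sy = np.sqrt((yc ** 2).sum(axis=0))
        ok = (sx > 0) & (sy > 0)
        r = np.where(ok, (xc @ yc) / np.where(ok, sx * sy, 1.0), 0.0)
        return r * r
    out = np.zeros(ys.shape[1])
    x_ok = np.isfinite(x)
    for j in range(ys.shape[1]):
        y = ys[:, j]
        ok = x_ok & np.isfinite(y)
        if ok.sum() < 2:
            raise ValueError("need >= 2 participants with complete dosages")
        xs, yv = x[ok], y[ok]
        sx, sy = xs.std(), yv.std()
        if sx == 0 or sy == 0:
            logger.debug("zero dosage variance; r^2 set to 0")
            continue
        r = float(np.corrcoef(xs, yv)[0, 1])
        out[j] = r * r
    return out


def clump(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_cut: float = DEFAULT_R2_CUT,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy p-value-informed LD clumping.

    Repeatedly promote the remaining variant with the smallest p-value to
    index status and remove every other remaining variant on the same
    chromosome within ``window_bp`` (|pos difference| <= window) whose
    in-sample ``r^2`` with the index is at least ``r2_cut``.  Ties on p are
    broken by (CHR, BP, SNP) so the output is independent of row order.

    Returns the index variants, ordered by ascending p.
    """
    ss = sumstats.reset_index(drop=True)
    if len(ss) == 0:
        return ss.copy()
    order = ss.sort_values(
        ["P", "CHR", "BP", "SNP"], kind="mergesort"
    ).index.to_numpy()
    col = {snp: genotypes.column_of(snp) for snp in ss["SNP"]}
    chrom = ss["CHR"].to_numpy()
    pos = ss["BP"].to_numpy()
    removed = np.zeros(len(ss), dtype=bool)
    keep: list[int] = []
    for i in order:
        if removed[i]:
            continue
        keep.append(i)
        near = np.flatnonzero(
            ~removed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        near = near[near != i]
        if near.size:
            x = genotypes.dosages[:, col[ss["SNP"].iloc[i]]]
            ys = genotypes.dosages[:, [col[ss["SNP"].iloc[j]] for j in near]]
            r2 = _r2_vector(x, ys)
            removed[near[r2 >= r2_cut]] = True
    out = ss.loc[keep].sort_values(
        ["P", "CHR", "BP", "SNP"], kind="mergesort"
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_thresholds(
    sumstats_clumped: pd.DataFrame,
    genotypes: GenotypeMatrix,
    thresholds=DEFAULT_THRESHOLDS,
    mode: str = "sum",
) -> PRSSet:
    """Effect-weighted dosage sums at each p-value threshold.

    ``score_t(participant) = sum over {v : p_v <= t} dosage(v) * beta_v``.
    Missing dosages are replaced by the variant's mean dosage.  In
    ``"mean"`` mode each score is divided by its variant count.  Retained
    variant ids are recorded per threshold; the sets are nested because a
    p-value filter is monotone.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    thresholds = sorted(float(t) for t in thresholds)
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be unique")
    ss = sumstats_clumped.reset_index(drop=True)
    cols = [genotypes.column_of(snp) for snp in ss["SNP"]]
    dos = genotypes.dosages[:, cols] if cols else np.zeros((len(genotypes.participants), 0))
    if dos.size:
        col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    beta = ss["BETA"].to_numpy(float)
    p = ss["P"].to_numpy(float)
    scores = {}
    retained = {}
    for t in thresholds:
        mask = p <= t
        retained[t] = ss.loc[mask, "SNP"].tolist()
        if not mask.any():
            warnings.warn(f"no variants retained at threshold {t:g}; scores are 0")
            scores[f"pt_{t:g}"] = np.zeros(len(genotypes.participants))
            continue
        s = dos[:, mask] @ beta[mask]
        if mode == "mean":
            s = s / mask.sum()
        scores[f"pt_{t:g}"] = s
    frame = pd.DataFrame(
        scores, index=pd.Index(genotypes.participants, name="participant_id")
    )
    return PRSSet(thresholds=thresholds, scores=frame, retained=retained, mode=mode)
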