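"""Synthetic cohorts, connectomes and genetics with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so that every stage — and the pipeline end to end — can be
exercised and its parameter recovery quantified without any external
data:

* a three-group cohort (schizophrenia / genetic-high-risk / control,
  default 97/79/192, ages 18–54) with a genotyped subsample (26 SZ +
  48 GHR);
* per-participant weighted connectomes built from a shared,
  hemispherically mirror-symmetric base graph.  Group effects enter as a
  left-versus-right multiplicative weight shift (raising the asymmetry
  index of the efficiency metrics in the SZ and GHR groups, with an
  extra shift focused on one designated homologous pair), and as a
  uniform whole-brain weight attenuation in the SZ group only (lowering
  whole-brain efficiency without touching asymmetry, which is
  scale-invariant).  Participant-level multiplicative edge noise breaks
  the mirror symmetry and provides the within-group variance;
* an LD-blocked genotype panel with matching discovery summary
  statistics, and a genetic coupling: each genotyped participant's
  asymmetry shift receives a term proportional to their (standardised,
  covariate-residualised) polygenic score, scaled so that the population
  partial correlation between the score and AI of local efficiency
  equals the configured ``rho``.

Scaling the intra-hemisphere weights of side L by ``exp(+a/2)`` and side
R by ``exp(-a/2)`` scales the extracted-hemisphere efficiencies by the
same factors, so the noiseless asymmetry index is exactly
``100 * tanh(a / 2)`` — the generator uses this closed form (and its
inverse) to translate between AI percent and weight-shift units.

Everything is deterministic given ``(seed, config)``; independent random
streams are derived per stage so that, e.g., changing the genetics
configuration does not perturb the connectome draw.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import prs as prs_mod
from .connectome import AtlasNode, Connectome, write_atlas
from .enrichment import write_gmt

# stage tags for per-stage random streams
_S_COHORT, _S_BASE, _S_NOISE, _S_GENETICS, _S_CALIB, _S_GENES = range(1, 7)


@dataclass
class SimulationConfig:
    """All tunables of the synthetic study, with the cohort-scale defaults."""

    seed: int = 0
    # cohort
    n_sz: int = 97
    n_ghr: int = 79
    n_hc: int = 192
    n_geno_sz: int = 26
    n_geno_ghr: int = 48
    age_mean: float = 30.0
    age_sd: float = 8.0
    age_min: float = 18.0
    age_max: float = 54.0
    # connectome
    n_nodes: int = 90
    edge_density: float = 0.4
    base_weight_logmean: float = 3.0
    base_weight_logsd: float = 0.8
    noise_sd: float = 0.25
    asym_shift_sz: float = 0.07
    asym_shift_ghr: float = 0.06
    focal_pair: int = 0
    focal_shift_sz: float = 0.12
    focal_shift_ghr: float = 0.10
    wholebrain_atten_sz: float = 0.88
    age_asym_coef: float = 0.006
    sex_asym_coef: float = 0.005
    age_scale_coef: float = -0.02
    # genetics
    n_variants: int = 1200
    block_size: int = 20
    block_latent_corr: float = 0.8
    maf_min: float = 0.05
    maf_max: float = 0.5
    causal_frac: float = 0.1
    beta_sd: float = 0.05
    discovery_n: int = 65_967  # 33,426 cases + 32,541 controls
    ambiguous_frac: float = 0.05
    flip_frac: float = 0.1
    extra_variant_frac: float = 0.03
    missing_frac: float = 0.01
    rho: float = 0.4
    coupling_threshold: float = 0.05
    coupling_scale: float | None = None  # AI percent per SD of score; None -> calibrate
    calibration_reps: int = 2

    def __post_init__(self):
        if min(self.n_sz, self.n_ghr, self.n_hc) <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_geno_sz > self.n_sz or self.n_geno_ghr > self.n_ghr:
            raise ValueError("genotyped subsample larger than its group")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.n_nodes % 2 != 0:
            raise ValueError("n_nodes must be even")
        for name in ("asym_shift_sz", "asym_shift_ghr", "focal_shift_sz",
                     "focal_shift_ghr", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Participant table: id, group, age, gender, genotyped flag.

    Ages are truncated-normal on [age_min, age_max]; gender is a fair
    0/1 draw.  The genotyped subsample is the first ``n_geno_*``
    participants of the SZ and GHR groups.
    """
    rng = _rng(cfg, _S_COHORT)
    groups = ["SZ"] * cfg.n_sz + ["GHR"] * cfg.n_ghr + ["HC"] * cfg.n_hc
    n = len(groups)
    a = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    b = (cfg.age_max - cfg.age_mean) / cfg.age_sd
    ages = sps.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )
    genders = rng.integers(0, 2, size=n)
    ids = (
        [f"SZ{i + 1:03d}" for i in range(cfg.n_sz)]
        + [f"GHR{i + 1:03d}" for i in range(cfg.n_ghr)]
        + [f"HC{i + 1:03d}" for i in range(cfg.n_hc)]
    )
    genotyped = (
        [i < cfg.n_geno_sz for i in range(cfg.n_sz)]
        + [i < cfg.n_geno_ghr for i in range(cfg.n_ghr)]
        + [False] * cfg.n_hc
    )
    return pd.DataFrame(
        {
            "participant_id": ids,
            "group": groups,
            "age": np.round(ages, 2),
            "gender": genders,
            "genotyped": genotyped,
        }
    )


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def default_atlas(n_nodes: int) -> list[AtlasNode]:
    """AAL-style fixture atlas: all L nodes first, homologues mirrored."""
    h = n_nodes // 2
    nodes = [AtlasNode(k, f"ROI{k:02d}_L", "L", k) for k in range(h)]
    nodes += [AtlasNode(h + k, f"ROI{k:02d}_R", "R", k) for k in range(h)]
    return nodes


def _base_weights(cfg: SimulationConfig) -> np.ndarray:
    """Shared mirror-symmetric base graph (left block == right block)."""
    rng = _rng(cfg, _S_BASE)
    h = cfg.n_nodes // 2
    # intra-hemisphere block, reused on both sides
    intra = np.zeros((h, h))
    iu = np.triu_indices(h, 1)
    present = rng.random(len(iu[0])) < cfg.edge_density
    w = np.exp(rng.normal(cfg.base_weight_logmean, cfg.base_weight_logsd, len(iu[0])))
    intra[iu] = np.where(present, w, 0.0)
    intra += intra.T
    # inter-hemisphere block; must be symmetric for mirror symmetry of the
    # whole graph.  Homotopic (callosal) edges are always present and strong.
    inter = np.zeros((h, h))
    present = rng.random(len(iu[0])) < cfg.edge_density / 2
    w = np.exp(rng.normal(cfg.base_weight_logmean - 0.5, cfg.base_weight_logsd, len(iu[0])))
    inter[iu] = np.where(present, w, 0.0)
    inter += inter.T
    np.fill_diagonal(inter, np.exp(rng.normal(cfg.base_weight_logmean + 0.5,
                                              cfg.base_weight_logsd, h)))
    top = np.hstack([intra, inter])
    bot = np.hstack([inter, intra])
    return np.vstack([top, bot])


def _age_z(cfg: SimulationConfig, age: np.ndarray) -> np.ndarray:
    return (np.asarray(age, float) - cfg.age_mean) / cfg.age_sd


def asym_to_ai_percent(a) -> np.ndarray:
    """Noiseless AI percent produced by a log left/right weight shift ``a``."""
    return 100.0 * np.tanh(np.asarray(a, float) / 2.0)


def ai_percent_to_asym(ai) -> np.ndarray:
    """Inverse of :func:`asym_to_ai_percent`."""
    return 2.0 * np.arctanh(np.asarray(ai, float) / 100.0)


def generate_connectomes(
    cohort: pd.DataFrame,
    cfg: SimulationConfig,
    extra_asym: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[AtlasNode], np.ndarray]:
    """Weight matrices for every cohort row, stacked (n_participants, n, n).

    ``extra_asym`` adds per-participant log L/R weight shift on top of
    the group, age and gender terms (used for the genetic coupling).
    Node order follows :func:`default_atlas`: left hemisphere first.
    """
    if rng is None:
        rng = _rng(cfg, _S_NOISE)
    atlas = default_atlas(cfg.n_nodes)
    base = _base_weights(cfg)
    n_part = len(cohort)
    n = cfg.n_nodes
    h = n // 2

    group = cohort["group"].to_numpy()
    z_age = _age_z(cfg, cohort["age"].to_numpy())
    sex_c = cohort["gender"].to_numpy(float) - 0.5
    alpha = np.where(group == "SZ", cfg.asym_shift_sz,
                     np.where(group == "GHR", cfg.asym_shift_ghr, 0.0))
    alpha = alpha + cfg.age_asym_coef * z_age + cfg.sex_asym_coef * sex_c
    if extra_asym is not None:
        add = cohort["participant_id"].map(extra_asym).fillna(0.0).to_numpy()
        alpha = alpha + add
    phi = np.where(group == "SZ", cfg.focal_shift_sz,
                   np.where(group == "GHR", cfg.focal_shift_ghr, 0.0))
    scale = np.where(group == "SZ", cfg.wholebrain_atten_sz, 1.0)
    scale = scale * np.exp(cfg.age_scale_coef * z_age)

    z = rng.standard_normal((n_part, n, n))
    z = np.triu(z, 1)
    z = z + z.transpose(0, 2, 1)
    weights = base[None, :, :] * np.exp(cfg.noise_sd * z)

    mult = np.ones((n_part, n, n))
    mult[:, :h, :h] *= np.exp(alpha / 2.0)[:, None, None]
    mult[:, h:, h:] *= np.exp(-alpha / 2.0)[:, None, None]
    f = cfg.focal_pair
    if not 0 <= f < h:
        raise ValueError(f"focal_pair {f} outside atlas ({h} pairs)")
    mult[:, f, :h] *= np.exp(phi / 2.0)[:, None]
    mult[:, :h, f] *= np.exp(phi / 2.0)[:, None]
    mult[:, h + f, h:] *= np.exp(-phi / 2.0)[:, None]
    mult[:, h:, h + f] *= np.exp(-phi / 2.0)[:, None]
    weights = weights * mult * scale[:, None, None]
    if not np.all(np.isfinite(weights)):
        raise ValueError("effect sizes too large: degenerate (non-finite) weights")
    return atlas, weights


def participant_connectome(
    atlas: list[AtlasNode], weights: np.ndarray, index: int
) -> Connectome:
    return Connectome(atlas, weights[index])


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

@dataclass
class GeneticsSim:
    """Genotypes + discovery summary stats + realised score coupling."""

    genotypes: prs_mod.GenotypeMatrix
    sumstats: pd.DataFrame
    prs: prs_mod.PRSSet
    score_component: pd.Series  # standardised covariate-residualised score
    causal: pd.DataFrame  # SNP, beta_true
    maf: np.ndarray


def _draw_alleles(rng: np.random.Generator, m: int, ambiguous_frac: float):
    """Allele pairs, a controlled fraction strand-ambiguous (A/T or C/G)."""
    nonamb = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
              ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
    amb = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    is_amb = rng.random(m) < ambiguous_frac
    a1 = np.empty(m, dtype="<U1")
    a2 = np.empty(m, dtype="<U1")
    pick_n = rng.integers(0, len(nonamb), m)
    pick_a = rng.integers(0, len(amb), m)
    for i in range(m):
        a1[i], a2[i] = amb[pick_a[i]] if is_amb[i] else nonamb[pick_n[i]]
    return a1, a2


def generate_genetics(cohort: pd.DataFrame, cfg: SimulationConfig) -> GeneticsSim:
    """LD-blocked genotypes for the genotyped subsample plus summary stats.

    Haplotypes come from a one-factor Gaussian model per LD block
    (latent within-block correlation ``block_latent_corr``) thresholded
    at each variant's allele frequency.  A random ``causal_frac`` of
    variants carries true effects; the discovery file reports those
    effects plus estimation noise at the configured discovery sample
    size, with Wald p-values.  A fraction of records has swapped allele
    orientation (beta negated), and a fraction of extra records is
    absent from the target panel, so harmonisation is exercised on
    realistic input.
    """
    rng = _rng(cfg, _S_GENETICS)
    sub = cohort[cohort["genotyped"]].reset_index(drop=True)
    n_g = len(sub)
    m = cfg.n_variants
    bs = cfg.block_size
    n_blocks = (m + bs - 1) // bs

    maf = rng.uniform(cfg.maf_min, cfg.maf_max, m)
    chrom = np.empty(m, dtype=object)
    bp = np.empty(m, dtype=int)
    block_id = np.empty(m, dtype=int)
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        chrom[lo:hi] = str(b % 22 + 1)
        start = 1_000_000 + (b // 22) * 2_000_000
        bp[lo:hi] = start + np.arange(hi - lo) * 5_000
        block_id[lo:hi] = b
    a1, a2 = _draw_alleles(rng, m, cfg.ambiguous_frac)
    snp = np.array([f"rs{i + 1:06d}" for i in range(m)])

    # haplotypes: one-factor latent Gaussian per block, thresholded at MAF
    c = cfg.block_latent_corr
    thr = sps.norm.ppf(maf)
    haps = np.zeros((2, n_g, m))
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        for h_i in range(2):
            shared = rng.standard_normal((n_g, 1))
            eps = rng.standard_normal((n_g, hi - lo))
            latent = np.sqrt(c) * shared + np.sqrt(1 - c) * eps
            haps[h_i, :, lo:hi] = latent < thr[lo:hi]
    dosage = haps.sum(axis=0)
    if cfg.missing_frac > 0:
        miss = rng.random(dosage.shape) < cfg.missing_frac
        dosage = np.where(miss, np.nan, dosage)

    variants = pd.DataFrame({"SNP": snp, "CHR": chrom, "BP": bp, "A1": a1, "A2": a2})
    geno = prs_mod.GenotypeMatrix(
        participants=sub["participant_id"].tolist(),
        variants=variants,
        dosages=dosage,
    )

    n_causal = max(1, int(round(cfg.causal_frac * m)))
    causal_idx = rng.choice(m, n_causal, replace=False)
    beta_true = np.zeros(m)
    beta_true[causal_idx] = rng.normal(0.0, cfg.beta_sd, n_causal)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.discovery_n * 0.25)
    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)

    ss = pd.DataFrame(
        {"SNP": snp, "CHR": chrom, "BP": bp, "A1": a1, "A2": a2,
         "BETA": beta_hat, "P": p}
    )
    flip = rng.random(m) < cfg.flip_frac
    ss.loc[flip, ["A1", "A2"]] = ss.loc[flip, ["A2", "A1"]].to_numpy()
    ss.loc[flip, "BETA"] = -ss.loc[flip, "BETA"]
    n_extra = int(round(cfg.extra_variant_frac * m))
    if n_extra:
        ea1, ea2 = _draw_alleles(rng, n_extra, cfg.ambiguous_frac)
        extra = pd.DataFrame(
            {
                "SNP": [f"rsX{i + 1:06d}" for i in range(n_extra)],
                "CHR": rng.integers(1, 23, n_extra).astype(str),
                "BP": 900_000_000 + np.arange(n_extra) * 10_000,
                "A1": ea1,
                "A2": ea2,
                "BETA": rng.normal(0, 0.02, n_extra),
                "P": rng.uniform(1e-6, 1.0, n_extra),
            }
        )
        ss = pd.concat([ss, extra], ignore_index=True)

    harmonized, _ = prs_mod.harmonize(ss, geno)
    clumped = prs_mod.clump(harmonized, geno)
    prs_set = prs_mod.score_thresholds(clumped, geno)
    s = prs_set.scores[f"pt_{cfg.coupling_threshold:g}"].to_numpy(float)
    X = np.column_stack(
        [np.ones(n_g), _age_z(cfg, sub["age"].to_numpy()),
         sub["gender"].to_numpy(float) - 0.5]
    )
    resid = s - X @ np.linalg.lstsq(X, s, rcond=None)[0]
    sd = resid.std()
    if sd == 0:
        raise ValueError("degenerate polygenic score (zero variance)")
    component = pd.Series(resid / sd, index=sub["participant_id"].to_numpy())
    return GeneticsSim(
        genotypes=geno,
        sumstats=ss,
        prs=prs_set,
        score_component=component,
        causal=pd.DataFrame({"SNP": snp[causal_idx], "beta_true": beta_true[causal_idx],
                             "block": block_id[causal_idx]}),
        maf=maf,
    )


# ---------------------------------------------------------------------------
# genetic coupling calibration
# ---------------------------------------------------------------------------

def calibrate_coupling(cfg: SimulationConfig) -> float:
    """Coupling scale (AI percent per SD of score) that realises ``rho``.

    If the residual spread of AI-E_loc around the covariate fit in the
    genotyped subsample is ``sigma``, adding ``lambda * s`` (``s``
    standardised, covariate-orthogonal) yields a population partial
    correlation ``lambda / sqrt(lambda^2 + sigma^2)``; inverting gives
    ``lambda = rho * sigma / sqrt(1 - rho^2)``.  ``sigma`` is estimated
    by simulating score-free copies of the genotyped subsample under the
    same base graph and noise level.
    """
    from .recovery import efficiency_summaries  # local import, avoids cycle

    cohort = generate_cohort(cfg)
    sub = cohort[cohort["genotyped"]].reset_index(drop=True)
    reps = pd.concat([sub] * max(1, cfg.calibration_reps), ignore_index=True)
    rng = _rng(cfg, _S_CALIB)
    _, weights = generate_connectomes(reps, cfg, rng=rng)
    summ = efficiency_summaries(weights, cfg.n_nodes // 2)
    ai = summ["ai_e_loc"]
    ok = np.isfinite(ai)
    if ok.sum() < 10:
        raise ValueError(
            "calibration failed: asymmetry index undefined for nearly all "
            "participants (degenerate hemispheres — increase edge density "
            "or atlas size)"
        )
    X = np.column_stack(
        [np.ones(len(reps)), _age_z(cfg, reps["age"].to_numpy()),
         reps["gender"].to_numpy(float) - 0.5]
    )[ok]
    ai = ai[ok]
    resid = ai - X @ np.linalg.lstsq(X, ai, rcond=None)[0]
    sigma = float(resid.std(ddof=X.shape[1]))
    return float(cfg.rho * sigma / np.sqrt(1.0 - cfg.rho ** 2))


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    """One synthetic study: cohort, connectomes, genetics, coupling."""

    cfg: SimulationConfig
    cohort: pd.DataFrame
    atlas: list[AtlasNode]
    weights: np.ndarray  # (n_participants, n, n), cohort row order
    genetics: GeneticsSim | None
    coupling_scale: float

    def connectome(self, participant_id: str) -> Connectome:
        idx = self.cohort.index[self.cohort["participant_id"] == participant_id]
        if len(idx) != 1:
            raise KeyError(participant_id)
        return Connectome(self.atlas, self.weights[int(idx[0])])


def simulate_dataset(cfg: SimulationConfig, with_genetics: bool = True) -> SimulatedData:
    """Generate a complete in-memory synthetic study."""
    cohort = generate_cohort(cfg)
    genetics = None
    extra = None
    lam = 0.0
    if with_genetics:
        genetics = generate_genetics(cohort, cfg)
        lam = cfg.coupling_scale if cfg.coupling_scale is not None else calibrate_coupling(cfg)
        ai_add = lam * genetics.score_component
        extra = pd.Series(ai_percent_to_asym(ai_add.to_numpy()), index=ai_add.index)
    atlas, weights = generate_connectomes(cohort, cfg, extra_asym=extra)
    return SimulatedData(
        cfg=cfg, cohort=cohort, atlas=atlas, weights=weights,
        genetics=genetics, coupling_scale=lam,
    )


def _synthetic_gene_annotation(cfg: SimulationConfig, genetics: GeneticsSim):
    """Synthetic gene intervals tiling the LD blocks, plus synthetic GMT terms.

    One gene spans each block; one term collects the genes of
    causal-variant blocks (so enrichment has signal to find), the rest
    are random subsets.
    """
    rng = _rng(cfg, _S_GENES)
    var = genetics.genotypes.variants
    blocks = var.assign(block=np.arange(len(var)) // cfg.block_size)
    rows = []
    for b, g in blocks.groupby("block"):
        rows.append(
            {"gene_id": f"GENE{b:03d}", "chrom": str(g["CHR"].iloc[0]),
             "start": int(g["BP"].min() - 2_000), "end": int(g["BP"].max() + 2_000)}
        )
    genes = pd.DataFrame(rows)
    universe = genes["gene_id"].tolist()
    causal_blocks = sorted(set(genetics.causal["block"]))
    causal_genes = [f"GENE{b:03d}" for b in causal_blocks]
    terms = [{"term_id": "SET000", "term_name": "causal_block_genes",
              "genes": frozenset(causal_genes)}]
    for t in range(1, 12):
        size = int(rng.integers(5, max(6, len(universe) // 3)))
        members = rng.choice(universe, min(size, len(universe)), replace=False)
        terms.append(
            {"term_id": f"SET{t:03d}", "term_name": f"random_set_{t}",
             "genes": frozenset(members)}
        )
    return genes, pd.DataFrame(terms)


def simulate(cfg: SimulationConfig, outdir) -> Path:
    """Materialise a synthetic study as the file tree the pipeline reads.

    Writes cohort.tsv, atlas.tsv, connectomes/<participant>.tsv, and —
    for the genotyped subsample — dosages.tsv, variants.tsv,
    sumstats.tsv, genes.tsv and genesets.gmt, plus the generating
    configuration as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    data.cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    write_atlas(data.atlas, outdir / "atlas.tsv")
    cdir = outdir / "connectomes"
    cdir.mkdir(exist_ok=True)
    labels = [n.label for n in data.atlas]
    for i, pid in enumerate(data.cohort["participant_id"]):
        pd.DataFrame(data.weights[i], index=labels, columns=labels).to_csv(
            cdir / f"{pid}.tsv", sep="\t", float_format=lambda v: repr(float(v))
        )
    if data.genetics is not None:
        g = data.genetics
        prs_mod.write_genotypes(
            g.genotypes, outdir / "dosages.tsv", outdir / "variants.tsv"
        )
        g.sumstats.to_csv(outdir / "sumstats.tsv", sep="\t", index=False)
        genes, terms = _synthetic_gene_annotation(cfg, g)
        genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        write_gmt(terms, outdir / "genesets.gmt")
    with open(outdir / "simulation_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2)
    return outdir
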