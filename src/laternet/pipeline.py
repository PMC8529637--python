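"""Stage orchestration: files in, tidy result tables out.

``run_pipeline`` executes metrics → asymmetry → polygenic scores →
association statistics → enrichment on a directory of input files (the
formats written by :func:`laternet.simulate.simulate`), writing one TSV
per result family plus a JSON manifest with the seed, parameters and
input digests so a run can be reproduced bit for bit.  The genetics
stages are optional: a config without genotype paths runs the imaging
arm only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import asymmetry_profile
from .connectome import load_atlas, load_connectome
from .enrichment import (
    GeneSetCollection,
    hypergeometric_enrichment,
    map_snps_to_genes,
    read_gene_intervals,
)
from .metrics import metric_table
from .prs import (
    DEFAULT_R2_CUT,
    DEFAULT_THRESHOLDS,
    DEFAULT_WINDOW_BP,
    clump,
    harmonize,
    read_genotypes,
    read_sumstats,
    score_thresholds,
)
from .stats import (
    ancova_group_test,
    bonferroni,
    chi_square_independence,
    lsd_posthoc,
    partial_correlation,
    read_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    cohort_path: str
    atlas_path: str
    connectome_dir: str
    outdir: str
    dosage_path: str | None = None
    variants_path: str | None = None
    sumstats_path: str | None = None
    genes_path: str | None = None
    gene_sets_path: str | None = None
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    clump_r2: float = DEFAULT_R2_CUT
    clump_window_bp: int = DEFAULT_WINDOW_BP
    covariates: list[str] = field(default_factory=lambda: ["age", "gender"])
    nodal_family_size: int = 90
    global_family_size: int = 2
    prs_family_size: int | None = None  # default: number of thresholds
    enrichment_threshold: float = 0.05
    degree_mode: str = "binary"
    min_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = [float(x) for x in self.thresholds]
        if sorted(set(t)) != t:
            raise ValueError("thresholds must be ascending and unique")
        if self.prs_family_size is None:
            self.prs_family_size = len(t)

    @property
    def has_genetics(self) -> bool:
        return all(
            p is not None
            for p in (self.dosage_path, self.variants_path, self.sumstats_path)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _flatten_results(fits, posthocs) -> tuple[pd.DataFrame, pd.DataFrame]:
    res_rows = [r.to_row() for r in fits]
    ph_rows = []
    for outcome, ph in posthocs:
        ph = ph.copy()
        ph.insert(0, "outcome", outcome)
        ph_rows.append(ph)
    results = pd.DataFrame(res_rows)
    posthoc = pd.concat(ph_rows, ignore_index=True) if ph_rows else pd.DataFrame()
    return results, posthoc


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with an error naming the stage; partial
    outputs are kept alongside a FAILED marker file.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        cohort = read_cohort(cfg.cohort_path)
        atlas = load_atlas(cfg.atlas_path)

        stage = "metrics"
        metric_frames = []
        ai_frames = []
        for pid in cohort["participant_id"]:
            c = load_connectome(
                Path(cfg.connectome_dir) / f"{pid}.tsv", cfg.atlas_path,
                min_weight=cfg.min_weight,
            )
            whole = metric_table(c, "whole", cfg.degree_mode)
            left = metric_table(c, "L", cfg.degree_mode)
            right = metric_table(c, "R", cfg.degree_mode)
            metric_frames.extend(
                t.to_frame(pid) for t in (whole, left, right)
            )
            stage = "asymmetry"
            ai_frames.append(asymmetry_profile(left, right, atlas).to_frame(pid))
            stage = "metrics"
        metrics_df = pd.concat(metric_frames, ignore_index=True)
        metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        ai_df = pd.concat(ai_frames, ignore_index=True)
        ai_df.to_csv(outdir / "asymmetry.tsv", sep="\t", index=False)

        prs_set = None
        harm_report = None
        clumped = None
        if cfg.has_genetics:
            stage = "prs"
            geno = read_genotypes(cfg.dosage_path, cfg.variants_path)
            sumstats = read_sumstats(cfg.sumstats_path)
            harmonized, harm_report = harmonize(sumstats, geno)
            clumped = clump(harmonized, geno, cfg.clump_r2, cfg.clump_window_bp)
            prs_set = score_thresholds(clumped, geno, cfg.thresholds)
            prs_set.write(outdir / "prs_scores.tsv", outdir / "prs_retained.tsv")
        else:
            logger.warning("no genetics inputs configured; skipping PRS and enrichment")

        stage = "associate"
        results, posthoc = _associate(cfg, cohort, metrics_df, ai_df, prs_set)
        results.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        posthoc.to_csv(outdir / "posthoc.tsv", sep="\t", index=False)

        if prs_set is not None and cfg.genes_path and cfg.gene_sets_path:
            stage = "enrich"
            genes = read_gene_intervals(cfg.genes_path)
            retained = set(prs_set.retained[float(cfg.enrichment_threshold)])
            variants = geno.variants[geno.variants["SNP"].isin(retained)]
            gene_list = map_snps_to_genes(variants, genes)
            collection = GeneSetCollection.from_gmt(
                cfg.gene_sets_path, genes["gene_id"]
            )
            enrich = hypergeometric_enrichment(gene_list, collection)
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "laternet_version": __version__,
            "seed": cfg.seed,
            "parameters": dataclasses.asdict(cfg),
            "inputs": {
                name: _digest(p)
                for name, p in {
                    "cohort": cfg.cohort_path,
                    "atlas": cfg.atlas_path,
                    "dosages": cfg.dosage_path,
                    "variants": cfg.variants_path,
                    "sumstats": cfg.sumstats_path,
                }.items()
                if p is not None
            },
            "harmonization": None if harm_report is None else dataclasses.asdict(harm_report),
            "n_clumped": None if clumped is None else int(len(clumped)),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return outdir


def _associate(cfg, cohort, metrics_df, ai_df, prs_set):
    """Group-difference and score-correlation statistics on tidy tables."""
    fits = []
    posthocs = []

    # demographics
    age_fit = ancova_group_test(
        cohort["age"], cohort, covariates=[], outcome_name="age"
    )
    fits.append(age_fit.to_result(family_size=1))
    table = pd.crosstab(cohort["group"], cohort["gender"]).to_numpy()
    chi2, dof, p = chi_square_independence(table)
    from .stats import AssociationResult

    fits.append(
        AssociationResult(
            outcome="gender", test="chi_square", statistic=chi2,
            df=(dof,), p_raw=p, n_used=int(table.sum()),
            p_bonferroni=p, family_size=1,
        )
    )

    def run_family(outcomes: dict[str, np.ndarray], family: int):
        for name, values in outcomes.items():
            fit = ancova_group_test(
                values, cohort, covariates=cfg.covariates, outcome_name=name
            )
            ph = lsd_posthoc(fit)
            fits.append(fit.to_result(family_size=family, post_hoc=ph))
            posthocs.append((name, ph))

    # AI, nodal: one test per homologous pair per nodal metric
    nodal_ai = {}
    for metric in ("ai_d_nodal", "ai_e_nodal"):
        sub = ai_df[ai_df["metric"] == metric]
        wide = sub.pivot(index="participant_id", columns="pair_label", values="ai_percent")
        wide = wide.reindex(cohort["participant_id"])
        for pair in wide.columns:
            nodal_ai[f"{metric}[{pair}]"] = wide[pair].to_numpy()
    run_family(nodal_ai, cfg.nodal_family_size)

    # AI, global
    global_ai = {}
    for metric in ("ai_e_glob", "ai_e_loc"):
        sub = ai_df[ai_df["metric"] == metric].set_index("participant_id")
        global_ai[metric] = sub["ai_percent"].reindex(cohort["participant_id"]).to_numpy()
    run_family(global_ai, cfg.global_family_size)

    # whole-brain nodal and global metrics
    whole = metrics_df[metrics_df["scope"] == "whole"]
    nodal_whole = {}
    for metric in ("d_nodal", "e_nodal"):
        sub = whole[whole["metric"] == metric]
        wide = sub.pivot(index="participant_id", columns="node_label", values="value")
        wide = wide.reindex(cohort["participant_id"])
        for node in wide.columns:
            nodal_whole[f"{metric}[{node}]"] = wide[node].to_numpy()
    run_family(nodal_whole, max(cfg.nodal_family_size, len(nodal_whole)))
    global_whole = {}
    for metric in ("e_glob", "e_loc"):
        sub = whole[(whole["metric"] == metric)].set_index("participant_id")
        global_whole[metric] = sub["value"].reindex(cohort["participant_id"]).to_numpy()
    run_family(global_whole, cfg.global_family_size)

    results, posthoc = _flatten_results(fits, posthocs)

    # partial correlations of every PRS threshold with the AI and
    # whole-brain global metrics, in the genotyped SZ+GHR participants
    if prs_set is not None:
        rows = []
        geno_ids = prs_set.scores.index
        sub = cohort.set_index("participant_id").loc[
            [p for p in geno_ids if p in set(cohort["participant_id"])]
        ]
        covs = sub[cfg.covariates].to_numpy(float)
        outcome_values = {
            name: pd.Series(vals, index=cohort["participant_id"])
            .reindex(sub.index)
            .to_numpy()
            for name, vals in {**global_ai, **global_whole}.items()
        }
        for name, values in outcome_values.items():
            for col in prs_set.scores.columns:
                scores = prs_set.scores.loc[sub.index, col].to_numpy(float)
                r, p = partial_correlation(values, scores, covs)
                rows.append({"outcome": name, "threshold": col, "r": r, "p_raw": p})
        pc = pd.DataFrame(rows)
        pc["p_bonferroni"] = np.concatenate(
            [
                bonferroni(g["p_raw"].to_numpy(), cfg.prs_family_size)
                for _, g in pc.groupby("outcome", sort=False)
            ]
        )
        pc_path_frame = pc
    else:
        pc_path_frame = pd.DataFrame(
            columns=["outcome", "threshold", "r", "p_raw", "p_bonferroni"]
        )
    outdir = Path(cfg.outdir)
    pc_path_frame.to_csv(outdir / "partial_correlations.tsv", sep="\t", index=False)
    return results, posthoc
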