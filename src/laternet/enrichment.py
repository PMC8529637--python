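"""Positional SNP-to-gene mapping and hypergeometric gene-set enrichment.

Variants are assigned to genes by coordinate containment in a local gene
interval table (1-based inclusive start/end, optional symmetric flank).
Over-representation of the resulting gene list in each annotated gene
set is tested with the upper-tail hypergeometric distribution

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the background universe size, K the gene-set size, n the
query list size (after intersection with the universe) and k the
overlap.  Bonferroni correction runs over the number of tested terms,
with the significance gate at adjusted p < 0.01 emitted as a flag
column, never as a row filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end"]
SIGNIFICANCE_LEVEL = 0.01


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene interval TSV: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("gene intervals must have start <= end")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene_id must be unique")
    return df


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    The default background is every gene in the local annotation table
    (members outside the universe are dropped with a log message).
    """

    terms: pd.DataFrame  # columns: term_id, term_name, genes (frozenset)
    universe: frozenset

    def __post_init__(self):
        if len(self.universe) < 2:
            raise ValueError("background universe must contain >= 2 genes")
        trimmed = []
        for genes in self.terms["genes"]:
            extra = genes - self.universe
            if extra:
                logger.info("dropping %d gene-set members outside universe", len(extra))
            kept = frozenset(genes) & self.universe
            if not kept:
                raise ValueError("gene set empty after intersection with universe")
            trimmed.append(kept)
        self.terms = self.terms.assign(genes=trimmed)

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                rows.append(
                    {"term_id": parts[0], "term_name": parts[1],
                     "genes": frozenset(g for g in parts[2:] if g)}
                )
        if not rows:
            raise ValueError("no gene sets found in GMT file")
        return cls(pd.DataFrame(rows), frozenset(universe))


def write_gmt(terms: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in terms.itertuples(index=False):
            fh.write("\t".join([row.term_id, row.term_name, *sorted(row.genes)]) + "\n")


def map_snps_to_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 0
) -> list[str]:
    """Genes whose interval (± flank) contains at least one variant.

    ``variants`` needs CHR and BP columns; a variant inside several
    overlapping genes maps to all of them.  The result is deduplicated
    and ordered as in the gene table.
    """
    out = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        pos = np.sort(variants.loc[variants["CHR"].astype(str) == str(chrom), "BP"].to_numpy())
        if pos.size == 0:
            continue
        lo = np.searchsorted(pos, gsub["start"].to_numpy() - flank_bp, side="left")
        hi = np.searchsorted(pos, gsub["end"].to_numpy() + flank_bp, side="right")
        out.extend(gsub.loc[(hi > lo).tolist(), "gene_id"])
    order = {g: i for i, g in enumerate(genes["gene_id"])}
    return sorted(set(out), key=order.get)


def hypergeometric_enrichment(
    gene_list, collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    Query genes outside the universe are dropped (logged).  Returns one
    row per term — no silent drops — sorted by raw p, with Bonferroni
    adjustment over the number of tested terms and a ``significant`` flag
    at adjusted p < 0.01.
    """
    query = set(gene_list)
    outside = query - collection.universe
    if outside:
        logger.info("dropping %d query genes outside universe", len(outside))
    query &= collection.universe
    if not query:
        raise ValueError("gene list empty after intersection with universe")
    n_univ = len(collection.universe)
    n_query = len(query)
    n_terms = len(collection.terms)
    rows = []
    for row in collection.terms.itertuples(index=False):
        k_overlap = len(query & row.genes)
        k_term = len(row.genes)
        p = float(hypergeom.sf(k_overlap - 1, n_univ, k_term, n_query))
        rows.append(
            {"term_id": row.term_id, "term_name": row.term_name,
             "overlap": k_overlap, "list_size": n_query,
             "term_size": k_term, "universe_size": n_univ, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_terms)
    out["significant"] = out["p_bonferroni"] < SIGNIFICANCE_LEVEL
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
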