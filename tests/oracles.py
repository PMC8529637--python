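"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, no shared code
with the package — so agreement with the fast implementation is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- shortest paths / efficiency --------------------------------------------

def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """Textbook O(n^3) all-pairs shortest paths with explicit loops."""
    n = lengths.shape[0]
    d = [[float(lengths[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = d[i][k] + d[k][j]
                if via < d[i][j]:
                    d[i][j] = via
    return np.array(d)


def lengths_from_weights(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.full((n, n), np.inf)
    for i in range(n):
        out[i, i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                out[i, j] = 1.0 / w[i, j]
    return out


def brute_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = floyd_warshall(lengths_from_weights(w))
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and math.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def brute_global_efficiency(w: np.ndarray) -> float:
    if w.shape[0] < 2:
        return 0.0
    return float(np.mean(brute_nodal_efficiency(w)))


def brute_local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    acc = 0.0
    for i in range(n):
        nbr = [j for j in range(n) if j != i and w[i, j] > 0]
        if len(nbr) < 2:
            continue
        sub = w[np.ix_(nbr, nbr)]
        acc += brute_global_efficiency(sub)
    return acc / n


# -- clumping / scoring ------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def naive_clump(sumstats, genotypes, r2_cut=0.1, window_bp=250_000) -> list[str]:
    """Greedy clumping by full enumeration over sorted rows."""
    rows = sumstats.sort_values(["P", "CHR", "BP", "SNP"]).to_dict("records")
    col = {snp: i for i, snp in enumerate(genotypes.variants["SNP"])}
    removed: set[str] = set()
    kept: list[str] = []
    for row in rows:
        if row["SNP"] in removed:
            continue
        kept.append(row["SNP"])
        x = genotypes.dosages[:, col[row["SNP"]]]
        for other in rows:
            if other["SNP"] == row["SNP"] or other["SNP"] in removed or other["SNP"] in kept:
                continue
            if other["CHR"] != row["CHR"]:
                continue
            if abs(other["BP"] - row["BP"]) > window_bp:
                continue
            y = genotypes.dosages[:, col[other["SNP"]]]
            if _pairwise_r2(x, y) >= r2_cut:
                removed.add(other["SNP"])
    return kept


def naive_scores(sumstats, genotypes, threshold) -> np.ndarray:
    """Per-participant score by explicit double loop, mean-imputing missing."""
    rows = sumstats.to_dict("records")
    col = {snp: i for i, snp in enumerate(genotypes.variants["SNP"])}
    n = len(genotypes.participants)
    out = np.zeros(n)
    for row in rows:
        if row["P"] > threshold:
            continue
        dos = genotypes.dosages[:, col[row["SNP"]]]
        finite = [d for d in dos if math.isfinite(d)]
        mean = sum(finite) / len(finite) if finite else 0.0
        for i in range(n):
            d = dos[i] if math.isfinite(dos[i]) else mean
            out[i] += d * row["BETA"]
    return out


# -- ANCOVA ------------------------------------------------------------------

def ancova_f_oracle(y, groups, covariates) -> tuple[float, int, int]:
    """Partial F for the group factor via explicit residual sums of squares."""
    y = np.asarray(y, float)
    levels = sorted(set(groups))
    dummies = np.column_stack([[1.0 if g == lv else 0.0 for g in groups]
                               for lv in levels[1:]])
    C = np.asarray(covariates, float)
    if C.size == 0:
        C = C.reshape(len(y), 0)
    ones = np.ones((len(y), 1))
    X_full = np.hstack([ones, dummies, C])
    X_red = np.hstack([ones, C])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss_f, rss_r = rss(X_full), rss(X_red)
    df_num = len(levels) - 1
    df_den = len(y) - X_full.shape[1]
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return f, df_num, df_den


# -- hypergeometric ----------------------------------------------------------

def hypergeom_upper_tail_enumeration(n_universe, k_term, n_query, k_overlap) -> float:
    """P(overlap >= k) by enumerating every possible query draw."""
    universe = range(n_universe)
    term = set(range(k_term))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(term.intersection(draw)) >= k_overlap:
            hits += 1
    return hits / total
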