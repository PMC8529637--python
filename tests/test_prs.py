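import numpy as np
import pandas as pd
import pytest

from laternet.prs import (
    DEFAULT_THRESHOLDS,
    GenotypeMatrix,
    clump,
    harmonize,
    ld_r2,
    read_genotypes,
    read_sumstats,
    score_thresholds,
    validate_sumstats,
    write_genotypes,
)

import oracles


def make_panel(dosages, chrom=None, bp=None, a1=None, a2=None):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(m)],
            "CHR": chrom if chrom is not None else ["1"] * m,
            "BP": bp if bp is not None else (np.arange(m) + 1) * 1000,
            "A1": a1 if a1 is not None else ["A"] * m,
            "A2": a2 if a2 is not None else ["G"] * m,
        }
    )
    return GenotypeMatrix([f"p{i}" for i in range(n)], variants, dosages)


def sumstats_for(panel, beta=None, p=None):
    m = len(panel.variants)
    df = panel.variants.copy()
    df["BETA"] = beta if beta is not None else np.linspace(0.1, 0.5, m)
    df["P"] = p if p is not None else np.linspace(0.001, 0.5, m)
    return df


def random_panel_and_sumstats(rng, n=40, m=20, missing=0.0, chroms=2):
    dos = rng.integers(0, 3, size=(n, m)).astype(float)
    # induce some LD by copying columns with noise
    for j in range(1, m):
        if rng.random() < 0.5:
            src = dos[:, j - 1].copy()
            flip = rng.random(n) < 0.2
            src[flip] = rng.integers(0, 3, flip.sum())
            dos[:, j] = src
    if missing:
        dos[rng.random(dos.shape) < missing] = np.nan
    chrom = [str(1 + (j % chroms)) for j in range(m)]
    bp = [1000 + 40_000 * (j // chroms) for j in range(m)]
    panel = make_panel(dos, chrom=chrom, bp=bp)
    ss = panel.variants.copy()
    ss["BETA"] = rng.normal(0, 0.1, m)
    ss["P"] = rng.uniform(1e-6, 1.0, m)
    return panel, ss


class TestHarmonize:
    def test_ambiguous_excluded(self):
        panel = make_panel(np.zeros((3, 2)))
        ss = sumstats_for(panel)
        ss.loc[0, ["A1", "A2"]] = ["A", "T"]  # strand-ambiguous
        out, report = harmonize(ss, panel)
        assert report.n_ambiguous == 1
        assert "rs0" not in set(out["SNP"])

    def test_cg_ambiguous_excluded(self):
        panel = make_panel(np.zeros((3, 1)), a1=["C"], a2=["G"])
        ss = sumstats_for(panel)
        out, report = harmonize(ss, panel)
        assert report.n_ambiguous == 1
        assert len(out) == 0

    def test_swapped_alleles_realigned(self):
        """Negating beta after an A1/A2 swap equals reading dosage as 2 - g."""
        dosages = np.array([[0.0], [1.0], [2.0]])
        panel = make_panel(dosages, a1=["A"], a2=["G"])
        ss = sumstats_for(panel, beta=[0.5], p=[0.01])
        ss.loc[0, ["A1", "A2"]] = ["G", "A"]  # swapped vs panel
        out, report = harmonize(ss, panel)
        assert report.n_flipped == 1
        assert out["BETA"].iloc[0] == -0.5
        scores = score_thresholds(out, panel, thresholds=[0.05]).scores.iloc[:, 0]
        manual = (2.0 - dosages[:, 0]) * 0.5  # original orientation by hand
        diff = manual - scores.to_numpy()
        assert np.allclose(diff, diff[0])  # equal up to a per-person constant

    def test_unmatched_dropped(self):
        panel = make_panel(np.zeros((3, 1)))
        ss = sumstats_for(panel)
        extra = ss.iloc[[0]].assign(SNP="rs_missing", BP=99_999)
        out, report = harmonize(pd.concat([ss, extra], ignore_index=True), panel)
        assert report.n_unmatched == 1
        assert list(out["SNP"]) == ["rs0"]

    def test_conflicting_duplicate_position_rejected(self):
        panel = make_panel(np.zeros((3, 2)))
        ss = sumstats_for(panel)
        ss["BP"] = [1000, 1000]
        ss.loc[1, ["A1", "A2"]] = ["T", "C"]
        with pytest.raises(ValueError, match="onflicting alleles"):
            harmonize(ss, panel)

    def test_irreconcilable_alleles_dropped(self):
        panel = make_panel(np.zeros((3, 1)), a1=["A"], a2=["G"])
        ss = sumstats_for(panel)
        ss.loc[0, ["A1", "A2"]] = ["A", "C"]
        out, report = harmonize(ss, panel)
        assert report.n_allele_mismatch == 1
        assert len(out) == 0


class TestLD:
    def test_identical_vectors(self):
        panel = make_panel(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], float))
        assert ld_r2(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        d0 = np.array([0.0, 1.0, 2.0, 0.0])
        panel = make_panel(np.column_stack([d0, 2 - d0]))
        assert ld_r2(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_uncorrelated(self):
        d0 = np.array([0.0, 0.0, 2.0, 2.0])
        d1 = np.array([0.0, 2.0, 0.0, 2.0])
        panel = make_panel(np.column_stack([d0, d1]))
        assert ld_r2(panel, "rs0", "rs1") == 0.0

    def test_zero_variance_is_zero(self):
        panel = make_panel(np.column_stack([[1, 1, 1], [0, 1, 2]]).astype(float))
        assert ld_r2(panel, "rs0", "rs1") == 0.0

    def test_missing_excluded_pairwise(self):
        d0 = np.array([0, 1, 2, np.nan, 2.0])
        d1 = np.array([0, 1, 2, 2, np.nan])
        panel = make_panel(np.column_stack([d0, d1]))
        assert ld_r2(panel, "rs0", "rs1") == pytest.approx(1.0)


class TestClump:
    def test_strongest_survives_within_window(self):
        d = np.array([[0.0], [1.0], [2.0], [0.0], [1.0]])
        dos = np.hstack([d, d, d])  # all pairwise r2 = 1 >= 0.1
        panel = make_panel(dos, bp=[1000, 50_000, 100_000])
        ss = sumstats_for(panel, p=[1e-8, 1e-5, 1e-3])
        out = clump(ss, panel)
        assert list(out["SNP"]) == ["rs0"]

    def test_window_excludes_distant_variants(self):
        d = np.array([[0.0], [1.0], [2.0], [0.0]])
        panel = make_panel(np.hstack([d, d]), bp=[1000, 301_000])
        ss = sumstats_for(panel, p=[1e-8, 1e-3])
        out = clump(ss, panel)
        assert sorted(out["SNP"]) == ["rs0", "rs1"]  # r2=1 but outside 250 kb

    def test_empty_input(self):
        panel = make_panel(np.zeros((3, 1)))
        ss = sumstats_for(panel).iloc[:0]
        assert len(clump(ss, panel)) == 0

    def test_row_order_invariance(self, rng):
        panel, ss = random_panel_and_sumstats(rng)
        base = list(clump(ss, panel)["SNP"])
        shuffled = ss.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert list(clump(shuffled, panel)["SNP"]) == base

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            panel, ss = random_panel_and_sumstats(
                rng, n=int(rng.integers(10, 40)), m=int(rng.integers(3, 25)),
                missing=float(rng.choice([0.0, 0.05])),
            )
            ours = list(clump(ss, panel)["SNP"])
            theirs = oracles.naive_clump(ss, panel)
            assert sorted(ours) == sorted(theirs)


class TestScoring:
    def test_single_variant_scores(self):
        panel = make_panel(np.array([[0.0], [1.0], [2.0]]))
        ss = sumstats_for(panel, beta=[0.5], p=[0.001])
        prs = score_thresholds(ss, panel, thresholds=[0.01])
        assert np.allclose(prs.scores.iloc[:, 0], [0.0, 0.5, 1.0])

    def test_retained_sets_nest(self, rng):
        panel, ss = random_panel_and_sumstats(rng)
        prs = score_thresholds(clump(ss, panel), panel)
        for lo, hi in zip(prs.thresholds, prs.thresholds[1:]):
            assert set(prs.retained[lo]) <= set(prs.retained[hi])

    def test_matches_naive_oracle(self, rng):
        panel, ss = random_panel_and_sumstats(rng, missing=0.05)
        prs = score_thresholds(ss, panel)
        for t in DEFAULT_THRESHOLDS:
            expected = oracles.naive_scores(ss, panel, t)
            assert np.allclose(prs.scores[f"pt_{t:g}"], expected, atol=1e-12)

    def test_empty_threshold_warns_and_zeroes(self):
        panel = make_panel(np.array([[0.0], [1.0]]))
        ss = sumstats_for(panel, p=[0.5])
        with pytest.warns(UserWarning, match="no variants"):
            prs = score_thresholds(ss, panel, thresholds=[0.0001, 1.0])
        assert np.all(prs.scores["pt_0.0001"] == 0.0)

    def test_mean_mode(self):
        panel = make_panel(np.array([[2.0, 2.0], [0.0, 0.0]]))
        ss = sumstats_for(panel, beta=[0.5, 0.3], p=[0.001, 0.001])
        s_sum = score_thresholds(ss, panel, thresholds=[0.01]).scores.iloc[:, 0]
        s_mean = score_thresholds(ss, panel, thresholds=[0.01], mode="mean").scores.iloc[:, 0]
        assert np.allclose(s_mean, s_sum / 2)

    def test_variant_reordering_invariance(self, rng):
        panel, ss = random_panel_and_sumstats(rng)
        prs1 = score_thresholds(ss, panel)
        prs2 = score_thresholds(ss.sample(frac=1.0, random_state=3), panel)
        assert np.allclose(prs1.scores.to_numpy(), prs2.scores.to_numpy(), atol=1e-12)


class TestIO:
    def test_genotype_roundtrip(self, rng, tmp_path):
        panel, _ = random_panel_and_sumstats(rng, missing=0.1)
        write_genotypes(panel, tmp_path / "dos.tsv", tmp_path / "var.tsv")
        back = read_genotypes(tmp_path / "dos.tsv", tmp_path / "var.tsv")
        assert back.participants == panel.participants
        assert np.allclose(back.dosages, panel.dosages, equal_nan=True)

    def test_or_log_transformed(self, tmp_path):
        df = pd.DataFrame(
            {"SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["A"], "A2": ["G"],
             "OR": [np.e], "P": [0.5]}
        )
        df.to_csv(tmp_path / "ss.tsv", sep="\t", index=False)
        out = read_sumstats(tmp_path / "ss.tsv")
        assert out["BETA"].iloc[0] == pytest.approx(1.0)

    def test_invalid_p_rejected(self):
        df = pd.DataFrame(
            {"SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["A"], "A2": ["G"],
             "BETA": [0.1], "P": [0.0]}
        )
        with pytest.raises(ValueError, match="p-values"):
            validate_sumstats(df)

    def test_dosage_range_enforced(self):
        with pytest.raises(ValueError, match="dosages"):
            make_panel(np.array([[3.0]]))
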