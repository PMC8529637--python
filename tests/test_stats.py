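import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from laternet.stats import (
    ancova_group_test,
    bonferroni,
    chi_square_independence,
    lsd_posthoc,
    partial_correlation,
)

import oracles


def cohort_frame(groups, ages=None, genders=None):
    n = len(groups)
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "group": groups,
            "age": ages if ages is not None else rng.uniform(20, 50, n),
            "gender": genders if genders is not None else rng.integers(0, 2, n),
        }
    )


class TestAncova:
    def test_matches_sums_of_squares_oracle(self):
        groups = ["SZ"] * 3 + ["GHR"] * 3 + ["HC"] * 3
        ages = [25, 30, 41, 22, 35, 28, 33, 27, 45]
        genders = [0, 1, 0, 1, 1, 0, 0, 1, 1]
        y = [1.2, 0.8, 1.5, 0.4, 0.9, 0.7, 0.2, 0.5, 0.6]
        cohort = cohort_frame(groups, ages, genders)
        fit = ancova_group_test(y, cohort)
        covs = np.column_stack([ages, genders])
        f, d1, d2 = oracles.ancova_f_oracle(y, groups, covs)
        assert fit.f_statistic == pytest.approx(f, rel=1e-10)
        assert fit.df == (d1, d2)
        assert fit.p_raw == pytest.approx(float(sps.f.sf(f, d1, d2)), rel=1e-10)

    def test_zero_covariates_equals_oneway_anova(self, rng):
        groups = ["A"] * 20 + ["B"] * 25 + ["C"] * 15
        y = rng.normal(0, 1, 60) + np.repeat([0.0, 0.3, -0.2], [20, 25, 15])
        cohort = cohort_frame(groups)
        fit = ancova_group_test(y, cohort, covariates=[])
        f_ref, p_ref = sps.f_oneway(y[:20], y[20:45], y[45:])
        assert fit.f_statistic == pytest.approx(f_ref, rel=1e-10)
        assert fit.p_raw == pytest.approx(p_ref, rel=1e-8)

    def test_covariate_absorbs_outcome(self, rng):
        """Outcome identical to a covariate leaves nothing for the groups."""
        cohort = cohort_frame(list(rng.choice(["A", "B", "C"], 60)))
        fit = ancova_group_test(cohort["age"], cohort)
        assert fit.f_statistic == pytest.approx(0.0, abs=1e-18)
        assert fit.p_raw == pytest.approx(1.0)

    def test_rank_deficient_design_named(self, rng):
        cohort = cohort_frame(["A"] * 10 + ["B"] * 10)
        cohort["age2"] = cohort["age"]
        with pytest.raises(ValueError, match="age2"):
            ancova_group_test(rng.normal(size=20), cohort, covariates=["age", "age2"])

    def test_missing_outcomes_dropped(self, rng):
        cohort = cohort_frame(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        y = rng.normal(size=30)
        y[3] = np.nan
        fit = ancova_group_test(y, cohort)
        assert fit.n_used == 29
        assert fit.n_dropped == 1

    def test_small_groups_rejected(self, rng):
        cohort = cohort_frame(["A"] * 2 + ["B"] * 10)
        with pytest.raises(ValueError, match="3 participants"):
            ancova_group_test(rng.normal(size=12), cohort)


class TestLSD:
    def test_identical_groups_give_null_contrast(self):
        y = [1.0, 2.0, 2.7, 1.0, 2.0, 2.7]  # not collinear with age
        cohort = cohort_frame(["A", "A", "A", "B", "B", "B"],
                              ages=[30, 40, 45, 30, 40, 45],
                              genders=[0, 1, 0, 0, 1, 0])
        fit = ancova_group_test(y, cohort)
        ph = lsd_posthoc(fit)
        assert ph["t"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert ph["p"].iloc[0] == pytest.approx(1.0)

    def test_contrast_antisymmetry(self, rng):
        groups = list(rng.choice(["SZ", "GHR", "HC"], 60))
        y = rng.normal(size=60)
        fit = ancova_group_test(y, cohort_frame(groups), covariates=[])
        ph = lsd_posthoc(fit).set_index(["group1", "group2"])
        # estimates are differences of adjusted means: g1 - g2
        est = {k: v for k, v in ph["estimate"].items()}
        means = {g: np.mean([yi for yi, gi in zip(y, groups) if gi == g])
                 for g in ("SZ", "GHR", "HC")}
        for (g1, g2), e in est.items():
            assert e == pytest.approx(means[g1] - means[g2], abs=1e-6)

    def test_shift_detected_only_in_shifted_group(self, rng):
        """+1 SD shift in one group: its contrasts fire, the null one doesn't."""
        n = 90
        hits_sz, hits_null = 0, 0
        runs = 200
        for _ in range(runs):
            groups = ["SZ"] * n + ["GHR"] * n + ["HC"] * n
            y = rng.normal(size=3 * n)
            y[:n] += 1.0
            cohort = cohort_frame(groups)
            fit = ancova_group_test(y, cohort)
            ph = lsd_posthoc(fit).set_index(["group1", "group2"])
            ps = {k: v for k, v in ph["p"].items()}
            def p_of(a, b):
                return ps.get((a, b), ps.get((b, a)))
            if p_of("SZ", "HC") < 0.05 and p_of("SZ", "GHR") < 0.05:
                hits_sz += 1
            if p_of("GHR", "HC") < 0.05:
                hits_null += 1
        assert hits_sz / runs >= 0.90
        assert hits_null / runs < 0.15


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.0004], 90)[0] == pytest.approx(0.036)
        assert bonferroni([0.5], 90)[0] == 1.0
        assert np.allclose(bonferroni([0.1, 0.7], 2), [0.2, 1.0])

    def test_family_one_is_identity(self):
        assert bonferroni([0.123], 1)[0] == 0.123

    def test_monotone_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=10))
        adj = bonferroni(p, 50)
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)
        with pytest.raises(ValueError, match="smaller"):
            bonferroni([0.5, 0.6], 1)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identity_gives_unit_correlation(self, rng):
        x = rng.normal(size=25)
        covs = rng.normal(size=(25, 2))
        r, p = partial_correlation(x, x, covs)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_pingouin(self, rng):
        n = 74
        age = rng.uniform(20, 50, n)
        sex = rng.integers(0, 2, n).astype(float)
        x = 0.02 * age + rng.normal(size=n)
        y = 0.03 * age - 0.2 * sex + 0.3 * x + rng.normal(size=n)
        r, p = partial_correlation(x, y, np.column_stack([age, sex]))
        df = pd.DataFrame({"x": x, "y": y, "age": age, "sex": sex})
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "sex"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        c = rng.normal(size=(40, 1))
        r1, p1 = partial_correlation(x, y, c)
        r2, p2 = partial_correlation(3 * x - 1, -2 * y + 5, 10 * c + 2)
        assert abs(r2) == pytest.approx(abs(r1), abs=1e-10)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_shared_covariate_confounding_removed(self, rng):
        z = rng.normal(size=200)
        x = z + 0.5 * rng.normal(size=200)
        y = z + 0.5 * rng.normal(size=200)
        r_raw, _ = partial_correlation(x, y)
        r_adj, _ = partial_correlation(x, y, z)
        assert r_raw > 0.5
        assert abs(r_adj) < 0.25

    def test_degenerate_residuals_rejected(self, rng):
        c = rng.normal(size=(20, 1))
        x = 2 * c[:, 0] + 1  # exactly linear in the covariate
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(x, rng.normal(size=20), c)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation([1, 2, 3], [1, 2, 3], np.ones((3, 1)))


class TestChiSquare:
    def test_independent_table(self):
        chi2, dof, p = chi_square_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_perfect_association(self):
        chi2, dof, p = chi_square_independence([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert dof == 1

    def test_df_of_3x2(self):
        _, dof, _ = chi_square_independence([[5, 6], [7, 8], [9, 10]])
        assert dof == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 5]])
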