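"""Repeated-measures ANOVA, Tukey HSD, exact Mann-Whitney, sample size.

Oracles: a from-scratch sum-of-squares partition written independently
here; statsmodels' AnovaRM; p-values frozen from an R lmer/emmeans run
(Tukey adjustment, within-subject error, Satterthwaite df) on the fixed
matrix below; complete enumeration for Mann-Whitney.
"""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from kneerig import mann_whitney_u, required_sample_size, rm_anova, tukey_hsd

# fixed 8 subjects x 4 conditions matrix (decreasing condition means,
# subject offsets, within noise); also the R-oracle reference dataset
FIXED = np.array([
    [99.876523, 79.118914, 63.442396, 29.963304],
    [80.322855, 75.513700, 56.953860, 18.401196],
    [102.945488, 86.255546, 70.115081, 34.302233],
    [106.173107, 104.662791, 69.384936, 23.770522],
    [102.380269, 81.759202, 66.457865, 24.030855],
    [94.320319, 80.351781, 65.579548, 19.562982],
    [92.450971, 83.060526, 60.136067, 23.801146],
    [106.554825, 96.699532, 80.386145, 25.001644],
])

# lmer(y ~ cond + (1|subject)) + emmeans pairs(adjust="tukey") on FIXED
R_TUKEY_P = {
    (0, 1): 8.02948956229e-04,
    (0, 2): 4.63738492051e-10,
    (0, 3): 4.36317648678e-14,
    (1, 2): 1.86448007689e-06,
    (1, 3): 4.49640324973e-14,
    (2, 3): 2.50166554139e-12,
}


def ss_partition_oracle(x):
    """Brute-force two-way (subject + treatment) partition, cell by cell."""
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    treat_means = x.mean(axis=0)
    ss_treat = sum(n * (treat_means[j] - grand) ** 2 for j in range(k))
    ss_err = sum(
        (x[i, j] - subj_means[i] - treat_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    F = (ss_treat / df_t) / (ss_err / df_e)
    return F, float(sps.f.sf(F, df_t, df_e))


class TestRmAnova:
    def test_no_treatment_effect_gives_f_zero_p_one(self):
        x = np.tile(np.array([[5.0], [7.0], [2.0]]), (1, 4))
        res = rm_anova(x)
        assert res.F_stat == 0.0 and res.p_value == 1.0

    def test_hand_computable_three_by_two(self):
        """{(1,2),(2,3),(3,5)}: SS partition by hand gives F = 16, p = F-sf."""
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])
        res = rm_anova(x)
        F_oracle, p_oracle = ss_partition_oracle(x)
        assert res.F_stat == pytest.approx(F_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)
        assert (res.df_treatment, res.df_error) == (1, 2)

    def test_matches_ss_partition_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n, k = rng.integers(3, 12), rng.integers(2, 6)
            x = rng.normal(50, 10, (n, k)) + rng.normal(0, 5, (n, 1))
            res = rm_anova(x)
            F_oracle, _ = ss_partition_oracle(x)
            assert res.F_stat == pytest.approx(F_oracle, rel=1e-10)

    def test_matches_statsmodels_anovarm(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        n, k = FIXED.shape
        long = pd.DataFrame({
            "y": FIXED.ravel(),
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
        })
        sm = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        res = rm_anova(FIXED)
        assert res.F_stat == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), rel=1e-10)
        assert res.p_value == pytest.approx(
            float(sm.anova_table["Pr > F"].iloc[0]), rel=1e-8)

    def test_missing_cells_rejected(self):
        x = FIXED.copy()
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova(x)

    def test_type_one_error_rate_under_null(self, rng):
        """10 000 null datasets (14 subjects, 4 states): rejection rate ~ alpha."""
        n, k, reps, alpha = 14, 4, 10_000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            rejections += rm_anova(x).p_value < alpha
        rate = rejections / reps
        assert abs(rate - alpha) <= 0.01

    def test_simulated_power_monotone_in_effect_size(self):
        """Power climbs along a fixed effect-size ladder, seeded."""
        rng = np.random.default_rng(7)
        powers = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            hits = 0
            for _ in range(300):
                x = rng.normal(0, 1, (14, 4))
                x[:, 1] += effect
                hits += rm_anova(x).p_value < 0.05
            powers.append(hits / 300)
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.9


class TestTukeyHsd:
    def test_identical_condition_means_give_p_one(self):
        x = np.array([[1.0, 1.0, 1.0]]) + np.arange(4)[:, None].astype(float)
        x = x + np.random.default_rng(0).normal(0, 0, x.shape)
        table = tukey_hsd(x)
        off_diag = table.p[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 1.0)

    def test_two_condition_case_equals_paired_t(self, rng):
        """k = 2: studentized-range p equals the paired t-test p (q = t sqrt 2)."""
        for _ in range(20):
            x = rng.normal(10, 3, (9, 2))
            table = tukey_hsd(x)
            t_res = sps.ttest_rel(x[:, 0], x[:, 1])
            assert table.p[0, 1] == pytest.approx(t_res.pvalue, rel=1e-9)

    def test_matches_frozen_r_emmeans_oracle(self):
        table = tukey_hsd(FIXED)
        for (i, j), p_oracle in R_TUKEY_P.items():
            assert table.p[i, j] == pytest.approx(p_oracle, abs=1e-6)

    def test_p_monotone_decreasing_in_mean_difference(self):
        """Larger mean separation -> smaller p at fixed error structure."""
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1.0, (10, 2))
        ps = []
        for delta in (0.1, 0.5, 1.0, 2.0):
            x = noise.copy()
            x[:, 1] += delta
            ps.append(tukey_hsd(x).p[0, 1])
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_symmetry_and_range(self):
        table = tukey_hsd(FIXED)
        assert np.allclose(table.p, table.p.T)
        assert np.all((table.p >= 0) & (table.p <= 1))


def mw_enumeration_oracle(a, b):
    """Exact two-sided p by direct enumeration (independent rewrite)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)

    def folded_u(idx):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        return max(u, na * nb - u)

    obs = folded_u(range(na))
    hits = total = 0
    for idx in combinations(range(na + nb), na):
        total += 1
        if folded_u(idx) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0

    def test_complete_separation_three_vs_three(self):
        """{1,2,3} vs {4,5,6}: 2 of 20 assignments are as extreme -> p = 0.1."""
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exhaustive_agreement_with_enumeration_up_to_n12(self, rng):
        """All sample-size splits with combined n <= 12, ties included."""
        for na in range(1, 7):
            for nb in range(na, 13 - na):
                a = np.round(rng.normal(0, 2, na), 0)  # coarse -> ties likely
                b = np.round(rng.normal(0.5, 2, nb), 0)
                assert mann_whitney_u(a, b) == pytest.approx(
                    mw_enumeration_oracle(a, b), abs=1e-12)

    def test_matches_scipy_exact_for_tie_free_data(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(1, 1, 5)
            ours = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRequiredSampleSize:
    def test_unit_effect_paired_t_needs_ten(self):
        """delta = sd, power 0.80, alpha 0.05 two-sided -> n = 10 (noncentral t)."""
        assert required_sample_size(30.0, 30.0) == 10

    def test_monotone_in_power(self):
        ns = [required_sample_size(30, 50, power=p) for p in (0.5, 0.8, 0.9, 0.99)]
        assert all(b >= a for a, b in zip(ns, ns[1:]))

    def test_doubling_sd_roughly_quadruples_n(self):
        n1 = required_sample_size(10.0, 40.0)
        n2 = required_sample_size(10.0, 80.0)
        assert n2 == pytest.approx(4 * n1, rel=0.10)

    def test_rm_anova_design_monotone_in_correlation(self):
        """Higher within-subject correlation -> fewer subjects needed; the
        omnibus F never beats the focused paired t at equal noncentrality."""
        ns = [required_sample_size(30, 50, design="rm_anova", correlation=r)
              for r in (0.2, 0.5, 0.8)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))
        for r, n_rm in zip((0.2, 0.5, 0.8), ns):
            n_t = required_sample_size(30, 50 * np.sqrt(2 * (1 - r)))
            assert n_rm >= n_t

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(-1.0, 50.0)
        with pytest.raises(ValueError):
            required_sample_size(30.0, 50.0, power=1.5)
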