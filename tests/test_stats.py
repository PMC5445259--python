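import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

import lesionmap as lm


class TestChi2:
    def test_guided_pop_vs_control_incidence(self):
        # impairment incidence 10/13 vs 10/30
        res = lm.chi2_2x2([10, 3, 10, 20])
        assert round(res.statistic, 2) == 6.93
        assert res.df == 1
        assert round(res.effect_size, 2) == 6.67

    def test_equal_proportions_give_zero(self):
        res = lm.chi2_2x2([10, 10, 20, 20])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_scipy_contingency(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 11, 4)
            ours = lm.chi2_2x2([a, b, c, d])
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_yates_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 11, 4)
            ours = lm.chi2_2x2([a, b, c, d], correction=True)
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_invariant_under_transpose_and_swaps(self, rng):
        a, b, c, d = 7, 3, 5, 11
        base = lm.chi2_2x2([a, b, c, d]).statistic
        assert lm.chi2_2x2([a, c, b, d]).statistic == pytest.approx(base)  # transpose
        assert lm.chi2_2x2([c, d, a, b]).statistic == pytest.approx(base)  # row swap
        assert lm.chi2_2x2([b, a, d, c]).statistic == pytest.approx(base)  # col swap

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            lm.chi2_2x2([0, 0, 5, 5])


def _fisher_enumeration(a, b, c, d, tails):
    """Independent hypergeometric enumeration oracle."""
    n = a + b + c + d
    k = a + c  # impaired margin
    m = a + b  # positive margin

    def prob(x):
        return (
            math.comb(k, x) * math.comb(n - k, m - x) / math.comb(n, m)
        )
    lo, hi = max(0, m - (n - k)), min(m, k)
    if tails == 1:
        return sum(prob(x) for x in range(a, hi + 1))
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_perfect_separation_small_table(self):
        res = lm.fisher_exact([5, 0, 0, 5], tails=1)
        assert res.p == pytest.approx(1.0 / 252.0)

    def test_symmetric_table_two_tailed_p_one(self):
        assert lm.fisher_exact([4, 4, 4, 4], tails=2).p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            a, b, c, d = rng.integers(0, 11, 4)
            if a + b == 0 or c + d == 0:
                continue
            for tails in (1, 2):
                ours = lm.fisher_exact([a, b, c, d], tails=tails)
                assert ours.p == pytest.approx(
                    _fisher_enumeration(a, b, c, d, tails), abs=1e-9
                )

    def test_directional_one_tailed_not_larger_than_two_tailed(self, rng):
        # the p of the observed direction never exceeds the two-tailed p
        for _ in range(40):
            a, b, c, d = rng.integers(0, 11, 4)
            p_greater = lm.fisher_exact([a, b, c, d], tails=1).p
            p_less = lm.fisher_exact([b, a, d, c], tails=1).p  # column swap
            p2 = lm.fisher_exact([a, b, c, d], tails=2).p
            assert min(p_greater, p_less) <= p2 + 1e-12

    def test_approaches_chi_square_for_large_balanced_tables(self):
        table = [200, 150, 150, 200]
        pf = lm.fisher_exact(table, tails=2).p
        pc = lm.chi2_2x2(table).p
        assert np.log(pf) == pytest.approx(np.log(pc), rel=0.05)


class TestMcNemar:
    def test_published_discordant_pairs(self):
        # phonological vs semantic-association impairment, frontal site
        assert round(lm.mcnemar(18, 1).statistic, 2) == 15.21
        # phonological vs auditory-matching impairment, frontal site
        assert round(lm.mcnemar(11, 1).statistic, 2) == 8.33

    def test_balanced_discordance_gives_zero(self):
        assert lm.mcnemar(7, 7).statistic == 0.0

    def test_no_discordant_pairs_undefined(self):
        with pytest.raises(ValueError):
            lm.mcnemar(0, 0)

    def test_uncorrected_formula(self, rng):
        for _ in range(30):
            b, c = rng.integers(0, 20, 2)
            if b + c == 0:
                continue
            assert lm.mcnemar(b, c).statistic == pytest.approx((b - c) ** 2 / (b + c))


class TestPooledT:
    def test_size_matched_severity_comparison(self):
        # frontal-damage group (46.9, 7.0, n=13) vs control (53.1, 7.3, n=30)
        res = lm.ttest_pooled(46.9, 7.0, 13, 53.1, 7.3, 30)
        assert res.df == 41
        assert abs(res.statistic) == pytest.approx(2.59, abs=0.01)
        assert res.effect_size == pytest.approx(0.86, abs=0.01)

    def test_matches_scipy_from_stats(self, rng):
        for _ in range(30):
            ma, mb = rng.normal(50, 10, 2)
            sa, sb = rng.uniform(2, 12, 2)
            na, nb = rng.integers(5, 40, 2)
            ours = lm.ttest_pooled(ma, sa, na, mb, sb, nb)
            ref = sps.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_raw_scores_accepted(self, rng):
        xa, xb = rng.normal(50, 5, 12), rng.normal(55, 5, 15)
        ours = lm.ttest_pooled(scores_a=xa, scores_b=xb)
        ref = sps.ttest_ind(xa, xb, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_equal_means_zero_effect(self):
        res = lm.ttest_pooled(50.0, 5.0, 10, 50.0, 5.0, 10)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_doubling_ns_preserves_d_increases_t(self):
        r1 = lm.ttest_pooled(50.0, 5.0, 10, 54.0, 5.0, 10)
        r2 = lm.ttest_pooled(50.0, 5.0, 20, 54.0, 5.0, 20)
        assert r2.effect_size == pytest.approx(r1.effect_size)
        assert abs(r2.statistic) > abs(r1.statistic)


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        assert lm.compare_dependent_correlations(0.5, 0.5, 0.3, 42).statistic == 0.0

    def test_sign_flips_with_difference(self):
        z1 = lm.compare_dependent_correlations(0.6, 0.3, 0.4, 42).statistic
        z2 = lm.compare_dependent_correlations(0.3, 0.6, 0.4, 42).statistic
        assert z1 == pytest.approx(-z2)
        assert z1 > 0

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            lm.compare_dependent_correlations(0.9, -0.9, 0.9, 42)

    def test_matches_bootstrap_on_trivariate_normal(self, rng):
        # bootstrap oracle: resample the correlation difference, z = d / se
        n = 42
        cov = np.array([[1.0, 0.6, 0.35], [0.6, 1.0, 0.45], [0.35, 0.45, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=n)
        r_xy = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        r_xz = np.corrcoef(x[:, 0], x[:, 2])[0, 1]
        r_yz = np.corrcoef(x[:, 1], x[:, 2])[0, 1]
        ours = lm.compare_dependent_correlations(r_xy, r_xz, r_yz, n)

        diffs = np.empty(10_000)
        for i in range(10_000):
            idx = rng.integers(0, n, n)
            s = x[idx]
            diffs[i] = (
                np.corrcoef(s[:, 0], s[:, 1])[0, 1] - np.corrcoef(s[:, 0], s[:, 2])[0, 1]
            )
        z_boot = (r_xy - r_xz) / diffs.std(ddof=1)
        assert ours.statistic == pytest.approx(z_boot, abs=0.5)


class TestPairedPredictiveValues:
    def test_identical_tests_give_unit_ratio(self, rng):
        pos = rng.random(80) < 0.4
        imp = rng.random(80) < 0.5
        out = lm.compare_paired_predictive_values(pos, pos, imp)
        assert out["ppv"].effect_size == pytest.approx(1.0)
        assert out["ppv"].statistic == 0.0
        assert out["npv"].statistic == 0.0

    def test_superset_of_impaired_extras_raises_ppv_ratio(self):
        imp = np.array([True] * 6 + [False] * 6)
        test_b = np.array([True] * 3 + [False] * 3 + [True] * 3 + [False] * 3)
        test_a = test_b.copy()
        test_a[3] = True  # extra positive who is impaired
        out = lm.compare_paired_predictive_values(test_a, test_b, imp)
        assert out["ppv"].effect_size >= 1.0

    def test_type_one_error_calibrated(self, rng):
        # exchangeable tests: both are noisy copies of the same latent signal
        n, reps, hits = 120, 600, 0
        for _ in range(reps):
            imp = rng.random(n) < 0.4
            latent = imp ^ (rng.random(n) < 0.25)
            ta = latent ^ (rng.random(n) < 0.15)
            tb = latent ^ (rng.random(n) < 0.15)
            try:
                out = lm.compare_paired_predictive_values(ta, tb, imp)
            except ValueError:
                continue
            hits += out["ppv"].p < 0.05
        rate = hits / reps
        assert 0.02 <= rate <= 0.09  # ~5% within Monte-Carlo slack

    def test_no_positives_flagged(self):
        with pytest.raises(ValueError):
            lm.compare_paired_predictive_values(
                [False, False], [True, False], [True, False]
            )


class TestBonferroni:
    def test_scaling_and_capping(self):
        assert lm.bonferroni([0.001], 27) == [pytest.approx(0.027)]
        assert lm.bonferroni([0.05], 27) == [1.0]
        assert lm.bonferroni([0.2]) == [pytest.approx(0.2)]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            lm.bonferroni([1.5])
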