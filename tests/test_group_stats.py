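"""Variance-gated group comparisons, effect sizes and paired region tests."""

import numpy as np
import pytest
from scipy import stats as sps

from entsense.group_stats import (
    cohens_d,
    effect_ci,
    effect_size,
    hedges_correction,
    region_paired_test,
    run_comparison,
    significance_stars,
    variance_gate,
)


class TestVarianceGate:
    def test_equal_variance_chooses_t_test(self):
        rng = np.random.default_rng(0)
        chosen, _, p = variance_gate(rng.normal(0, 1, 200), rng.normal(5, 1, 200))
        assert chosen == "t-test" and p >= 0.05

    def test_unequal_variances_choose_mann_whitney(self):
        rng = np.random.default_rng(1)
        chosen, _, _ = variance_gate(rng.normal(0, 1, 50), rng.normal(0, 5, 50))
        assert chosen == "mann-whitney"

    def test_identical_degenerate_groups_declared_equal(self):
        chosen, stat, p = variance_gate([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert chosen == "t-test" and p == 1.0

    def test_levene_type_i_rate_near_alpha(self):
        # same-normal draws: t-test chosen with probability ~ 1 - alpha
        rng = np.random.default_rng(2)
        chosen = [
            variance_gate(rng.normal(size=100), rng.normal(size=100))[0]
            for _ in range(400)
        ]
        frac_t = np.mean([c == "t-test" for c in chosen])
        assert frac_t == pytest.approx(0.95, abs=0.04)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            variance_gate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEffectSizes:
    def test_equal_means_zero_effect(self):
        name, val = effect_size([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert val == pytest.approx(0.0)

    def test_hand_example_pooled_sd_magnitude(self):
        # a=(0,0,1,1), b=(10,10,11,11): pooled SD = sqrt(1/3), |d| = 17.32;
        # sign follows sign(mean_b - mean_a), positive here
        d = cohens_d([0, 0, 1, 1], [10, 10, 11, 11])
        assert d == pytest.approx(10 / np.sqrt(1.0 / 3.0), rel=1e-12)
        assert d > 0

    def test_sign_negative_when_first_group_larger(self):
        # transgenic group (a) larger mean -> negative effect
        _, g = effect_size([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        assert g < 0

    def test_hedges_correction_small_sample_factor(self):
        # J = 1 - 3/(4 df - 1) with df = 6 at n=4 per group
        assert hedges_correction(4, 4) == pytest.approx(1 - 3 / 23)
        _, g = effect_size([0, 0, 1, 1], [10, 10, 11, 11], equal_variance=True)
        assert g == pytest.approx(cohens_d([0, 0, 1, 1], [10, 10, 11, 11]) * (1 - 3 / 23))

    def test_glass_delta_uses_control_sd(self):
        a = [0.0, 1.0, 2.0, 3.0]
        b = [10.0, 12.0, 14.0, 16.0]
        name, val = effect_size(a, b, equal_variance=False)
        assert name == "glass_delta"
        assert val == pytest.approx((13.0 - 1.5) / np.std(b, ddof=1))

    def test_glass_delta_zero_control_sd_rejected(self):
        with pytest.raises(ValueError, match="control"):
            effect_size([0.0, 1.0, 2.0], [5.0, 5.0, 5.0], equal_variance=False)

    def test_large_n_definition_limit(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, 20_000)
        b = rng.normal(0.0, 1.0, 20_000)
        assert cohens_d(a, b) == pytest.approx(-1.0, abs=0.05)


class TestEffectCI:
    def test_zero_effect_symmetric_ci(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        lo, hi = effect_ci(x, x.copy(), "hedges_g")
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        a_s, b_s = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        a_l = np.concatenate([a_s + rng.normal(0, 1e-3, 10) for _ in range(10)])
        b_l = np.concatenate([b_s + rng.normal(0, 1e-3, 10) for _ in range(10)])
        w_small = np.diff(effect_ci(a_s, b_s, "cohens_d"))[0]
        w_large = np.diff(effect_ci(a_l, b_l, "cohens_d"))[0]
        assert w_large < w_small

    def test_noncentral_t_inversion_matches_grid_oracle(self):
        # two n=20 groups constructed so d = -1 exactly (b - a convention)
        x = np.sqrt(19.0 / 20.0)
        a = np.array([x, -x] * 10) + 1.0
        b = np.array([x, -x] * 10)
        d = cohens_d(a, b)
        assert d == pytest.approx(-1.0, abs=1e-12)
        lo, hi = effect_ci(a, b, "cohens_d")
        # independent grid-search oracle over the noncentrality parameter
        df, scale = 38, np.sqrt(20 * 20 / 40)
        t_obs = d * scale
        ncs = np.linspace(t_obs - 8, t_obs + 8, 200_001)
        cdfs = sps.nct.cdf(t_obs, df, ncs)
        valid = np.isfinite(cdfs)
        ncs, cdfs = ncs[valid], cdfs[valid]
        lo_oracle = ncs[np.argmin(np.abs(cdfs - 0.975))] / scale
        hi_oracle = ncs[np.argmin(np.abs(cdfs - 0.025))] / scale
        assert lo == pytest.approx(lo_oracle, abs=1e-3)
        assert hi == pytest.approx(hi_oracle, abs=1e-3)

    def test_glass_bootstrap_is_seeded_and_covers_effect(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1, 2, 30)
        b = rng.normal(0, 1, 30)
        ci1 = effect_ci(a, b, "glass_delta", seed=3, n_boot=2000)
        ci2 = effect_ci(a, b, "glass_delta", seed=3, n_boot=2000)
        assert ci1 == ci2
        _, delta = effect_size(a, b, equal_variance=False)
        assert ci1[0] <= delta <= ci1[1]


class TestRunComparison:
    def test_identical_groups_unit_p_zero_effect(self):
        comp = run_comparison([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert comp.chosen_test == "t-test"
        assert comp.test_stat == 0.0
        assert comp.p_value == 1.0
        assert comp.effect == 0.0

    def test_strongly_shifted_normals_significant(self):
        rng = np.random.default_rng(7)
        comp = run_comparison(rng.normal(5, 1, 20), rng.normal(0, 1, 20))
        assert comp.p_value < 0.001
        assert comp.stars == "***"
        assert comp.ci_low <= comp.effect <= comp.ci_high

    def test_mann_whitney_branch_on_unequal_variances(self):
        rng = np.random.default_rng(8)
        comp = run_comparison(rng.normal(0, 1, 50), rng.normal(0, 5, 50))
        assert comp.chosen_test == "mann-whitney"
        assert comp.effect_name == "glass_delta"

    def test_mann_whitney_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 6, 40)
        _, p1 = sps.mannwhitneyu(a, b, alternative="two-sided")
        _, p2 = sps.mannwhitneyu(np.exp(a), np.exp(b), alternative="two-sided")
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            run_comparison([1.0, 2.0], [3.0, 4.0])


class TestRegionPairedTest:
    def test_four_all_positive_differences_exact_p(self):
        # exact two-sided sign-extreme probability: 2/2^4
        _, p = region_paired_test([2.0, 3.0, 4.0, 5.0], [1.0, 1.5, 2.0, 2.5])
        assert p == pytest.approx(0.125)

    def test_mirrored_differences_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 1.0, 4.0, 3.0]  # differences -1, +1, -1, +1
        _, p = region_paired_test(a, b)
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError, match="zero"):
            region_paired_test(x, list(x))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            region_paired_test([1, 2, 3, 4], [1, 2, 3])


def test_significance_star_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == "ns"
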