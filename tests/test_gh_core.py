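"""Closed-form ratio statistics: transformation, CI, thresholds, power."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from volratio import (
    DEFAULT_CV,
    RatioStatistics,
    classify_change,
    gh_transform,
    no_change_test,
    normal_quantile,
    power_at_ratio,
    pvalue_no_change,
    ratio_confidence_interval,
    symmetric_thresholds,
)


class TestGhTransform:
    def test_zero_at_true_ratio(self):
        """Z vanishes by construction when w equals mu2/mu1."""
        stats = RatioStatistics(mu1=40.0, mu2=26.0, sigma1=6.0, sigma2=4.0, rho=0.2)
        assert gh_transform(26.0 / 40.0, stats) == pytest.approx(0.0, abs=1e-14)

    def test_matches_95pct_quantile_at_upper_threshold(self):
        """The ~1.55 upper critical ratio transforms to ~1.96 under the null."""
        k = DEFAULT_CV
        stats = RatioStatistics(mu1=1.0, mu2=1.0, sigma1=k, sigma2=k)
        z = gh_transform(1.5543, stats)
        assert z == pytest.approx(1.96, abs=2e-3)
        # consistent with a two-sided p-value of ~5%
        assert 2 * (1 - 0.5 * (1 + math.erf(z / math.sqrt(2)))) == pytest.approx(
            0.05, abs=1e-3
        )

    def test_sign_follows_numerator(self):
        k = DEFAULT_CV
        stats = RatioStatistics(mu1=1.0, mu2=0.5, sigma1=k, sigma2=0.5 * k)
        z = gh_transform(1.0, stats)
        assert z > 0
        assert z == pytest.approx(0.5 / math.hypot(stats.sigma1, stats.sigma2))

    def test_degenerate_denominator_raises(self):
        stats = RatioStatistics(mu1=1.0, mu2=1.0, sigma1=0.1, sigma2=0.1, rho=1.0)
        with pytest.raises(ValueError, match="radicand"):
            gh_transform(1.0, stats)

    def test_cv_outside_validity_warns(self):
        stats = RatioStatistics(mu1=1.0, mu2=1.0, sigma1=0.5, sigma2=0.5)
        with pytest.warns(UserWarning, match="normal approximation"):
            gh_transform(1.2, stats)


class TestRatioStatistics:
    def test_cvs_are_derived(self):
        stats = RatioStatistics(mu1=50.0, mu2=25.0, sigma1=5.0, sigma2=5.0)
        assert stats.c1 == pytest.approx(0.1)
        assert stats.c2 == pytest.approx(0.2)
        assert stats.valid

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu1=0.0, mu2=1.0, sigma1=0.1, sigma2=0.1),
            dict(mu1=1.0, mu2=-2.0, sigma1=0.1, sigma2=0.1),
            dict(mu1=1.0, mu2=1.0, sigma1=-0.1, sigma2=0.1),
            dict(mu1=1.0, mu2=1.0, sigma1=0.1, sigma2=0.1, rho=1.5),
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            RatioStatistics(**kwargs)


class TestConfidenceInterval:
    def test_simplified_95pct_limits(self):
        """Equal volumes at the ~15% CV give the [~0.64, ~1.55] interval."""
        ci = ratio_confidence_interval(100.0, 100.0, DEFAULT_CV, DEFAULT_CV)
        assert ci.lower == pytest.approx(0.643288, abs=5e-6)
        assert ci.upper == pytest.approx(1.554515, abs=5e-6)
        assert ci.t == 1.96

    def test_zero_variance_degenerates_to_point(self):
        ci = ratio_confidence_interval(80.0, 60.0, 0.0, 0.0)
        assert ci.lower == ci.upper == pytest.approx(0.75)

    @given(
        k=st.floats(0.02, 0.35),
        w=st.floats(0.2, 5.0),
    )
    def test_symmetric_product_identity(self, k, w):
        """For rho=0, c1=c2: lower*upper = (x2/x1)^2 to machine precision."""
        ci = ratio_confidence_interval(1.0, w, k, k)
        assert ci.lower * ci.upper == pytest.approx(w * w, rel=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.3, -0.5, 0.9])
    def test_general_contains_observed_ratio(self, rho):
        ci = ratio_confidence_interval(100.0, 70.0, 0.12, 0.18, rho=rho)
        assert ci.lower < 0.7 < ci.upper

    def test_general_reduces_to_simplified_form(self):
        """With rho=0, c1=c2=k the general CI equals the threshold formulas."""
        for k in np.linspace(0.02, 0.3, 15):
            ci = ratio_confidence_interval(1.0, 1.0, k, k, rho=0.0)
            ts = symmetric_thresholds(k)
            assert abs(ci.lower - ts.lower_ratio) < 1e-12
            assert abs(ci.upper - ts.upper_ratio) < 1e-12

    def test_large_follow_up_cv_raises(self):
        with pytest.raises(ValueError, match="denominator"):
            ratio_confidence_interval(1.0, 1.0, 0.1, 0.6)

    def test_non_positive_volume_raises(self):
        with pytest.raises(ValueError, match="positive"):
            ratio_confidence_interval(0.0, 1.0, 0.1, 0.1)


class TestSymmetricThresholds:
    @pytest.mark.parametrize(
        "k, lower_pct, upper_pct",
        [
            (0.3 / 1.96, -35, 55),  # ~15% SD: the clinical volumetry pair
            (0.05, -13, 15),
            (0.1 / 1.96, -13, 15),
        ],
    )
    def test_integer_percent_pairs(self, k, lower_pct, upper_pct):
        ts = symmetric_thresholds(k)
        assert (ts.lower_pct, ts.upper_pct) == (lower_pct, upper_pct)

    def test_ten_percent_cv_lower_threshold(self):
        assert symmetric_thresholds(0.10).lower_pct == -25

    def test_exact_ratios(self, default_thresholds):
        assert default_thresholds.lower_ratio == pytest.approx(0.6432876, abs=1e-6)
        assert default_thresholds.upper_ratio == pytest.approx(1.5545146, abs=1e-6)

    @given(k=st.floats(0.011, 0.349))
    def test_reciprocity(self, k):
        ts = symmetric_thresholds(k)
        assert abs(ts.lower_ratio * ts.upper_ratio - 1.0) < 1e-12

    def test_small_cv_limit(self):
        ts = symmetric_thresholds(1e-6)
        assert (ts.lower_pct, ts.upper_pct) == (0, 0)
        assert ts.lower_ratio == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("k", [0.0, -0.1, 0.6])
    def test_invalid_cv_raises(self, k):
        with pytest.raises(ValueError):
            symmetric_thresholds(k)

    def test_non_default_level_uses_exact_quantile(self):
        ts = symmetric_thresholds(DEFAULT_CV, level=0.90)
        assert normal_quantile(0.90) == pytest.approx(1.6448536, abs=1e-6)
        # narrower level, narrower band
        assert ts.upper_ratio < symmetric_thresholds(DEFAULT_CV).upper_ratio


class TestRejectionRegion:
    def test_ci_exclusion_matches_threshold_band(self, default_thresholds):
        """{w : 1 not in CI(w)} is exactly {w < w_L or w > w_U}."""
        k = DEFAULT_CV
        for w in np.linspace(0.4, 1.8, 281):
            ci = ratio_confidence_interval(1.0, w, k, k)
            excluded = not ci.contains(1.0)
            outside = (
                w < default_thresholds.lower_ratio
                or w > default_thresholds.upper_ratio
            )
            assert excluded == outside, f"mismatch at w={w}"


class TestPValue:
    def test_unity_ratio_gives_p_one(self):
        assert pvalue_no_change(1.0, DEFAULT_CV) == pytest.approx(1.0)

    def test_alpha_at_critical_ratios(self, default_thresholds):
        for w in (default_thresholds.lower_ratio, default_thresholds.upper_ratio):
            assert pvalue_no_change(w, DEFAULT_CV) == pytest.approx(0.05, abs=1e-3)

    def test_half_ratio_is_significant(self):
        assert pvalue_no_change(0.5, DEFAULT_CV) < 0.05

    def test_monotone_decreasing_away_from_one(self):
        grid_up = np.linspace(1.0, 1.8, 81)
        grid_down = np.linspace(1.0, 0.4, 61)
        for grid in (grid_up, grid_down):
            p = [pvalue_no_change(w, DEFAULT_CV) for w in grid]
            assert all(a > b for a, b in zip(p, p[1:]))


class TestPower:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.5, 0.875), (0.8, 0.16), (1.3, 0.206), (1.8, 0.75)],
    )
    def test_anchor_values(self, r, expected, default_thresholds):
        power = power_at_ratio(r, DEFAULT_CV, default_thresholds)
        assert power == pytest.approx(expected, abs=3e-3)

    def test_size_at_null(self, default_thresholds):
        assert power_at_ratio(1.0, DEFAULT_CV, default_thresholds) == pytest.approx(
            0.05, abs=5e-3
        )

    def test_half_power_at_critical_ratios(self, default_thresholds):
        for r in (default_thresholds.lower_ratio, default_thresholds.upper_ratio):
            assert power_at_ratio(r, DEFAULT_CV, default_thresholds) == pytest.approx(
                0.5, abs=5e-3
            )

    def test_monotone_away_from_one(self, default_thresholds):
        up = [power_at_ratio(r, DEFAULT_CV, default_thresholds) for r in np.linspace(1.0, 1.8, 81)]
        down = [power_at_ratio(r, DEFAULT_CV, default_thresholds) for r in np.linspace(1.0, 0.4, 61)]
        for seq in (up, down):
            assert all(b > a for a, b in zip(seq, seq[1:]))


class TestClassification:
    @pytest.mark.parametrize(
        "w, expected",
        [
            (0.60, "decrease"),
            (1.0, "no-change"),
            (1.55, "no-change"),  # boundary is non-rejection
            (0.65, "no-change"),
            (1.56, "increase"),
        ],
    )
    def test_categories(self, w, expected, default_thresholds):
        assert classify_change(w, default_thresholds) == expected

    def test_non_positive_ratio_raises(self, default_thresholds):
        with pytest.raises(ValueError):
            classify_change(0.0, default_thresholds)

    def test_no_change_test_consistency(self):
        """Rejection agrees with p < alpha across a ratio grid."""
        for w in np.linspace(0.45, 1.75, 53):
            result = no_change_test(w, DEFAULT_CV)
            assert result.rejected == (result.p_value < 0.05)
            assert result.rejected == (result.category != "no-change")
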