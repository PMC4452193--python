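"""Bland-Altman statistics, the agreement index, and mixed-effects models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octlayers import (
    agreement_index,
    aggregate_agreement_index,
    bland_altman,
    compare_groups,
    fit_rate_of_change,
    modified_bland_altman,
    simulate_longitudinal_cohort,
    upper_loa_from_symmetry,
)
from octlayers.exceptions import InsufficientDataError, ValidationError

positive = st.floats(min_value=1.0, max_value=500.0)


class TestBlandAltman:
    def test_identical_pairs_collapse_loa(self):
        x = np.array([50.0, 60.0, 70.0, 80.0])
        with pytest.warns(UserWarning, match="collapse"):
            res = bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_monte_carlo_recovery_of_known_difference(self, rng):
        """Differences ~ N(0.5, 1), n = 10^4: mean within 0.03, LOA within
        0.05 of (-1.46, 2.46)."""
        n = 10_000
        a = rng.normal(60.0, 5.0, n)
        b = a + rng.normal(0.5, 1.0, n)
        res = bland_altman(a, b)
        assert res.mean_diff == pytest.approx(0.5, abs=0.03)
        assert res.loa_lower == pytest.approx(0.5 - 1.96, abs=0.05)
        assert res.loa_upper == pytest.approx(0.5 + 1.96, abs=0.05)
        # CI widths behave like t-based SEs
        assert res.ci_mean[0] < res.mean_diff < res.ci_mean[1]
        width = res.ci_mean[1] - res.ci_mean[0]
        assert width == pytest.approx(2 * 1.96 / np.sqrt(n), rel=0.1)

    def test_loa_symmetry_invariant(self, rng):
        a = rng.normal(60, 5, 50)
        b = a + rng.normal(1.0, 2.0, 50)
        res = bland_altman(a, b)
        assert (res.loa_upper - res.mean_diff) == pytest.approx(
            res.mean_diff - res.loa_lower, abs=1e-9)

    def test_swapping_devices_negates_and_mirrors(self, rng):
        a = rng.normal(60, 5, 40)
        b = a + rng.normal(1.0, 2.0, 40)
        r1 = bland_altman(a, b)
        r2 = bland_altman(b, a)
        assert r2.mean_diff == pytest.approx(-r1.mean_diff)
        assert r2.loa_lower == pytest.approx(-r1.loa_upper)
        assert r2.loa_upper == pytest.approx(-r1.loa_lower)

    def test_symmetry_reproduces_reported_upper_limits(self):
        """From a table's mean difference and lower LOA, symmetry pins the
        upper LOA (worked examples: 3.17 and 8.22 um)."""
        assert upper_loa_from_symmetry(0.26, -2.65) == pytest.approx(3.17)
        assert upper_loa_from_symmetry(4.71, 1.20) == pytest.approx(8.22)


class TestAgreementIndex:
    def test_identity_and_total_discordance(self):
        assert agreement_index(50.0, 50.0) == 1.0
        assert agreement_index(30.0, 10.0) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(a=positive, b=positive)
    def test_bounded_swap_and_scale_invariant(self, a, b):
        v = agreement_index(a, b)
        assert v <= 1.0
        assert agreement_index(b, a) == pytest.approx(v, abs=1e-12)
        assert agreement_index(3.7 * a, 3.7 * b) == pytest.approx(v, rel=1e-9)
        if a == b:
            assert v == 1.0

    def test_equal_iff_one(self):
        assert agreement_index(42.0, 42.0) == 1.0
        assert agreement_index(42.0, 42.1) < 1.0

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValidationError):
            agreement_index(0.0, 0.0)

    def test_folded_normal_expectation(self, rng):
        """mu=0, sigma=1 differences on a 65 um base: mean index ~
        1 - sigma*sqrt(2/pi)/65."""
        n = 10_000
        a = np.full(n, 65.0)
        b = a + rng.normal(0.0, 1.0, n)
        res = aggregate_agreement_index(a, b, "GCIP")
        expected = 1.0 - np.sqrt(2 / np.pi) / 65.0
        assert res.mean == pytest.approx(expected, abs=3 * res.sd / np.sqrt(n) + 1e-4)


class TestModifiedBlandAltman:
    def test_zero_changes_collapse(self):
        with pytest.warns(UserWarning):
            res = modified_bland_altman([0.0] * 4, [0.0] * 4,
                                        ["s1", "s1", "s2", "s2"])
        assert res.mean_diff == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_mean_difference_of_reported_changes(self):
        """Per-device mean changes -0.54 / -0.60 give a 0.060 um mean
        difference of changes."""
        rng = np.random.default_rng(0)
        n = 40
        spread = rng.normal(0.0, 1.0, n)
        spread -= spread.mean()
        d_cirrus = -0.60 + spread
        d_spectralis = -0.54 + spread
        subj = np.repeat([f"s{i}" for i in range(n // 2)], 2)
        res = modified_bland_altman(d_cirrus, d_spectralis, subj)
        assert res.mean_diff == pytest.approx(0.060, abs=1e-12)

    def test_variance_components_recovered(self, rng):
        """100 subjects x 2 eyes, between SD 0.5, within SD 1.0: the
        rebuilt total SD is within 10% of sqrt(1.25)."""
        n_subj = 100
        subj_effect = rng.normal(0, 0.5, n_subj)
        d = (subj_effect[:, None] + rng.normal(0, 1.0, (n_subj, 2))).ravel()
        subj = np.repeat(np.arange(n_subj), 2)
        res = modified_bland_altman(np.zeros_like(d), d, subj)
        assert res.sd_diff == pytest.approx(np.sqrt(1.25), rel=0.10)
        assert res.n_subjects == n_subj

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            modified_bland_altman([0.1, 0.2, 0.3], [0.2, 0.3, 0.1],
                                  ["s1", "s1", "s1"])


class TestRateOfChange:
    def test_noise_free_slope_recovered_exactly(self):
        df = simulate_longitudinal_cohort(
            30, slope_um_per_year=-0.66, intercept_sd_um=5.0,
            residual_sd_um=0.0, seed=3, devices=("cirrus",), layers=("GCIP",))
        res = fit_rate_of_change(df, "cirrus", "GCIP")
        assert res.slope == pytest.approx(-0.66, abs=1e-6)
        assert res.ci[0] <= res.slope <= res.ci[1]

    def test_slope_ci_covers_truth(self):
        df = simulate_longitudinal_cohort(200, slope_um_per_year=-0.59,
                                          seed=21, layers=("GCIP",))
        res = fit_rate_of_change(df, "spectralis", "GCIP")
        assert res.ci[0] <= -0.59 <= res.ci[1]
        assert res.n_subjects == 200

    def test_no_time_variation_rejected(self):
        df = simulate_longitudinal_cohort(10, seed=0, layers=("GCIP",))
        df = df[df["years"] == 0.0]
        with pytest.raises((InsufficientDataError, ValidationError)):
            fit_rate_of_change(df, "spectralis", "GCIP")


@pytest.fixture(scope="module")
def cross_sectional():
    df = simulate_longitudinal_cohort(
        150, seed=9, visit_years=(0.0, 1.0), layers=("GCIP",),
        ms_deficit_um=-9.47)
    return df[df["years"] == 0.0]


class TestGroupComparison:
    def test_deficit_recovered_within_ci(self, cross_sectional):
        res = compare_groups(cross_sectional, "spectralis", "GCIP")
        assert res.ci[0] <= -9.47 <= res.ci[1]
        assert res.p_value < 0.05

    def test_identical_groups_noise_free_give_zero(self):
        df = simulate_longitudinal_cohort(
            20, seed=4, visit_years=(0.0, 1.0), layers=("GCIP",),
            residual_sd_um=0.0, ms_deficit_um=0.0, intercept_sd_um=0.0)
        df = df[df["years"] == 0.0]
        res = compare_groups(df, "spectralis", "GCIP")
        assert res.difference == pytest.approx(0.0, abs=1e-6)

    def test_scaling_thickness_scales_difference(self, cross_sectional):
        r1 = compare_groups(cross_sectional, "spectralis", "GCIP")
        doubled = cross_sectional.copy()
        doubled["GCIP"] = 2.0 * doubled["GCIP"]
        r2 = compare_groups(doubled, "spectralis", "GCIP")
        assert r2.difference == pytest.approx(2.0 * r1.difference, rel=1e-6)

    def test_single_group_rejected(self, cross_sectional):
        hc_only = cross_sectional[cross_sectional["group"] == "HC"]
        with pytest.raises(InsufficientDataError):
            compare_groups(hc_only, "spectralis", "GCIP")
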