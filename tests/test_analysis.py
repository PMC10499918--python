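"""Tilt averaging, TS-length regression, RFI, allometry, species comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pykrm import (
    S_COLIAS,
    T_MEDITERRANEUS,
    TiltDistribution,
    TSLengthModel,
    allometry_test,
    compare_species_morphometrics,
    fit_ts_length,
    generate_cohort,
    relative_frequency_response,
    tilt_averaged_sigma,
)
from pykrm.exceptions import DomainError, InsufficientDataError
from pykrm.krm import BackscatterGrid


def toy_grid(theta, sigma_by_theta):
    """Single-frequency grid with prescribed sigma_bs per tilt node."""
    theta = np.asarray(theta, float)
    sig = np.asarray(sigma_by_theta, float)
    return BackscatterGrid(
        f_hz=np.array([38e3]),
        theta_deg=theta,
        scattering_length=np.sqrt(sig)[None, :].astype(complex),
        c_w=1509.0,
        c_fb=1570.0,
    )


class TestTiltAveraging:
    def test_constant_sigma_is_identity(self):
        theta = np.arange(65.0, 116.0, 1.0)
        grid = toy_grid(theta, np.full_like(theta, 3.7e-5))
        for dist in (TiltDistribution(90, 5), TiltDistribution(101, 12)):
            assert tilt_averaged_sigma(grid, dist)[0] == pytest.approx(3.7e-5)

    def test_delta_limit_picks_value_at_mean(self):
        theta = np.arange(65.0, 116.0, 1.0)
        sig = 1e-5 * (1 + 0.5 * np.sin(theta / 7))
        grid = toy_grid(theta, sig)
        out = tilt_averaged_sigma(grid, TiltDistribution(93.0, 0.001))
        assert out[0] == pytest.approx(sig[theta == 93.0][0], rel=1e-12)

    def test_two_point_toy_grid_matches_brute_force(self):
        # explicit truncated-Gaussian weights recomputed by hand
        theta = np.array([90.0, 100.0])
        sig = np.array([2e-5, 1e-5])
        mu, sd = 95.0, 6.0
        w = stats.norm.pdf(theta, mu, sd)
        expected = float(np.sum(w * sig) / np.sum(w))
        grid = toy_grid(theta, sig)
        out = tilt_averaged_sigma(grid, TiltDistribution(mu, sd))
        assert out[0] == pytest.approx(expected, rel=1e-12)

    def test_nodes_outside_support_get_zero_weight(self):
        theta = np.array([60.0, 90.0, 120.0])  # only 90 inside [65, 115]
        w = TiltDistribution(90, 20).weights(theta)
        assert w[0] == 0.0 and w[2] == 0.0 and w[1] == pytest.approx(1.0)

    def test_no_nodes_in_support_raises(self):
        with pytest.raises(DomainError):
            TiltDistribution(90, 10).weights(np.array([40.0, 50.0]))

    @given(st.floats(70, 110), st.floats(0.5, 25))
    @settings(max_examples=30, deadline=None)
    def test_average_bounded_and_monotone(self, mu, sd):
        theta = np.arange(65.0, 116.0, 1.0)
        rng = np.random.default_rng(7)
        sig_a = rng.uniform(1e-6, 1e-4, theta.size)
        sig_b = sig_a * rng.uniform(0.0, 1.0, theta.size)  # sig_b <= sig_a
        dist = TiltDistribution(mu, sd)
        avg_a = tilt_averaged_sigma(toy_grid(theta, sig_a), dist)[0]
        avg_b = tilt_averaged_sigma(toy_grid(theta, sig_b), dist)[0]
        assert sig_a.min() - 1e-20 <= avg_a <= sig_a.max() + 1e-20
        assert avg_b <= avg_a


class TestTSLengthRegression:
    def test_noiseless_line_recovered_exactly(self):
        tl = np.linspace(11.0, 23.0, 12)
        ts = 20 * np.log10(tl) - 64.4
        fit = fit_ts_length(zip(tl, ts), fixed_slope=20.0)
        assert fit.slope == pytest.approx(20.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-64.4, abs=1e-9)
        assert fit.b20 == pytest.approx(-64.4, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        # free and fixed fits coincide on exactly slope-20 data
        assert fit.predict(15.0) == pytest.approx(fit.predict_fixed(15.0), abs=1e-9)

    def test_prediction_on_fitted_line(self):
        tl = np.linspace(11.0, 23.0, 12)
        fit = fit_ts_length(zip(tl, 20 * np.log10(tl) - 64.4))
        assert fit.predict(15.0) == pytest.approx(
            20 * np.log10(15.0) - 64.4, abs=1e-9
        )
        assert float(fit.predict(15.0)) == pytest.approx(-40.88, abs=0.005)

    def test_flat_data_gives_zero_slope_and_r2(self):
        tl = np.linspace(11.0, 23.0, 10)
        fit = TSLengthModel(tl, np.full(10, -45.0)).fit()
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_b20_is_mean_offset(self):
        rng = np.random.default_rng(3)
        tl = rng.uniform(11, 30, 40)
        ts = 20 * np.log10(tl) - 66.0 + rng.normal(0, 0.5, 40)
        fit = TSLengthModel(tl, ts).fit(fixed_slope=20.0)
        assert fit.b20 == pytest.approx(
            float(np.mean(ts - 20 * np.log10(tl))), rel=1e-12
        )

    def test_insufficient_data_and_domain_errors(self):
        with pytest.raises(InsufficientDataError):
            TSLengthModel([12.0, 14.0], [-45.0, -44.0]).fit()
        with pytest.raises(DomainError):
            TSLengthModel([12.0, -1.0, 15.0], [-45.0, -44.0, -43.0])

    def test_summary_mentions_both_intercepts(self):
        tl = np.linspace(11.0, 23.0, 12)
        fit = fit_ts_length(zip(tl, 20 * np.log10(tl) - 64.4), fixed_slope=20.0)
        text = fit.summary()
        assert "-64.40" in text and "b20" in text


class TestRelativeFrequencyResponse:
    def test_flat_spectrum_gives_unit_ratios(self):
        curve = relative_frequency_response(np.array([[2e-5] * 4]))
        np.testing.assert_allclose(curve.mean, 1.0)

    def test_reference_ratio_is_exactly_one(self):
        rng = np.random.default_rng(11)
        sig = rng.uniform(1e-6, 1e-4, size=(20, 4))
        curve = relative_frequency_response(sig)
        np.testing.assert_array_equal(curve.per_fish[:, 0], 1.0)
        assert curve.mean[0] == 1.0

    def test_single_fish_direct_division(self):
        sig = np.array([[2e-5, 7e-6, 4e-6, 4e-6]])
        curve = relative_frequency_response(sig)
        np.testing.assert_allclose(curve.mean, [1.0, 0.35, 0.20, 0.20])

    def test_zero_reference_sigma_rejected(self):
        with pytest.raises(DomainError):
            relative_frequency_response(np.array([[0.0, 1e-6, 1e-6, 1e-6]]))


class TestAllometry:
    def test_isometric_data(self):
        tl = np.linspace(11, 30, 15)
        res = allometry_test(3.1 * tl**2, tl)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_allometric_exponent_recovered_exactly(self):
        tl = np.linspace(11, 30, 15)
        res = allometry_test(0.8 * tl**2.69, tl)
        assert res.slope == pytest.approx(2.69, abs=1e-9)
        assert res.p_value < 1e-6

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            allometry_test([100.0, 200.0], [12.0, 15.0])


class TestSpeciesComparison:
    def test_identical_cohorts_show_no_difference(self):
        cohort = generate_cohort(T_MEDITERRANEUS, 12, seed=5)
        table = compare_species_morphometrics(cohort, list(cohort))
        np.testing.assert_allclose(table.t.to_numpy(), 0.0, atol=1e-10)
        np.testing.assert_allclose(table.p_value.to_numpy(), 1.0, atol=1e-10)

    def test_forced_separation_is_significant(self):
        cohort = generate_cohort(T_MEDITERRANEUS, 15, seed=5)
        shifted = []
        for f in cohort:
            b = f.bladder
            grown = type(b)(b.u, b.z_upper + 20.0, b.z_lower - 20.0, b.w)
            shifted.append(
                type(f)(
                    species=f.species,
                    total_length_cm=f.total_length_cm,
                    body=None,
                    bladder=grown,
                )
            )
        table = compare_species_morphometrics(cohort, shifted).set_index("measure")
        assert table.loc["sbh", "p_value"] < 1e-3

    def test_species_templates_preserve_published_contrast(self):
        a = generate_cohort(T_MEDITERRANEUS, 25, tl_range_cm=(11.2, 23.1), seed=1)
        b = generate_cohort(S_COLIAS, 25, tl_range_cm=(11.2, 23.1), seed=2)
        table = compare_species_morphometrics(a, b).set_index("measure")
        # horse mackerel: longer, narrower, flatter bladder than chub mackerel
        assert table.loc["sbl", "mean_resid_diff"] > 0
        assert table.loc["sbw", "mean_resid_diff"] < 0
        assert table.loc["sbh", "mean_resid_diff"] < 0
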