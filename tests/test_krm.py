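"""KRM engine: reflection coefficients, coherent sum, grids, slice effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pykrm import (
    KRM,
    MaterialSet,
    krm_grid,
    krm_scattering_length,
    reflection_coefficient,
    slice_sensitivity,
    spectrum_max_diff,
)
from pykrm.exceptions import (
    DeflatedSpecimenError,
    DomainError,
    ValidityRangeError,
)
from pykrm.io import spectrum_frame
from pykrm.krm import lambda_over_10_mm
from pykrm.shapes import FishModel, ShapeProfile


class TestReflectionCoefficient:
    def test_zero_for_equal_impedances(self):
        assert reflection_coefficient(1026, 1509, 513, 3018) == pytest.approx(0.0)

    def test_water_to_body(self):
        # (1070*1570 - 1026*1509)/(1070*1570 + 1026*1509)
        assert reflection_coefficient(1026, 1509, 1070, 1570) == pytest.approx(
            0.0408, abs=5e-4
        )

    def test_body_to_swimbladder(self):
        assert reflection_coefficient(1070, 1570, 1.24, 345) == pytest.approx(
            -0.99949, abs=5e-5
        )

    @given(
        st.floats(100, 2000), st.floats(300, 2000),
        st.floats(1, 2000), st.floats(300, 2000),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_and_bounded(self, r1, c1, r2, c2):
        fwd = reflection_coefficient(r1, c1, r2, c2)
        assert -1.0 < fwd < 1.0
        assert fwd == pytest.approx(-reflection_coefficient(r2, c2, r1, c1))

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            reflection_coefficient(0.0, 1509, 1070, 1570)


class TestScatteringLength:
    def test_zero_contrast_gives_no_echo(self, symmetric_fish):
        m = MaterialSet(
            c_fb=1509.0, c_sb=1509.0, rho_fb=1026.0, rho_sb=1026.0
        )
        ts = KRM(symmetric_fish, m, du_mm=1.0).ts(38e3, 90.0)
        assert ts[0] < -100.0
        grid = krm_grid(symmetric_fish, m, [38e3, 120e3], [80.0, 90.0, 100.0])
        assert np.all(grid.sigma_bs < 1e-10)

    @pytest.mark.parametrize("delta", [5.0, 12.5, 25.0])
    def test_mirror_symmetry_for_fore_aft_symmetric_fish(
        self, symmetric_fish, mats, delta
    ):
        k = KRM(symmetric_fish, mats, du_mm=1.0)
        up = k.ts(np.array([38e3, 200e3]), 90.0 + delta)
        dn = k.ts(np.array([38e3, 200e3]), 90.0 - delta)
        np.testing.assert_allclose(up, dn, atol=1e-9)

    def test_gas_sphere_matches_modal_series(self, gas_sphere_5mm, mats):
        from pykrm import sphere_modal_ts

        du = lambda_over_10_mm(mats.c_w)
        ts_krm = KRM(gas_sphere_5mm, mats, du_mm=du).ts(38e3, 90.0, part="bladder")
        ts_modal = sphere_modal_ts(
            0.005, (mats.c_sb, mats.rho_sb), (mats.c_w, mats.rho_w), 38e3
        )
        assert abs(float(ts_krm[0]) - ts_modal) < 1.5

    def test_theta_outside_validity_range(self, symmetric_fish, mats):
        with pytest.raises(ValidityRangeError):
            krm_scattering_length(symmetric_fish, mats, 38e3, 60.0)
        with pytest.raises(ValidityRangeError):
            krm_scattering_length(symmetric_fish, mats, 38e3, 120.0)

    def test_deflated_specimen_rejected(self, mats):
        u = np.linspace(0, 100, 101)
        body = ShapeProfile(u, 5 + 0 * u, -5 + 0 * u, 4 + 0 * u)
        fish = FishModel("deflated", 10.0, body=body)
        with pytest.raises(DeflatedSpecimenError):
            krm_scattering_length(fish, mats, 38e3, 90.0)

    def test_nonpositive_frequency_rejected(self, symmetric_fish, mats):
        with pytest.raises(DomainError):
            krm_scattering_length(symmetric_fish, mats, -38e3, 90.0)

    def test_conversion_identities_hold_per_cell(self, symmetric_fish, mats):
        grid = krm_grid(symmetric_fish, mats, [38e3, 70e3], [85.0, 90.0])
        np.testing.assert_array_equal(
            grid.sigma_bs, np.abs(grid.scattering_length) ** 2
        )
        np.testing.assert_array_equal(grid.ts, 10 * np.log10(grid.sigma_bs))
        # the sigma = 4 pi sigma_bs convention gives the same TS
        np.testing.assert_allclose(
            grid.ts, 10 * np.log10(4 * np.pi * grid.sigma_bs / (4 * np.pi))
        )


class TestGrid:
    def test_single_cell_equals_scalar_call(self, symmetric_fish, mats):
        grid = krm_grid(symmetric_fish, mats, [38e3], [90.0])
        scalar = krm_scattering_length(symmetric_fish, mats, 38e3, 90.0)
        assert grid.scattering_length[0, 0] == scalar

    def test_survey_grid_is_finite_everywhere(self, symmetric_fish, mats):
        f = np.array([38e3, 70e3, 120e3, 200e3])
        theta = np.arange(65.0, 116.0, 1.0)
        grid = krm_grid(symmetric_fish, mats, f, theta)
        assert np.all(np.isfinite(grid.ts))
        assert grid.ts.shape == (4, 51)

    def test_halved_slice_changes_little(self, symmetric_fish, mats):
        t1 = KRM(symmetric_fish, mats, du_mm=1.0).ts(38e3, 90.0)
        t2 = KRM(symmetric_fish, mats, du_mm=0.5).ts(38e3, 90.0)
        assert abs(float(t1[0]) - float(t2[0])) < 0.2

    def test_long_format_export_columns(self, symmetric_fish, mats):
        df = krm_grid(symmetric_fish, mats, [38e3], [90.0, 91.0]).to_dataframe()
        assert list(df.columns) == ["f_hz", "theta_deg", "ts_db", "sigma_bs_m2"]
        assert len(df) == 2


class TestSliceSensitivity:
    def test_identical_thickness_gives_zero(self, benchmark_spheroid, mats):
        f = np.arange(38e3, 201e3, 10e3)
        res = slice_sensitivity(
            benchmark_spheroid, mats, [1.0, 1.0], f, 90.0, part="bladder"
        )
        assert res.pairwise_max_dts.max_abs_dts_db.iloc[0] == 0.0

    def test_smooth_spheroid_1mm_close_to_lambda10(self, benchmark_spheroid, mats):
        f = np.arange(38e3, 201e3, 2e3)
        res = slice_sensitivity(
            benchmark_spheroid, mats, [1.0, "lambda/10"], f, 90.0, part="bladder"
        )
        assert res.max_dts("1 mm", "lambda/10") < 0.2

    def test_convergence_toward_refined_slices(self, benchmark_spheroid, mats):
        # |TS(du) - TS(du/2)| shrinks monotonically as du -> lambda/10
        for f in (38e3, 200e3):
            diffs = []
            for du in (4.0, 2.0, 1.0, 0.5):
                ka = KRM(benchmark_spheroid, mats, du_mm=du).ts(f, 90.0, "bladder")
                kb = KRM(benchmark_spheroid, mats, du_mm=du / 2).ts(f, 90.0, "bladder")
                diffs.append(abs(float(ka[0]) - float(kb[0])))
            assert diffs == sorted(diffs, reverse=True)

    def test_needs_two_thicknesses(self, benchmark_spheroid, mats):
        with pytest.raises(DomainError):
            slice_sensitivity(
                benchmark_spheroid, mats, [1.0], np.array([38e3]), 90.0
            )


class TestSpectrumMaxDiff:
    def test_identical_spectra(self):
        f = np.arange(38e3, 201e3, 1e3)
        a = spectrum_frame(f, np.sin(f / 1e4))
        d = spectrum_max_diff(a, a, (38e3, 200e3))
        assert d.max_abs_dts_db == 0.0

    def test_constant_offset(self):
        f = np.arange(38e3, 201e3, 1e3)
        a = spectrum_frame(f, np.sin(f / 1e4))
        b = spectrum_frame(f, np.sin(f / 1e4) + 0.5)
        d = spectrum_max_diff(a, b, (38e3, 200e3))
        assert d.max_abs_dts_db == pytest.approx(0.5)

    def test_coarse_grid_interpolated_onto_fine(self):
        f_fine = np.arange(38e3, 201e3, 1e3)
        f_coarse = np.arange(38e3, 201e3, 8e3)
        a = spectrum_frame(f_fine, 0.01 * f_fine / 1e3)
        b = spectrum_frame(f_coarse, 0.01 * f_coarse / 1e3)  # same line
        d = spectrum_max_diff(a, b, (40e3, 190e3))
        assert d.max_abs_dts_db < 1e-9

    def test_rejects_non_overlapping_band(self):
        f = np.arange(38e3, 71e3, 1e3)
        a = spectrum_frame(f, f * 0.0)
        with pytest.raises(DomainError):
            spectrum_max_diff(a, a, (100e3, 200e3))
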