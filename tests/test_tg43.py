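"""TG-43 operators: exact normalizations, formula oracles, table statistics."""

import numpy as np
import pandas as pd
import pytest

from mxtdosim import (
    DepthDoseCurve,
    PolarDoseSamples,
    PolarProfile,
    anisotropy_function,
    azimuthal_ratios,
    compare_tables,
    dose_rate_constant,
    extract_depth_dose,
    generate_dose_grid,
    geometry_function_point,
    polar_samples_from_grid,
    radial_dose_function,
)

from conftest import make_analytic_params


class TestGeometryFunction:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (2.0, 0.25), (5.0, 0.04)])
    def test_point_source_values(self, r, expected):
        assert geometry_function_point(r) == pytest.approx(expected)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            geometry_function_point(0.0)


class TestDoseRateConstant:
    def test_per_current_convention(self):
        """The electronic-source convention: the reference dose rate per uA
        is Lambda itself (the reference device value passes through)."""
        assert dose_rate_constant(1104.28) == pytest.approx(1104.28)
        assert dose_rate_constant(0.0) == 0.0

    def test_classical_unit_harmonization(self):
        """60 cGy/h over S_K = 1 Gy cm^2/min = 6000 cGy cm^2/h -> 0.01 cm^-2."""
        assert dose_rate_constant(60.0, s_k=1.0, mode="classical") == pytest.approx(
            0.01
        )

    def test_classical_requires_positive_sk(self):
        with pytest.raises(ValueError):
            dose_rate_constant(60.0, s_k=0.0, mode="classical")


class TestRadialDoseFunction:
    def test_inverse_square_cancellation(self):
        radii = np.array([0.5, 1.0, 2.0, 3.7, 5.0])
        curve = DepthDoseCurve(radii, 100.0 / radii**2, "water")
        g = radial_dose_function(curve)
        np.testing.assert_allclose(g["g"], 1.0, atol=1e-12)

    def test_reference_device_point(self):
        """D(1) = 1.0, D(2) = 0.1175 gives g(2) = 0.47 (film-measured water
        value at 2 cm, input constructed by inverting the definition)."""
        curve = DepthDoseCurve([1.0, 2.0], [1.0, 0.1175], "water")
        g = radial_dose_function(curve)
        assert g.loc[g["r_cm"] == 2.0, "g"].iloc[0] == pytest.approx(0.47)

    def test_matches_direct_formula_on_random_profile(self):
        rng = np.random.default_rng(11)
        radii = np.sort(rng.uniform(0.5, 6.0, 40))
        radii[0] = 1.0  # ensure the reference radius is present
        radii = np.unique(radii)
        doses = rng.uniform(0.1, 50.0, radii.size)
        curve = DepthDoseCurve(radii, doses, "abs")
        g = radial_dose_function(curve)
        d0 = doses[radii == 1.0][0]
        expected = (doses / d0) * radii**2
        np.testing.assert_allclose(g["g"], expected, rtol=1e-14)

    def test_exact_normalization_at_r0(self):
        rng = np.random.default_rng(3)
        radii = np.array([0.7, 1.0, 1.9, 4.2])
        curve = DepthDoseCurve(radii, rng.uniform(1, 10, 4), "water")
        g = radial_dose_function(curve)
        assert float(g.loc[g["r_cm"] == 1.0, "g"].iloc[0]) == 1.0

    def test_interpolated_reference(self):
        """g is computable when no sample sits exactly at r0."""
        radii = np.array([0.8, 1.2, 2.0, 3.0])
        curve = DepthDoseCurve(radii, 100.0 / radii**2, "water")
        g = radial_dose_function(curve)
        np.testing.assert_allclose(g["g"], 1.0, rtol=5e-3)

    def test_missing_reference_coverage_rejected(self):
        curve = DepthDoseCurve([2.0, 3.0], [1.0, 0.5], "water")
        with pytest.raises(ValueError, match="r0"):
            radial_dose_function(curve)


class TestAnisotropyFunction:
    @staticmethod
    def samples_from(profile, radii, thetas):
        r, t = np.meshgrid(radii, thetas, indexing="ij")
        dose = profile(t.ravel()) / r.ravel() ** 2
        return PolarDoseSamples(
            r_cm=r.ravel(), theta_deg=t.ravel(), dose=dose,
            valid=np.ones(r.size, dtype=bool),
        )

    def test_isotropic_kernel_gives_unity(self):
        samples = self.samples_from(
            lambda t: np.ones_like(np.asarray(t, dtype=float)),
            [1.0, 2.0, 3.0],
            np.arange(0.0, 100.0, 10.0),
        )
        table = anisotropy_function(samples)
        np.testing.assert_allclose(table["F"], 1.0, atol=1e-12)

    def test_transverse_normalization_exact(self):
        samples = self.samples_from(
            PolarProfile(a=0.1, b=0.05), [1.0, 4.0], [0.0, 45.0, 90.0, 135.0]
        )
        table = anisotropy_function(samples)
        ref = table[table["theta_deg"] == 90.0]["F"]
        assert (ref == 1.0).all()

    def test_forward_enhancement_recovery_from_grid(self, source_spec):
        """A kernel with f(theta) = 1 + 0.16 cos^2(theta) yields far-field
        F(r, 0) near 1.16 after grid extraction."""
        params = make_analytic_params(polar=PolarProfile(a=0.0, b=0.16))
        grid = generate_dose_grid(source_spec, params, "water", (105, 105, 89))
        samples = polar_samples_from_grid(grid, [3.0, 4.0], [0.0, 30.0, 90.0])
        table = anisotropy_function(samples)
        forward = table[(table["theta_deg"] == 0.0)]["F"]
        np.testing.assert_allclose(forward, 1.16, atol=0.01)

    def test_missing_transverse_reference_masks_row(self):
        samples = PolarDoseSamples(
            r_cm=np.array([1.0, 1.0, 2.0, 2.0]),
            theta_deg=np.array([30.0, 90.0, 30.0, 60.0]),  # no 90 at r = 2
            dose=np.array([1.0, 1.0, 0.2, 0.25]),
            valid=np.ones(4, dtype=bool),
        )
        with pytest.warns(UserWarning, match="r = 2"):
            table = anisotropy_function(samples)
        row2 = table[table["r_cm"] == 2.0]
        assert not row2["valid"].any()
        assert row2["F"].isna().all()


class TestAzimuthalRatios:
    def test_reference_device_measurements(self):
        """The measured azimuthal doses reproduce the published ratios with
        maximum 1.06 at 150 deg."""
        doses = [(0.0, 100.0), (30.0, 104.0), (60.0, 105.0), (90.0, 101.0),
                 (120.0, 103.0), (150.0, 106.0), (180.0, 102.0)]
        res = azimuthal_ratios(doses)
        np.testing.assert_allclose(
            res.table["ratio"], [1.00, 1.04, 1.05, 1.01, 1.03, 1.06, 1.02]
        )
        assert res.max_ratio == pytest.approx(1.06)
        assert res.argmax_phi_deg == 150.0

    def test_constant_doses(self):
        res = azimuthal_ratios([(p, 5.0) for p in (0.0, 90.0, 180.0)])
        assert (res.table["ratio"] == 1.0).all()

    def test_order_independence(self):
        doses = [(150.0, 106.0), (0.0, 100.0), (60.0, 105.0)]
        res1 = azimuthal_ratios(doses)
        res2 = azimuthal_ratios(list(reversed(doses)))
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_duplicate_angles_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            azimuthal_ratios([(0.0, 1.0), (30.0, 1.1), (30.0, 1.2)])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="phi = 0"):
            azimuthal_ratios([(30.0, 1.0), (60.0, 1.1)])


class TestCompareTables:
    def test_identical_tables_ratio(self):
        s = pd.Series([1.0, 0.5, 0.2], index=[1.0, 2.0, 3.0])
        cmp = compare_tables(s, s.copy(), mode="ratio")
        assert cmp.mean == 1.0 and cmp.sd == 0.0 and cmp.max_abs == 1.0

    def test_self_difference_is_zero(self):
        s = pd.Series([0.3, 0.7], index=[1.0, 2.0])
        cmp = compare_tables(s, s.copy(), mode="difference")
        assert (cmp.values == 0.0).all()

    def test_difference_antisymmetry(self):
        rng = np.random.default_rng(5)
        idx = [1.0, 2.0, 3.0, 4.0]
        a = pd.Series(rng.uniform(0, 1, 4), index=idx)
        b = pd.Series(rng.uniform(0, 1, 4), index=idx)
        ab = compare_tables(a, b, mode="difference")
        ba = compare_tables(b, a, mode="difference")
        np.testing.assert_allclose(ab.values, -ba.values)
        assert ab.max_abs == ba.max_abs

    def test_reference_ratio_column_mean(self, fixture_tables):
        """Water/ABS Monte-Carlo g(r) ratio over all 22 radii averages 0.85."""
        t1 = fixture_tables.radial_dose.set_index("r_cm")
        cmp = compare_tables(t1["g_water_mc"], t1["g_abs_mc"], mode="ratio")
        assert cmp.mean == pytest.approx(0.85, abs=0.005)
        assert cmp.n == 22

    def test_reference_difference_max_location(self, fixture_tables):
        """ABS MC-film difference peaks at 0.12 at r = 4.8 cm."""
        t1 = fixture_tables.radial_dose.set_index("r_cm")
        cmp = compare_tables(t1["g_abs_mc"], t1["g_abs_ebt"], mode="difference")
        assert cmp.max_abs == pytest.approx(0.12, abs=1e-9)
        assert cmp.argmax == pytest.approx(4.8)

    def test_mismatched_point_sets_rejected(self):
        a = pd.Series([1.0, 2.0], index=[1.0, 2.0])
        b = pd.Series([1.0, 2.0], index=[1.0, 3.0])
        with pytest.raises(ValueError, match="point set"):
            compare_tables(a, b)

    def test_nan_masks_intersected(self):
        idx = [1.0, 2.0, 3.0]
        a = pd.Series([1.0, np.nan, 3.0], index=idx)
        b = pd.Series([1.0, 2.0, np.nan], index=idx)
        cmp = compare_tables(a, b, mode="difference")
        assert cmp.n == 1


class TestSeparability:
    """g(r) depends only on attenuation; F(r, theta) only on the polar
    profile — the kernel factorization is recovered by the extractors."""

    def test_g_independent_of_polar_profile(self, source_spec):
        radii = np.array([1.0, 2.0, 3.0])
        gs = []
        for polar in (PolarProfile(), PolarProfile(a=0.1, b=0.06)):
            params = make_analytic_params(polar=polar)
            grid = generate_dose_grid(source_spec, params, "water", (71, 71, 15))
            gs.append(radial_dose_function(extract_depth_dose(grid, radii))["g"])
        np.testing.assert_allclose(gs[0], gs[1], rtol=1e-9)

    def test_f_independent_of_attenuation(self, source_spec):
        fs = []
        for coeffs in ((0.1,), (0.5, 0.03)):
            params = make_analytic_params(
                water_coeffs=coeffs, polar=PolarProfile(a=0.05, b=0.1)
            )
            grid = generate_dose_grid(source_spec, params, "water", (71, 71, 71))
            samples = polar_samples_from_grid(grid, [1.5, 2.5], [0.0, 40.0, 90.0])
            fs.append(anisotropy_function(samples)["F"])
        np.testing.assert_allclose(fs[0], fs[1], rtol=5e-3)
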