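"""Synthetic dose-kernel generator: closed forms, symmetry, determinism."""

import numpy as np
import pytest

from mxtdosim import (
    DoseGrid,
    ExpPolyAttenuation,
    KernelParams,
    PolarProfile,
    SourceSpec,
    extract_depth_dose,
    generate_dose_grid,
    sample_film_plane,
    read_grid_csv,
    write_grid_csv,
)
from mxtdosim.uncertainty import transverse_ring_doses

from conftest import DEFAULT_SHAPE, make_analytic_params, make_trivial_params


class TestKernelClosedForms:
    def test_pure_inverse_square_ratio(self, source_spec):
        """With trivial attenuation/polar/ripple, D(2 cm)/D(1 cm) = 1/4."""
        grid = generate_dose_grid(
            source_spec, make_trivial_params(), "water", (61, 61, 21)
        )
        curve = extract_depth_dose(grid, [1.0, 2.0])
        assert curve.doses[1] / curve.doses[0] == pytest.approx(0.25, rel=1e-2)

    def test_single_exponential_g_ratio(self, source_spec):
        """A(r) = exp(-0.2 r): the g-style ratio D(5)*25/D(1) is exp(-0.8)."""
        params = make_analytic_params(water_coeffs=(0.2,), abs_coeffs=(0.2,),
                                      abs_scale=1.0, polar=PolarProfile())
        grid = generate_dose_grid(source_spec, params, "water", DEFAULT_SHAPE)
        curve = extract_depth_dose(grid, [1.0, 5.0])
        g_ratio = (curve.doses[1] * 25.0) / (curve.doses[0] * 1.0)
        assert g_ratio == pytest.approx(np.exp(-0.8), rel=1e-2)

    def test_inverse_square_times_r2_constant(self, source_spec):
        """Normalization invariant: D * r^2 constant on the transverse axis."""
        grid = generate_dose_grid(
            source_spec, make_trivial_params(), "water", (81, 81, 21)
        )
        radii = np.array([0.6, 1.0, 1.7, 2.5, 3.4])
        curve = extract_depth_dose(grid, radii)
        products = curve.doses * radii**2
        assert np.ptp(products) / products.mean() < 2e-2

    def test_reference_normalization(self, source_spec):
        """Transverse water dose at 1 cm equals the configured reference."""
        params = make_analytic_params(reference_dose_rate=1234.5)
        grid = generate_dose_grid(source_spec, params, "water", (41, 41, 21))
        dose = extract_depth_dose(grid, [1.0]).doses[0]
        assert dose == pytest.approx(1234.5, rel=5e-3)


class TestGeneration:
    def test_determinism_bit_identical(self, source_spec):
        params = make_trivial_params(noise_sd=0.01, seed=42)
        g1 = generate_dose_grid(source_spec, params, "water", (31, 31, 15))
        g2 = generate_dose_grid(source_spec, params, "water", (31, 31, 15))
        assert np.array_equal(g1.values, g2.values, equal_nan=True)

    def test_media_noise_streams_differ(self, source_spec):
        params = make_trivial_params(noise_sd=0.01, seed=42)
        gw = generate_dose_grid(source_spec, params, "water", (31, 31, 15))
        ga = generate_dose_grid(source_spec, params, "abs", (31, 31, 15))
        with np.errstate(invalid="ignore"):
            assert not np.allclose(gw.values, ga.values, equal_nan=True)

    def test_source_voxel_flagged_unusable(self, source_spec):
        grid = generate_dose_grid(
            source_spec, make_trivial_params(), "water", (21, 21, 21)
        )
        assert grid.source_voxel == (10, 10, 10)
        assert np.isnan(grid.values[10, 10, 10])
        finite = np.delete(grid.values.ravel(), np.ravel_multi_index((10, 10, 10),
                                                                     (21, 21, 21)))
        assert np.all(np.isfinite(finite)) and np.all(finite >= 0)

    def test_unknown_medium_rejected(self, source_spec):
        with pytest.raises(ValueError, match="unknown medium"):
            generate_dose_grid(source_spec, make_trivial_params(), "pmma",
                               (11, 11, 11))

    def test_seed_required_with_noise(self, source_spec):
        params = make_trivial_params(noise_sd=0.01, seed=None)
        with pytest.raises(ValueError, match="seed"):
            generate_dose_grid(source_spec, params, "water", (11, 11, 11))

    def test_off_centre_source_origin(self):
        spec = SourceSpec(source_origin_cm=(0.5, 0.0, -0.3))
        grid = generate_dose_grid(spec, make_trivial_params(), "water", (41, 41, 41))
        # coordinates stay source-centred: the offset shifts the grid box,
        # so the box is asymmetric but the dose stays symmetric about 0
        assert grid.extent_cm[0] == pytest.approx((-2.5, 1.5))
        d1 = grid.interpolate([[1.0, 0.0, 0.0]])[0]
        d2 = grid.interpolate([[-1.0, 0.0, 0.0]])[0]
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_source_origin_outside_grid_rejected(self):
        spec = SourceSpec(source_origin_cm=(10.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="outside the grid"):
            generate_dose_grid(spec, make_trivial_params(), "water", (21, 21, 21))

    def test_grid_cannot_exceed_phantom(self, source_spec):
        with pytest.raises(ValueError, match="phantom"):
            generate_dose_grid(source_spec, make_trivial_params(), "water",
                               (305, 31, 15))


class TestDepthDoseExtraction:
    def test_matches_voxel_ring_average(self, source_spec):
        """Brute-force oracle: mean over voxels within +-0.5 mm of the
        transverse plane and of the target radius agrees within 0.5%.

        Radii start at 2 cm: in the near field the discrete annulus holds
        more voxels at its outer edge, biasing the bin mean low by a few
        percent against any point estimator of a 1/r^2 falloff."""
        params = make_analytic_params(water_coeffs=(0.25, 0.01))
        grid = generate_dose_grid(source_spec, params, "water", (91, 91, 21))
        radii = np.array([2.0, 3.0, 4.0])
        curve = extract_depth_dose(grid, radii)
        for r, d in zip(radii, curve.doses):
            ring = transverse_ring_doses(grid, r, half_width_mm=0.5)
            assert d == pytest.approx(ring.mean(), rel=5e-3)

    def test_azimuthal_rotation_invariance(self, source_spec):
        """Rotating the grid 90 deg about the tube axis leaves the
        azimuthally averaged curve unchanged."""
        params = make_analytic_params(azimuthal_amplitude=0.05)
        grid = generate_dose_grid(source_spec, params, "water", (61, 61, 21))
        rotated = DoseGrid(
            values=np.rot90(grid.values, k=1, axes=(0, 1)).copy(),
            voxel_size_mm=grid.voxel_size_mm,
            origin=grid.origin,
            medium=grid.medium,
            source_voxel=grid.source_voxel,
        )
        radii = np.array([1.0, 2.0, 2.8])
        c1 = extract_depth_dose(grid, radii, n_azimuth=360)
        c2 = extract_depth_dose(rotated, radii, n_azimuth=360)
        np.testing.assert_allclose(c1.doses, c2.doses, rtol=1e-6)

    def test_out_of_bounds_radius_rejected(self, source_spec):
        grid = generate_dose_grid(source_spec, make_trivial_params(), "water",
                                  (41, 41, 21))
        with pytest.raises(ValueError, match="exceeds"):
            extract_depth_dose(grid, [5.0])

    def test_resolution_convergence(self, source_spec):
        """Halving the voxel size changes the noise-free depth-dose by < 1%."""
        params = make_analytic_params()
        coarse = generate_dose_grid(source_spec, params, "water", (91, 91, 11), 1.0)
        fine = generate_dose_grid(source_spec, params, "water", (181, 181, 21), 0.5)
        radii = np.array([1.0, 2.0, 3.0, 4.0])
        d1 = extract_depth_dose(coarse, radii).doses
        d2 = extract_depth_dose(fine, radii).doses
        assert np.max(np.abs(d1 / d2 - 1.0)) < 1e-2


class TestFilmPlaneSampling:
    def test_centre_pixel_geometry(self, source_spec):
        """(u, v) = (0, 0) at 1 cm offset samples the point (r=1, theta=90)."""
        grid = generate_dose_grid(source_spec, make_trivial_params(), "water",
                                  (41, 41, 21))
        plane = sample_film_plane(grid, offset_cm=1.0)
        i = np.argmin(np.abs(plane.u_cm))
        j = np.argmin(np.abs(plane.v_cm))
        direct = grid.interpolate([[0.0, -1.0, 0.0]])[0]
        assert plane.values[i, j] == pytest.approx(direct, abs=1e-12)
        # isotropic inverse-square: the point nearest the source is the maximum
        assert plane.values[i, j] == pytest.approx(np.nanmax(plane.values))

    def test_values_match_kernel_evaluation(self, source_spec):
        """Interpolated plane values track the analytic kernel within 0.5%."""
        params = make_analytic_params()
        grid = generate_dose_grid(source_spec, params, "water", DEFAULT_SHAPE)
        plane = sample_film_plane(grid, offset_cm=1.0)
        iu = np.searchsorted(plane.u_cm, [0.0, 1.2, -2.0])
        jv = np.searchsorted(plane.v_cm, [0.0, 0.8, 2.5])
        d = plane.offset_cm
        for i in iu:
            for j in jv:
                u, v = plane.u_cm[i], plane.v_cm[j]
                r = np.sqrt(u**2 + v**2 + d**2)
                theta = np.degrees(np.arccos(u / r))
                law = params.attenuation["water"]
                expected = (
                    1000.0 / law(1.0)  # K for reference 1000 at 1 cm in water
                    * law(r) * params.polar(theta) / r**2
                )
                assert plane.values[i, j] == pytest.approx(expected, rel=5e-3)

    def test_offset_outside_grid_rejected(self, source_spec):
        grid = generate_dose_grid(source_spec, make_trivial_params(), "water",
                                  (41, 41, 21))
        with pytest.raises(ValueError, match="outside the grid"):
            sample_film_plane(grid, offset_cm=5.0)


def test_grid_csv_round_trip(tmp_path, source_spec):
    grid = generate_dose_grid(
        source_spec, make_trivial_params(noise_sd=0.01, seed=7), "abs", (9, 9, 7)
    )
    path = tmp_path / "grid.csv"
    write_grid_csv(grid, path, metadata={"seed": 7})
    back = read_grid_csv(path)
    assert back.medium == "abs"
    assert back.voxel_size_mm == grid.voxel_size_mm
    assert back.source_voxel == grid.source_voxel
    np.testing.assert_allclose(back.values, grid.values, rtol=1e-6, equal_nan=True)


def test_source_spec_validation():
    with pytest.raises(ValueError):
        SourceSpec(operating_voltage_kvp=80.0)  # tube tops out at 70 kVp
    with pytest.raises(ValueError):
        SourceSpec(air_kerma_strength=-1.0)


def test_kernel_params_validation():
    with pytest.raises(ValueError, match="amplitude"):
        KernelParams(
            medium_scale={"water": 1.0},
            attenuation={"water": ExpPolyAttenuation(())},
            azimuthal_amplitude=0.5,
        )
    with pytest.raises(ValueError, match="positive"):
        PolarProfile(a=-2.5, b=0.0)
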