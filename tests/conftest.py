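"""Shared fixtures: calibrated default grids and simple analytic kernels.

Session-scoped grids are generated once; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mxtdosim import (
    ExpPolyAttenuation,
    KernelParams,
    PolarProfile,
    SourceSpec,
    default_kernel_params,
    generate_dose_grid,
    load_fixtures,
)

DEFAULT_SHAPE = (105, 105, 89)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixtures()


@pytest.fixture(scope="session")
def source_spec():
    return SourceSpec()


def make_analytic_params(
    water_coeffs=(0.3, 0.02),
    abs_coeffs=(0.2, 0.02),
    abs_scale=0.75,
    polar=PolarProfile(a=0.0, b=0.16),
    azimuthal_amplitude=0.0,
    noise_sd=0.0,
    seed=None,
    reference_dose_rate=1000.0,
) -> KernelParams:
    """Closed-form kernel: exponential-polynomial attenuation per medium."""
    return KernelParams(
        medium_scale={"water": 1.0, "abs": abs_scale},
        attenuation={
            "water": ExpPolyAttenuation(tuple(water_coeffs)),
            "abs": ExpPolyAttenuation(tuple(abs_coeffs)),
        },
        polar=polar,
        azimuthal_amplitude=azimuthal_amplitude,
        noise_sd=noise_sd,
        seed=seed,
        reference_dose_rate=reference_dose_rate,
    )


def make_trivial_params(noise_sd=0.0, seed=None) -> KernelParams:
    """Pure inverse-square kernel: no attenuation, isotropic, no ripple."""
    return KernelParams(
        medium_scale={"water": 1.0, "abs": 1.0},
        attenuation={"water": ExpPolyAttenuation(()), "abs": ExpPolyAttenuation(())},
        polar=PolarProfile(),
        azimuthal_amplitude=0.0,
        noise_sd=noise_sd,
        seed=seed,
        reference_dose_rate=1000.0,
    )


@pytest.fixture(scope="session")
def default_params_noisefree():
    return default_kernel_params(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_grids_noisefree(source_spec, default_params_noisefree):
    return {
        m: generate_dose_grid(source_spec, default_params_noisefree, m, DEFAULT_SHAPE)
        for m in ("water", "abs")
    }


@pytest.fixture(scope="session")
def default_grids_noisy(source_spec):
    params = default_kernel_params(noise_sd=0.007, seed=20260926)
    return {
        m: generate_dose_grid(source_spec, params, m, DEFAULT_SHAPE)
        for m in ("water", "abs")
    }


@pytest.fixture(scope="session")
def analytic_params_noisefree():
    return make_analytic_params()


@pytest.fixture(scope="session")
def analytic_grid_noisefree(source_spec, analytic_params_noisefree):
    return generate_dose_grid(
        source_spec, analytic_params_noisefree, "water", DEFAULT_SHAPE
    )
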