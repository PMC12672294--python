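"""Distance-dependent ABS-to-water conversion of measured dose quantities.

TG-43 parameters are defined in water, but measurements in a machined ABS
phantom are far more practical for an electronic source.  Because ABS
(effective atomic number below water's) attenuates the soft kV spectrum
less than water, the water/ABS dose ratio is distance dependent: above 1
near the source, falling below 1 a few cm out.  The conversion function

    CF(r) = D_water(r) / D_ABS(r)

is derived from paired transverse depth-dose curves, applied
multiplicatively to ABS-measured doses, and its residual error quantified
as a relative RMSE which doubles as the conversion's uncertainty
component in the budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .grids import DepthDoseCurve

__all__ = ["ConversionFunction", "derive_cf", "apply_cf", "cf_rmse"]


@dataclass
class ConversionFunction:
    """Water/ABS dose ratio versus radial distance.

    ``fit_form`` is ``"pointwise"`` (monotone cubic interpolation between
    the derivation radii — the default, since no particular functional
    form is privileged) or ``"poly:N"`` (least-squares polynomial of
    degree N in r).  ``rmse`` is the relative RMSE of converting the ABS
    derivation curve back to water, stored at derivation time.
    """

    radii: np.ndarray
    cf_values: np.ndarray
    fit_form: str = "pointwise"
    fit_coeffs: Optional[np.ndarray] = None  # ascending powers for poly:N
    rmse: float = 0.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.cf_values = np.asarray(self.cf_values, dtype=float)
        if self.radii.ndim != 1 or self.radii.shape != self.cf_values.shape:
            raise ValueError("radii and cf_values must be 1-D of equal length")
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if not np.all(self.cf_values > 0):
            raise ValueError("conversion factors must be positive")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        self._interp = (
            PchipInterpolator(self.radii, self.cf_values)
            if self.radii.size >= 2
            else None
        )

    @property
    def range_cm(self) -> tuple[float, float]:
        return float(self.radii[0]), float(self.radii[-1])

    def __call__(self, r, extrapolate: bool = False) -> np.ndarray:
        """Evaluate CF(r); refuses extrapolation unless asked explicitly."""
        r = np.asarray(r, dtype=float)
        lo, hi = self.range_cm
        if not extrapolate and (np.any(r < lo - 1e-12) or np.any(r > hi + 1e-12)):
            raise ValueError(
                f"r outside the conversion range [{lo}, {hi}] cm; pass "
                "extrapolate=True to override"
            )
        if self.fit_form.startswith("poly:"):
            out = np.polynomial.polynomial.polyval(r, self.fit_coeffs)
        elif self._interp is not None:
            out = self._interp(np.clip(r, lo, hi))
            if extrapolate:
                # linear continuation of the end segments
                dlo = float(self._interp.derivative()(lo))
                dhi = float(self._interp.derivative()(hi))
                out = np.where(r < lo, self.cf_values[0] + dlo * (r - lo), out)
                out = np.where(r > hi, self.cf_values[-1] + dhi * (r - hi), out)
        else:
            out = np.full_like(r, self.cf_values[0])
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_cm": self.radii, "cf": self.cf_values})


def _common_radii(
    water: DepthDoseCurve, abs_curve: DepthDoseCurve
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Doses of both curves on a shared radius set (overlap of ranges)."""
    if np.array_equal(water.radii, abs_curve.radii):
        return water.radii, water.doses, abs_curve.doses
    lo = max(water.radii.min(), abs_curve.radii.min())
    hi = min(water.radii.max(), abs_curve.radii.max())
    if lo >= hi:
        raise ValueError("depth-dose curves have non-overlapping radius ranges")
    sel = (water.radii >= lo - 1e-12) & (water.radii <= hi + 1e-12)
    radii = water.radii[sel]
    # log-log interpolation: exact for power laws and well conditioned for
    # exponential-attenuation curves, unlike interpolation in dose space
    d_abs = np.exp(
        PchipInterpolator(np.log(abs_curve.radii), np.log(abs_curve.doses))(
            np.log(radii)
        )
    )
    return radii, water.doses[sel], np.asarray(d_abs)


def derive_cf(
    water: DepthDoseCurve,
    abs_curve: DepthDoseCurve,
    fit_form: str = "pointwise",
) -> ConversionFunction:
    """Derive CF(r) as the ratio of water and ABS depth-dose curves.

    Curves sharing radii are divided pointwise; otherwise the ABS curve is
    interpolated (monotone cubic) onto the water radii inside the common
    range.  For ``poly:N`` the pointwise ratio is additionally fitted by a
    degree-N polynomial.  The relative RMSE of CF * D_ABS against D_water
    on the derivation radii is stored as the conversion uncertainty.
    """
    radii, d_water, d_abs = _common_radii(water, abs_curve)
    if np.any(d_abs <= 0) or np.any(d_water <= 0):
        raise ValueError("depth-dose values must be positive")
    ratio = d_water / d_abs
    coeffs = None
    if fit_form == "pointwise":
        cf_values = ratio
    elif fit_form.startswith("poly:"):
        degree = int(fit_form.split(":", 1)[1])
        if degree < 0 or degree >= radii.size:
            raise ValueError(f"polynomial degree {degree} unusable for {radii.size} radii")
        coeffs = np.polynomial.polynomial.polyfit(radii, ratio, degree)
        cf_values = np.polynomial.polynomial.polyval(radii, coeffs)
        if np.any(cf_values <= 0):
            raise ValueError("polynomial conversion fit goes non-positive")
    else:
        raise ValueError(f"unknown fit_form {fit_form!r}")
    cf = ConversionFunction(
        radii=radii, cf_values=cf_values, fit_form=fit_form, fit_coeffs=coeffs
    )
    cf.rmse = cf_rmse(cf, water, abs_curve)
    return cf


def apply_cf(
    quantity: Union[float, pd.DataFrame],
    cf: ConversionFunction,
    r: Optional[float] = None,
    r0: float = 1.0,
    extrapolate: bool = False,
) -> Union[float, pd.DataFrame]:
    """Convert an ABS-measured quantity to its water-equivalent value.

    A scalar quantity needs its radius ``r``; the result is
    ``quantity * CF(r)``.  A g-table (DataFrame with columns r_cm, g) is
    converted row-wise and then *renormalized* so that g(r0) = 1 again —
    mandatory, because a radial dose function is defined normalized at
    the reference radius.
    """
    if isinstance(quantity, pd.DataFrame):
        radii = quantity["r_cm"].to_numpy(dtype=float)
        g = quantity["g"].to_numpy(dtype=float)
        converted = g * cf(radii, extrapolate=extrapolate)
        at_r0 = np.isclose(radii, r0)
        if np.any(at_r0):
            norm = converted[at_r0][0]
        else:
            norm = float(PchipInterpolator(radii, converted)(r0))
        if norm <= 0:
            raise ValueError("converted table non-positive at the reference radius")
        out = converted / norm
        out[at_r0] = 1.0
        return pd.DataFrame({"r_cm": radii, "g": out})
    if r is None:
        raise ValueError("scalar conversion requires the radius r")
    return float(quantity) * float(cf(r, extrapolate=extrapolate))


def cf_rmse(
    cf: ConversionFunction, water: DepthDoseCurve, abs_curve: DepthDoseCurve
) -> float:
    """Relative RMSE of the conversion over the curves' shared radii.

    RMSE of (CF(r) * D_ABS(r) - D_water(r)) / D_water(r); zero for an
    exact pointwise conversion.
    """
    radii, d_water, d_abs = _common_radii(water, abs_curve)
    if radii.size == 0:
        raise ValueError("empty radius set")
    rel = (cf(radii, extrapolate=True) * d_abs - d_water) / d_water
    return float(np.sqrt(np.mean(rel**2)))
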