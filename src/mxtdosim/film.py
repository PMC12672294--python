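"""Radiochromic film dosimetry: netOD calibration and plane-to-polar mapping.

Scanned film is read as 16-bit-per-channel RGB TIFF (75 dpi flatbed scan
by default).  Pixel values are converted to net optical density

    netOD = log10((PV_unexposed - PV_background) / (PV_exposed - PV_background))

— the standard radiochromic convention with background subtraction — and
netOD to dose through a third-order polynomial calibration fitted from
(netOD, dose) pairs.  The film plane sits 1 cm below the source axis,
parallel to the tube axis; mapping its pixels into TG-43 polar
coordinates carries the geometric measurability constraint: a plane at
perpendicular distance d only reaches points with r*sin(theta) >= d, and
film directional dependence further restricts polar angles to >= 20 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .tg43 import PolarDoseSamples

__all__ = [
    "FilmCalibration",
    "FilmPlaneMap",
    "FilmDoseResult",
    "CalibrationError",
    "compute_netOD",
    "fit_calibration",
    "film_to_dose",
    "map_film_plane_to_polar",
    "read_film_image",
    "write_film_image",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}

#: Default scan resolution: 75 dpi -> 0.3387 mm pixel pitch.
DEFAULT_PIXEL_PITCH_MM = 25.4 / 75.0

#: Minimum measurable polar angle, degrees (film directional dependence).
MIN_POLAR_ANGLE_DEG = 20.0


class CalibrationError(ValueError):
    """Raised for unusable calibration data or a non-monotone fit."""


def compute_netOD(pv_exposed, pv_unexposed, pv_background=0.0):
    """Net optical density of exposed film, elementwise.

    All inputs broadcast; net signals (pixel value minus background) must
    be positive.  netOD is >= 0 whenever exposure darkens the film, and 0
    for an unexposed film regardless of the background level.
    """
    exposed = np.asarray(pv_exposed, dtype=float)
    unexposed = np.asarray(pv_unexposed, dtype=float)
    background = np.asarray(pv_background, dtype=float)
    net_exp = exposed - background
    net_unexp = unexposed - background
    if np.any(net_unexp <= 0):
        raise ValueError("unexposed net signal must be positive")
    if np.any(net_exp <= 0):
        raise ValueError(
            f"{int(np.sum(net_exp <= 0))} pixel(s) with non-positive exposed "
            "net signal (saturated or background exceeds pixel value)"
        )
    return np.log10(net_unexp / net_exp)


@dataclass(frozen=True)
class FilmCalibration:
    """Dose as a third-order polynomial in netOD for one colour channel.

    ``poly_coeffs`` are ascending (c0 + c1 x + c2 x^2 + c3 x^3), dose in
    cGy.  The fit is strictly non-decreasing over the calibrated netOD
    range; ``fit_residual_sd`` is the residual SD in cGy.
    """

    channel: str
    poly_coeffs: tuple[float, float, float, float]
    calibration_points: tuple[tuple[float, float], ...]
    fit_residual_sd: float

    @property
    def netod_range(self) -> tuple[float, float]:
        netods = [p[0] for p in self.calibration_points]
        return (min(netods), max(netods))

    def dose(self, netod) -> np.ndarray:
        """Evaluate the calibration polynomial (no range checking here)."""
        x = np.asarray(netod, dtype=float)
        c0, c1, c2, c3 = self.poly_coeffs
        return c0 + x * (c1 + x * (c2 + x * c3))


def fit_calibration(
    points: Sequence[tuple[float, float]] | np.ndarray,
    channel: str = "red",
) -> FilmCalibration:
    """Least-squares cubic dose(netOD) calibration.

    Requires >= 4 distinct netOD values (fewer make the cubic design
    rank-deficient).  Fits that decrease anywhere inside the calibrated
    netOD range are refused with a diagnostic, since a dose-darkening
    curve must be monotone.
    """
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns netOD, dose_cGy")
    netod, dose = pts[:, 0], pts[:, 1]
    if np.unique(netod).size < 4:
        raise CalibrationError(
            f"need >= 4 distinct netOD values, got {np.unique(netod).size} "
            "(duplicated netODs make the cubic design rank-deficient)"
        )
    coeffs = np.polynomial.polynomial.polyfit(netod, dose, 3)
    fitted = np.polynomial.polynomial.polyval(netod, coeffs)
    dof = netod.size - 4
    residual_sd = float(np.sqrt(np.sum((dose - fitted) ** 2) / dof)) if dof > 0 else 0.0

    grid = np.linspace(netod.min(), netod.max(), 512)
    slope = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coeffs)
    )
    tol = 1e-9 * max(1.0, float(np.abs(dose).max()))
    if np.any(slope < -tol):
        worst = grid[int(np.argmin(slope))]
        raise CalibrationError(
            f"calibration fit is decreasing near netOD = {worst:.4f} "
            f"(min slope {slope.min():.4g} cGy/netOD); dose(netOD) must be "
            "non-decreasing over the calibrated range"
        )
    return FilmCalibration(
        channel=channel,
        poly_coeffs=tuple(float(c) for c in coeffs),
        calibration_points=tuple((float(a), float(b)) for a, b in pts),
        fit_residual_sd=residual_sd,
    )


@dataclass
class FilmPlaneMap:
    """Planar dose map on the film plane below the source.

    ``values`` is indexed (u, v): u runs along the tube axis, v lateral.
    ``offset_cm`` is the perpendicular distance of the plane from the
    source axis (default 1 cm).  ``u_cm``/``v_cm`` are the in-plane pixel
    centre coordinates; when omitted they form a lattice at
    ``pixel_pitch_mm`` centred on the foot of the source perpendicular.
    """

    values: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    offset_cm: float = 1.0
    u_cm: Optional[np.ndarray] = None
    v_cm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("film plane values must be 2-D (u, v)")
        if self.offset_cm <= 0:
            raise ValueError("offset_cm must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        pitch = self.pixel_pitch_mm / 10.0
        nu, nv = self.values.shape
        if self.u_cm is None:
            self.u_cm = (np.arange(nu) - (nu - 1) / 2.0) * pitch
        if self.v_cm is None:
            self.v_cm = (np.arange(nv) - (nv - 1) / 2.0) * pitch
        self.u_cm = np.asarray(self.u_cm, dtype=float)
        self.v_cm = np.asarray(self.v_cm, dtype=float)
        if self.u_cm.shape != (nu,) or self.v_cm.shape != (nv,):
            raise ValueError("u_cm/v_cm lengths must match the value grid")


@dataclass(frozen=True)
class FilmDoseResult:
    """Pixelwise dose map plus quality flags from a film conversion."""

    dose: np.ndarray  # cGy
    netod: np.ndarray
    out_of_range: np.ndarray  # netOD outside the calibrated range
    saturated: np.ndarray

    @property
    def report(self) -> dict[str, int]:
        return {
            "pixels": int(self.dose.size),
            "out_of_range": int(np.sum(self.out_of_range)),
            "saturated": int(np.sum(self.saturated)),
        }


def film_to_dose(
    image,
    calibration: FilmCalibration,
    unexposed,
    background=0.0,
    saturation: int = 65535,
) -> FilmDoseResult:
    """Convert a scanned film image to absorbed dose, pixelwise.

    ``image`` may be a path to a 16-bit RGB TIFF or an array (H, W) /
    (H, W, 3); the calibration's colour channel is extracted from RGB
    input.  ``unexposed`` is the unexposed-film reference (scalar or
    image).  Pixels whose netOD falls outside the calibrated range are
    evaluated at the clamped range edge and flagged rather than silently
    extrapolated; pixels at the scanner saturation level (or below
    background) are flagged saturated and excluded from conversion.
    """
    pv = read_film_image(image, channel=calibration.channel)
    unexp = read_film_image(unexposed, channel=calibration.channel)
    saturated = (pv >= saturation) | (pv - np.asarray(background, dtype=float) <= 0)
    safe_pv = np.where(saturated, np.asarray(unexp, dtype=float), pv)
    netod = compute_netOD(safe_pv, unexp, background)
    lo, hi = calibration.netod_range
    out_of_range = (netod < lo) | (netod > hi)
    dose = calibration.dose(np.clip(netod, lo, hi))
    dose = np.where(saturated, np.nan, dose)
    netod = np.where(saturated, np.nan, netod)
    return FilmDoseResult(
        dose=dose, netod=netod, out_of_range=out_of_range & ~saturated,
        saturated=saturated,
    )


def map_film_plane_to_polar(
    plane: FilmPlaneMap, min_theta_deg: float = MIN_POLAR_ANGLE_DEG
) -> "PolarDoseSamples":
    """Map film-plane pixels into TG-43 polar coordinates.

    A pixel at in-plane position (u, v) on a plane at perpendicular
    distance d from the source axis sits at

        r = sqrt(u^2 + v^2 + d^2),   theta = arccos(u / r).

    Validity requires theta >= ``min_theta_deg`` (film directional
    dependence) and r*sin(theta) >= d (the geometric reach of the plane;
    automatically satisfied by points *on* the plane, but kept explicit so
    the mask composes with externally supplied samples).  Invalid samples
    are masked, never dropped.
    """
    from .tg43 import PolarDoseSamples

    d = plane.offset_cm
    U, V = np.meshgrid(plane.u_cm, plane.v_cm, indexing="ij")
    r = np.sqrt(U**2 + V**2 + d**2)
    theta = np.degrees(np.arccos(np.clip(U / r, -1.0, 1.0)))
    valid = (theta >= min_theta_deg) & (
        r * np.sin(np.radians(theta)) >= d * (1.0 - 1e-12)
    )
    dose = plane.values
    valid = valid & np.isfinite(dose)
    return PolarDoseSamples(
        r_cm=r.ravel(),
        theta_deg=theta.ravel(),
        dose=np.where(np.isfinite(dose), dose, 0.0).ravel(),
        valid=valid.ravel(),
    )


# -- image I/O -------------------------------------------------------------


def read_film_image(image, channel: str = "red") -> np.ndarray:
    """Return one colour channel of a film scan as a float array.

    Accepts a TIFF path, an (H, W, 3) RGB array, an (H, W) single-channel
    array, or a scalar (broadcast reference level).
    """
    if isinstance(image, (str, Path)):
        import tifffile

        image = tifffile.imread(str(image))
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise ValueError("RGB image must have 3 channels")
        arr = arr[:, :, _CHANNELS[channel]]
    elif arr.ndim not in (0, 2):
        raise ValueError("image must be scalar, (H, W) or (H, W, 3)")
    return arr


def write_film_image(path: str | Path, rgb: np.ndarray) -> None:
    """Write a 16-bit-per-channel RGB TIFF (e.g. a synthetic film scan)."""
    import tifffile

    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if arr.dtype != np.uint16:
        if np.any(arr < 0) or np.any(arr > 65535):
            raise ValueError("pixel values must fit uint16")
        arr = np.round(arr).astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="rgb")
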