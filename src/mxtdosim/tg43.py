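"""TG-43 dosimetric parameters for a point-like electronic source.

The TG-43 formalism factorizes the dose rate around a brachytherapy
source as Lambda * G(r, theta) * g(r) * F(r, theta).  For a miniature
X-ray tube with no conventional source volume, the point-source geometry
function G_P(r) = 1/r^2 is the appropriate (and only offered) choice, so

    g(r)       = [D(r, 90) / D(r0, 90)] * r^2 / r0^2,
    F(r, theta) = D(r, theta) / D(r, 90),

with the reference point at r0 = 1 cm, theta0 = 90 deg.  For an
electronic source the dose-rate constant is conventionally expressed per
unit tube current (cGy/h/uA); the classical division by air-kerma
strength is available as a clearly separated mode.

Azimuthal ratios (dose around the tube's long axis, normalized at 0 deg)
and the comparison statistics used to confront parameter tables
(ratio/difference mode, mean, sample SD, max |value| and its location)
live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .grids import DepthDoseCurve, DoseGrid

__all__ = [
    "PolarDoseSamples",
    "Tg43ParameterSet",
    "TableComparison",
    "AzimuthalRatios",
    "geometry_function_point",
    "dose_rate_constant",
    "radial_dose_function",
    "anisotropy_function",
    "azimuthal_ratios",
    "compare_tables",
    "polar_samples_from_grid",
    "bin_polar_samples",
]

R0_CM = 1.0
THETA0_DEG = 90.0

#: cGy cm^2 h^-1 per Gy cm^2 min^-1 (unit harmonization for classical mode).
_SK_TO_CGY_H = 100.0 * 60.0


@dataclass
class PolarDoseSamples:
    """Dose samples on a polar (r, theta) lattice or scatter.

    ``valid`` marks measurable samples; invalid entries are carried, never
    dropped, so masks compose.  Convention: r in cm (> 0), theta in
    degrees from the tube axis (0-180), dose in cGy/h/uA.
    """

    r_cm: np.ndarray
    theta_deg: np.ndarray
    dose: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.r_cm.shape
        if not (self.theta_deg.shape == self.dose.shape == self.valid.shape == n):
            raise ValueError("all sample arrays must share one shape")
        if not np.all(self.r_cm > 0):
            raise ValueError("radii must be positive")
        if np.any((self.theta_deg < 0) | (self.theta_deg > 180)):
            raise ValueError("theta must lie in [0, 180] degrees")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_cm": self.r_cm,
                "theta_deg": self.theta_deg,
                "dose": self.dose,
                "valid": self.valid,
            }
        )


@dataclass
class AzimuthalRatios:
    """Dose ratios versus azimuthal angle, normalized at phi = 0."""

    table: pd.DataFrame  # columns phi_deg, ratio
    max_ratio: float
    argmax_phi_deg: float


@dataclass
class Tg43ParameterSet:
    """Headline output of the pipeline: Lambda, g(r), F(r, theta), azimuth."""

    dose_rate_constant: float  # cGy/h/uA (per-current convention)
    g_table: pd.DataFrame  # columns r_cm, g
    f_table: pd.DataFrame  # columns r_cm, theta_deg, F, valid
    azimuthal: Optional[AzimuthalRatios]
    medium: str
    provenance: Literal["simulated", "film", "detector"] = "simulated"


@dataclass
class TableComparison:
    """Per-point ratio or difference between two parameter tables."""

    mode: Literal["ratio", "difference"]
    values: pd.Series
    mean: float
    sd: float
    max_abs: float
    argmax: object  # index label of max |value|; ties -> smallest label

    @property
    def n(self) -> int:
        return int(self.values.size)


def geometry_function_point(r):
    """Point-source geometry function G_P(r) = 1/r^2 (r in cm, > 0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("geometry function requires r > 0")
    out = 1.0 / r**2
    return float(out) if out.ndim == 0 else out


def dose_rate_constant(
    reference_dose_rate_per_ua: float,
    s_k: Optional[float] = None,
    mode: Literal["per_current", "classical"] = "per_current",
) -> float:
    """Dose-rate constant from the reference-point dose rate.

    ``per_current`` (default, the electronic-brachytherapy convention)
    takes the dose rate at (r0, theta0) per unit tube current, cGy/h/uA,
    as Lambda unchanged.  ``classical`` divides by the air-kerma strength
    ``s_k`` (Gy cm^2/min), harmonizing units to cGy cm^2/h, and returns
    Lambda in cm^-2.
    """
    d_ref = float(reference_dose_rate_per_ua)
    if d_ref < 0:
        raise ValueError("reference dose rate must be >= 0")
    if mode == "per_current":
        return d_ref
    if mode == "classical":
        if s_k is None or s_k <= 0:
            raise ValueError("classical mode requires air-kerma strength > 0")
        return d_ref / (s_k * _SK_TO_CGY_H)
    raise ValueError(f"unknown mode {mode!r}")


def _transverse_profile(
    transverse: Union[DepthDoseCurve, PolarDoseSamples],
    theta0: float,
    theta_tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(transverse, DepthDoseCurve):
        return transverse.radii, transverse.doses
    sel = transverse.valid & (np.abs(transverse.theta_deg - theta0) <= theta_tol)
    if not np.any(sel):
        raise ValueError(f"no valid transverse samples at theta0 = {theta0} deg")
    r = transverse.r_cm[sel]
    d = transverse.dose[sel]
    order = np.argsort(r)
    return r[order], d[order]


def radial_dose_function(
    transverse: Union[DepthDoseCurve, PolarDoseSamples],
    r0: float = R0_CM,
    theta0: float = THETA0_DEG,
    theta_tol: float = 1e-6,
) -> pd.DataFrame:
    """Radial dose function g(r) = [D(r)/D(r0)] * r^2/r0^2 on the transverse plane.

    The reference dose at ``r0`` is taken from the profile directly if a
    sample sits there, otherwise interpolated (monotone cubic).  g(r0) = 1
    holds exactly by construction.
    """
    radii, doses = _transverse_profile(transverse, theta0, theta_tol)
    if not (radii.min() <= r0 <= radii.max()):
        raise ValueError(f"r0 = {r0} cm not covered by the profile")
    at_r0 = np.isclose(radii, r0)
    if np.any(at_r0):
        d0 = float(doses[at_r0][0])
    elif radii.size >= 2:
        if np.all(doses > 0):
            # log-log interpolation: exact for power laws, well conditioned
            # for the steep near-field falloff
            d0 = float(
                np.exp(PchipInterpolator(np.log(radii), np.log(doses))(np.log(r0)))
            )
        else:
            d0 = float(np.interp(r0, radii, doses))
    else:
        raise ValueError("cannot interpolate the reference dose from one sample")
    if d0 <= 0:
        raise ValueError("zero dose at the reference radius")
    g = (doses / d0) * (radii**2 / r0**2)
    g[at_r0] = 1.0  # exact normalization at the reference point
    return pd.DataFrame({"r_cm": radii, "g": g})


def anisotropy_function(
    samples: PolarDoseSamples,
    theta0: float = THETA0_DEG,
    theta_tol: float = 1e-6,
) -> pd.DataFrame:
    """Anisotropy function F(r, theta) = D(r, theta) / D(r, theta0).

    With the theta-independent point-source geometry function the
    geometric factors cancel.  F(r, theta0) = 1 exactly.  Radii lacking a
    valid transverse reference have their whole row masked with an
    explicit warning; masked entries carry NaN, never silently filled.
    """
    df = samples.to_frame()
    radii = np.unique(df["r_cm"].to_numpy())
    out = []
    for r in radii:
        rows = df[np.isclose(df["r_cm"], r)]
        ref_rows = rows[
            rows["valid"] & (np.abs(rows["theta_deg"] - theta0) <= theta_tol)
        ]
        if len(ref_rows) == 0 or not np.all(ref_rows["dose"] > 0):
            warnings.warn(
                f"no valid transverse reference at r = {r:g} cm; row masked",
                stacklevel=2,
            )
            for _, row in rows.iterrows():
                out.append((r, row["theta_deg"], np.nan, False))
            continue
        d_ref = float(ref_rows["dose"].mean())
        for _, row in rows.iterrows():
            ok = bool(row["valid"])
            if abs(row["theta_deg"] - theta0) <= theta_tol:
                f_val = 1.0 if ok else np.nan
            else:
                f_val = row["dose"] / d_ref if ok else np.nan
            out.append((r, row["theta_deg"], f_val, ok))
    return pd.DataFrame(out, columns=["r_cm", "theta_deg", "F", "valid"])


def azimuthal_ratios(
    doses_by_phi: Union[Sequence[tuple[float, float]], pd.DataFrame],
) -> AzimuthalRatios:
    """Azimuthal dose ratios normalized to phi = 0 deg.

    Input is (phi_deg, dose) pairs; duplicates are rejected, phi = 0 must
    be present and all doses positive.  The maximum ratio and its angle
    are reported (ties break toward the smallest phi).  The result is
    independent of input order.
    """
    if isinstance(doses_by_phi, pd.DataFrame):
        pairs = doses_by_phi[["phi_deg", "dose"]].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(doses_by_phi), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected (phi_deg, dose) pairs")
    phi, dose = pairs[:, 0], pairs[:, 1]
    uniq, counts = np.unique(phi, return_counts=True)
    if np.any(counts > 1):
        raise ValueError(f"duplicate azimuthal angles: {uniq[counts > 1].tolist()}")
    if not np.any(phi == 0.0):
        raise ValueError("a phi = 0 deg reference dose is required")
    if not np.all(dose > 0):
        raise ValueError("doses must be positive")
    order = np.argsort(phi)
    phi, dose = phi[order], dose[order]
    ratio = dose / dose[phi == 0.0][0]
    imax = int(np.argmax(ratio))  # argmax returns the first (smallest phi) tie
    table = pd.DataFrame({"phi_deg": phi, "ratio": ratio})
    return AzimuthalRatios(
        table=table, max_ratio=float(ratio[imax]), argmax_phi_deg=float(phi[imax])
    )


def compare_tables(
    a: pd.Series,
    b: pd.Series,
    mode: Literal["ratio", "difference"] = "ratio",
) -> TableComparison:
    """Pointwise ratio a/b or difference a-b with summary statistics.

    ``a`` and ``b`` must be Series over an identical point set (index of
    radii, or a (r, theta) MultiIndex); entries that are NaN in either
    table are masked out jointly (mask intersection).  Statistics use the
    sample SD (n-1); the location of max |value| breaks ties toward the
    smallest index label.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    if not a.index.equals(b.index):
        if len(a) != len(b) or len(a.index.symmetric_difference(b.index)) > 0:
            raise ValueError("tables do not share an identical point set")
        b = b.reindex(a.index)
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if a.empty:
        raise ValueError("no jointly valid points to compare")
    values = (a / b) if mode == "ratio" else (a - b)
    values = values.sort_index()
    abs_vals = values.abs().to_numpy()
    imax = int(np.argmax(abs_vals))  # first occurrence = smallest label on sorted index
    return TableComparison(
        mode=mode,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        max_abs=float(abs_vals[imax]),
        argmax=values.index[imax],
    )


# -- grid extraction -------------------------------------------------------


def polar_samples_from_grid(
    grid: DoseGrid,
    radii: Sequence[float],
    thetas_deg: Sequence[float],
    theta_halfwidth_deg: float = 1.0,
    n_theta_sub: int = 5,
    n_azimuth: int = 120,
) -> PolarDoseSamples:
    """Ring-averaged polar dose samples from a voxel grid.

    Each requested (r, theta) is sampled trilinearly over a 2-deg-wide
    polar band (``theta_halfwidth_deg`` either side, ``n_theta_sub``
    sub-angles) and ``n_azimuth`` azimuths, then averaged — mirroring
    voxel-ring averaging and keeping scoring noise manageable at 1 mm
    voxels.  Samples whose band falls partly outside the grid are marked
    invalid (NaN dose) rather than averaged over a partial ring.
    """
    radii = np.asarray(radii, dtype=float)
    thetas = np.asarray(thetas_deg, dtype=float)
    dtheta = np.linspace(-theta_halfwidth_deg, theta_halfwidth_deg, n_theta_sub)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)

    r_grid, t_grid = np.meshgrid(radii, thetas, indexing="ij")
    r_flat, t_flat = r_grid.ravel(), t_grid.ravel()
    n_samples = r_flat.size

    t_sub = np.clip(t_flat[:, None] + dtheta[None, :], 0.0, 180.0)  # (n, s)
    t_rad = np.radians(t_sub)[:, :, None]
    r_ = r_flat[:, None, None]
    x = r_ * np.sin(t_rad) * np.cos(phi)[None, None, :]
    y = r_ * np.sin(t_rad) * np.sin(phi)[None, None, :]
    z = r_ * np.cos(t_rad) + np.zeros_like(x)
    pts = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    inside = grid.contains(pts).reshape(n_samples, -1)
    dose = np.full(n_samples, np.nan)
    valid = inside.all(axis=1)
    if np.any(valid):
        ok_pts = pts.reshape(n_samples, -1, 3)[valid].reshape(-1, 3)
        vals = grid.interpolate(ok_pts).reshape(valid.sum(), -1)
        dose[valid] = vals.mean(axis=1)
    valid &= np.isfinite(dose)
    return PolarDoseSamples(
        r_cm=r_flat,
        theta_deg=t_flat,
        dose=np.where(np.isfinite(dose), dose, 0.0),
        valid=valid,
    )


def bin_polar_samples(
    samples: PolarDoseSamples,
    radii: Sequence[float],
    thetas_deg: Sequence[float],
    r_tol_cm: float = 0.05,
    theta_tol_deg: float = 1.0,
) -> PolarDoseSamples:
    """Average scattered polar samples onto a requested (r, theta) lattice.

    Used to regrid film-plane samples (which land at arbitrary (r, theta))
    onto the tabulation lattice.  Lattice points with no valid sample in
    the (r_tol, theta_tol) bin are marked invalid.
    """
    radii = np.asarray(radii, dtype=float)
    thetas = np.asarray(thetas_deg, dtype=float)
    out_r, out_t, out_d, out_v = [], [], [], []
    sel_all = samples.valid
    for r in radii:
        near_r = sel_all & (np.abs(samples.r_cm - r) <= r_tol_cm)
        for t in thetas:
            sel = near_r & (np.abs(samples.theta_deg - t) <= theta_tol_deg)
            out_r.append(r)
            out_t.append(t)
            if np.any(sel):
                out_d.append(float(samples.dose[sel].mean()))
                out_v.append(True)
            else:
                out_d.append(0.0)
                out_v.append(False)
    return PolarDoseSamples(
        r_cm=np.array(out_r),
        theta_deg=np.array(out_t),
        dose=np.array(out_d),
        valid=np.array(out_v),
    )
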