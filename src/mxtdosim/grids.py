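"""Voxelized dose grids and transverse depth-dose curves.

The containers here are the common currency of the package: a
:class:`DoseGrid` stands in for a Monte-Carlo scoring lattice (dose rate
per unit tube current, cGy/h/uA, on a regular voxel grid in a stated
phantom medium), and a :class:`DepthDoseCurve` holds transverse-axis dose
versus radial distance in one medium.

Coordinate convention (used everywhere in this package)
-------------------------------------------------------
* The tube's long axis is +z; the polar angle theta is measured from +z,
  so the transverse plane (theta0 = 90 deg) is the xy-plane through the
  source.
* Physical positions are continuous centimetres with the source at the
  origin.  Voxel *centres* define sample positions: voxel index ``(i,j,k)``
  sits at ``((i - origin[0]) * d, (j - origin[1]) * d, (k - origin[2]) * d)``
  cm with ``d = voxel_size_mm / 10``.  ``origin`` is the (possibly
  fractional) grid index of the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DoseGrid", "DepthDoseCurve", "write_grid_csv", "read_grid_csv"]

#: Phantom outer dimensions in cm (x, y, z); grids may be truncated for
#: tests but never exceed the physical phantom.
PHANTOM_DIMENSIONS_CM = (30.0, 30.0, 20.0)

_KNOWN_MEDIA = ("water", "abs")


def _normalize_medium(medium: str) -> str:
    m = str(medium).strip().lower()
    if m not in _KNOWN_MEDIA:
        raise ValueError(f"unknown medium {medium!r}; expected one of {_KNOWN_MEDIA}")
    return m


@dataclass
class DoseGrid:
    """Dose rate per unit tube current on a regular voxel lattice.

    Parameters
    ----------
    values
        3-D array, cGy/h/uA.  All entries must be finite and >= 0 except
        for the voxel containing the source, which is flagged unusable
        (NaN) because 1/r^2 is singular there.
    voxel_size_mm
        Edge length of the cubic scoring voxel (default 1.0 mm).
    origin
        Grid index (i, j, k) of the source position; fractional values are
        allowed.
    medium
        ``"water"`` or ``"abs"``.
    """

    values: np.ndarray
    voxel_size_mm: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    medium: str = "water"
    source_voxel: Optional[tuple[int, int, int]] = None
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be a 3-D array")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        self.medium = _normalize_medium(self.medium)
        extent = np.array(self.values.shape) * self.voxel_size_mm / 10.0
        if np.any(extent > np.array(PHANTOM_DIMENSIONS_CM) + 1e-9):
            raise ValueError(
                f"grid extent {tuple(np.round(extent, 3))} cm exceeds the "
                f"{PHANTOM_DIMENSIONS_CM} cm phantom"
            )
        finite = np.isfinite(self.values)
        if not np.all(self.values[finite] >= 0):
            raise ValueError("dose values must be non-negative")
        bad = np.argwhere(~finite)
        if self.source_voxel is not None:
            allowed = {tuple(int(i) for i in self.source_voxel)}
        else:
            allowed = set()
        extra = {tuple(int(i) for i in idx) for idx in bad} - allowed
        if extra:
            raise ValueError(f"non-finite dose at voxels other than the source: {sorted(extra)[:5]}")

    # -- geometry -----------------------------------------------------

    @property
    def voxel_size_cm(self) -> float:
        return self.voxel_size_mm / 10.0

    @property
    def axes_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each axis, cm, source at 0."""
        d = self.voxel_size_cm
        return tuple(
            (np.arange(n) - o) * d for n, o in zip(self.values.shape, self.origin)
        )

    @property
    def extent_cm(self) -> tuple[tuple[float, float], ...]:
        """(min, max) voxel-centre coordinate per axis, cm."""
        return tuple((ax[0], ax[-1]) for ax in self.axes_cm)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 3) lying within the voxel-centre hull."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.ones(len(pts), dtype=bool)
        for k, (lo, hi) in enumerate(self.extent_cm):
            ok &= (pts[:, k] >= lo) & (pts[:, k] <= hi)
        return ok

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of dose at physical points (n, 3) in cm.

        Raises for points outside the voxel-centre hull.  Points within one
        voxel of a flagged source voxel evaluate to NaN (the singular voxel
        carries no dose value).
        """
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.axes_cm, self.values, method="linear", bounds_error=True
            )
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        bad = ~self.contains(pts)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} sample point(s) outside grid extent "
                f"{self.extent_cm}; first offender {pts[bad][0]}"
            )
        return self._interp(pts)


@dataclass
class DepthDoseCurve:
    """Transverse-axis (theta = 90 deg) dose versus radial distance.

    ``radii`` are strictly increasing, cm; ``doses`` are positive,
    cGy/h/uA.  For physically sensible kernels the curve is monotone
    non-increasing beyond ~0.5 cm, but that is not enforced: test kernels
    may be deliberately unphysical.
    """

    radii: np.ndarray
    doses: np.ndarray
    medium: str = "water"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.radii.shape != self.doses.shape or self.radii.ndim != 1:
            raise ValueError("radii and doses must be 1-D arrays of equal length")
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if not np.all(self.radii > 0):
            raise ValueError("radii must be positive")
        if not np.all(self.doses > 0):
            raise ValueError("doses must be positive")
        self.medium = _normalize_medium(self.medium)


# -- long-format CSV I/O ---------------------------------------------------

_CSV_HEADER = "x_cm,y_cm,z_cm,dose_cGy_per_h_per_uA"


def write_grid_csv(grid: DoseGrid, path: str | Path, metadata: dict | None = None) -> None:
    """Write a dose grid as long-format CSV plus a plain-text sidecar.

    The sidecar ``<path>.meta`` records medium, voxel size, shape and
    origin (and any extra ``metadata`` key/values) so the grid round-trips
    through :func:`read_grid_csv`.
    """
    path = Path(path)
    x, y, z = grid.axes_cm
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    table = np.column_stack(
        [X.ravel(), Y.ravel(), Z.ravel(), grid.values.ravel()]
    )
    np.savetxt(path, table, delimiter=",", header=_CSV_HEADER, comments="", fmt="%.9g")
    meta = {
        "medium": grid.medium,
        "voxel_size_mm": repr(grid.voxel_size_mm),
        "shape": " ".join(str(n) for n in grid.values.shape),
        "origin": " ".join(repr(float(o)) for o in grid.origin),
    }
    if grid.source_voxel is not None:
        meta["source_voxel"] = " ".join(str(int(i)) for i in grid.source_voxel)
    if metadata:
        meta.update({str(k): str(v) for k, v in metadata.items()})
    sidecar = Path(str(path) + ".meta")
    sidecar.write_text(
        "".join(f"{k}: {v}\n" for k, v in meta.items()), encoding="utf-8"
    )


def read_grid_csv(path: str | Path) -> DoseGrid:
    """Read a dose grid written by :func:`write_grid_csv`."""
    path = Path(path)
    sidecar = Path(str(path) + ".meta")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta: dict[str, str] = {}
    for line in sidecar.read_text(encoding="utf-8").splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    shape = tuple(int(s) for s in meta["shape"].split())
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    values = data[:, 3].reshape(shape)
    source_voxel = None
    if "source_voxel" in meta:
        source_voxel = tuple(int(s) for s in meta["source_voxel"].split())
    return DoseGrid(
        values=values,
        voxel_size_mm=float(meta["voxel_size_mm"]),
        origin=tuple(float(s) for s in meta["origin"].split()),
        medium=meta["medium"],
        source_voxel=source_voxel,
    )
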