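"""Measurement uncertainty budgets with quadrature combination.

Follows the standard brachytherapy dosimetry practice: components are
classed Type A (statistically evaluated, e.g. repeated film readings) or
Type B (systematic, e.g. film energy dependence taken from literature),
expressed in percent throughout, combined in quadrature within each type,
and the total is the quadrature of the two sums.

Two estimators specific to voxelized Monte-Carlo-style dose grids are
included: a dose-weighted mean of per-voxel relative errors (the global
statistical uncertainty of a scored grid) and a uniform-distribution
geometric uncertainty (max-min)/(2 * mean * sqrt(3)) over a thin
transverse ring, which captures the sensitivity of a point estimate to
voxel alignment in steep dose gradients near the source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .grids import DoseGrid

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "quadrature_sum",
    "combine_budget",
    "mc_geometric_uncertainty",
    "mc_statistical_uncertainty",
    "transverse_ring_doses",
    "default_components",
]


@dataclass(frozen=True)
class UncertaintyComponent:
    """One named budget entry, in percent, typed A or B."""

    name: str
    value: float  # percent
    type: Literal["A", "B"]
    source: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("uncertainty components must be >= 0")
        if self.type not in ("A", "B"):
            raise ValueError("component type must be 'A' or 'B'")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined budget: per-type quadrature sums and the overall total."""

    components: tuple[UncertaintyComponent, ...]
    quadrature_sum_a: float
    quadrature_sum_b: float
    total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.name, c.value, c.type, c.source) for c in self.components
        ]
        return pd.DataFrame(rows, columns=["name", "value_percent", "type", "source"])


def quadrature_sum(values: Iterable[float]) -> float:
    """sqrt(sum of squares); permutation-invariant and degree-1 homogeneous."""
    arr = np.asarray(list(values), dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative component in quadrature sum")
    return float(np.sqrt(np.sum(arr**2)))


def combine_budget(
    components: Sequence[UncertaintyComponent],
) -> UncertaintyBudget:
    """Combine typed components: per-type quadrature, total in quadrature.

    The total always equals sqrt(A_sum^2 + B_sum^2) of the supplied
    components; any additional printed total that differs from the strict
    quadrature is a reporting discrepancy, not something this function
    reproduces.
    """
    comps = tuple(components)
    for c in comps:
        if not isinstance(c, UncertaintyComponent):
            raise TypeError("components must be UncertaintyComponent instances")
    sum_a = quadrature_sum(c.value for c in comps if c.type == "A")
    sum_b = quadrature_sum(c.value for c in comps if c.type == "B")
    return UncertaintyBudget(
        components=comps,
        quadrature_sum_a=sum_a,
        quadrature_sum_b=sum_b,
        total=quadrature_sum([sum_a, sum_b]),
    )


def mc_geometric_uncertainty(region_doses: Sequence[float]) -> float:
    """Uniform-distribution geometric uncertainty of a scoring region, percent.

    100 * (max - min) / (2 * mean * sqrt(3)) over the doses of the voxels
    in the region; invariant under uniform scaling of the doses.  Larger
    near the source, where the dose gradient across a 1 mm ring is
    steeper.
    """
    doses = np.asarray(region_doses, dtype=float)
    doses = doses[np.isfinite(doses)]
    if doses.size == 0:
        raise ValueError("empty scoring region")
    mean = doses.mean()
    if mean <= 0:
        raise ValueError("region mean dose must be positive")
    return float(100.0 * (doses.max() - doses.min()) / (2.0 * mean * np.sqrt(3.0)))


def mc_statistical_uncertainty(
    relative_errors: Sequence[float], doses: Sequence[float]
) -> float:
    """Dose-weighted mean of per-voxel relative errors.

    sum(e_i * D_i) / sum(D_i); returned in the units of ``relative_errors``
    (pass percent to get percent).
    """
    e = np.asarray(relative_errors, dtype=float)
    d = np.asarray(doses, dtype=float)
    if e.shape != d.shape:
        raise ValueError("relative_errors and doses must have equal shape")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    total = d.sum()
    if total <= 0:
        raise ValueError("total dose must be positive")
    return float(np.sum(e * d) / total)


def transverse_ring_doses(
    grid: DoseGrid, r_cm: float, half_width_mm: float = 0.5
) -> np.ndarray:
    """Doses of voxels whose centres lie on a thin transverse ring.

    The ring is all voxel centres within ``half_width_mm`` of the
    transverse plane and within ``half_width_mm`` of radius ``r_cm`` from
    the source axis — the 1-mm radial scoring region used for the
    grid-based uncertainty estimators.
    """
    x, y, z = grid.axes_cm
    hw = half_width_mm / 10.0
    kz = np.abs(z) <= hw + 1e-12
    X, Y = np.meshgrid(x, y, indexing="ij")
    ring = np.abs(np.sqrt(X**2 + Y**2) - r_cm) <= hw + 1e-12
    vals = grid.values[:, :, kz][ring, :]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no voxels on the r = {r_cm} cm transverse ring")
    return vals


def default_components() -> tuple[UncertaintyComponent, ...]:
    """The packaged film-measurement budget components.

    Literature-sourced values are data, not computation; they are loaded
    from the checksummed fixture table.
    """
    from .fixtures import load_fixtures

    df = load_fixtures().uncertainty_components
    return tuple(
        UncertaintyComponent(
            name=row["name"],
            value=float(row["value_percent"]),
            type=row["type"],
            source=row["source"],
        )
        for _, row in df.iterrows()
    )
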