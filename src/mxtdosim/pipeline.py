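"""End-to-end analysis: simulate, extract, convert, budget, report.

``run_pipeline`` executes the full characterization exactly as it would
be performed against Monte-Carlo output for the real source: generate
ABS and water dose grids, extract transverse depth-dose curves, derive
the ABS-to-water conversion function, extract the TG-43 parameters in
ABS along both the grid path and the film-plane path, convert to water,
confront the result with the packaged reference tables, and assemble the
uncertainty budget — writing a reproducible report bundle whose bytes
depend only on the configuration and seed.

``regression_report`` is the codified self-test of the packaged
reference tables: it recomputes every headline summary statistic from
the raw fixture columns and compares with the printed value at printed
precision, listing (rather than hiding) the known discrepancies of the
source tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .conversion import ConversionFunction, apply_cf, derive_cf
from .film import map_film_plane_to_polar
from .fixtures import FixtureTables, load_fixtures
from .grids import DepthDoseCurve, DoseGrid
from .source import (
    KernelParams,
    SourceSpec,
    default_kernel_params,
    extract_depth_dose,
    generate_dose_grid,
    sample_film_plane,
)
from .tg43 import (
    AzimuthalRatios,
    Tg43ParameterSet,
    TableComparison,
    anisotropy_function,
    azimuthal_ratios,
    bin_polar_samples,
    compare_tables,
    dose_rate_constant,
    polar_samples_from_grid,
    radial_dose_function,
)
from .uncertainty import (
    UncertaintyBudget,
    combine_budget,
    default_components,
    mc_geometric_uncertainty,
    mc_statistical_uncertainty,
    transverse_ring_doses,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "regression_report"]


def _default_thetas() -> tuple[float, ...]:
    return tuple(float(t) for t in range(0, 100, 10))


def _default_azimuths() -> tuple[float, ...]:
    return tuple(float(p) for p in range(0, 210, 30))


@dataclass
class PipelineConfig:
    """Reproducible configuration of a full pipeline run.

    Angles in degrees, distances in cm, doses in cGy/h/uA.  ``g_radii``
    and ``f_radii`` default to the tabulation lattices of the packaged
    reference tables (22 radii 1.0-5.0 cm; 18 radii 1.0-4.2 cm).  The
    film-measurable polar subset is bounded below by
    ``film_theta_min_deg``.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (105, 105, 89)
    voxel_size_mm: float = 1.0
    media: tuple[str, ...] = ("water", "abs")
    r0_cm: float = 1.0
    theta0_deg: float = 90.0
    g_radii: Optional[tuple[float, ...]] = None
    f_radii: Optional[tuple[float, ...]] = None
    f_thetas_deg: tuple[float, ...] = field(default_factory=_default_thetas)
    film_theta_min_deg: float = 20.0
    azimuth_deg: tuple[float, ...] = field(default_factory=_default_azimuths)
    film_offset_cm: float = 1.0
    noise_sd: float = 0.007
    kernel: Optional[KernelParams] = None
    source: SourceSpec = field(default_factory=SourceSpec)

    def __post_init__(self) -> None:
        if self.r0_cm <= 0:
            raise ValueError("r0 must be positive")
        for name in ("g_radii", "f_radii"):
            radii = getattr(self, name)
            if radii is not None and not np.all(np.diff(radii) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    def resolved_kernel(self) -> KernelParams:
        if self.kernel is not None:
            k = self.kernel
            return k if k.seed is not None else replace(k, seed=self.seed)
        return default_kernel_params(noise_sd=self.noise_sd, seed=self.seed)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run produces, before/beside the on-disk report."""

    config: PipelineConfig
    grids: dict[str, DoseGrid]
    depth_dose: dict[str, DepthDoseCurve]
    cf: ConversionFunction
    lambda_abs: float
    lambda_water: float
    parameters_water: Tg43ParameterSet
    g_abs: pd.DataFrame
    g_water_direct: pd.DataFrame
    f_film: pd.DataFrame
    azimuthal: AzimuthalRatios
    comparison_g_water: TableComparison
    comparison_g_ratio: TableComparison
    budget: UncertaintyBudget
    mc_uncertainty: dict[str, float]


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full characterization; optionally write the report bundle.

    Stages run in a fixed order and any failure is re-raised annotated
    with the stage name and offending input, so a broken configuration
    fails loudly rather than producing a partial report.
    """
    stage = "configuration"
    try:
        fixtures = load_fixtures()
        g_radii = np.asarray(
            config.g_radii
            if config.g_radii is not None
            else fixtures.radial_dose["r_cm"].to_numpy(),
            dtype=float,
        )
        f_radii = np.asarray(
            config.f_radii
            if config.f_radii is not None
            else np.unique(fixtures.anisotropy_mc["r_cm"].to_numpy()),
            dtype=float,
        )
        params = config.resolved_kernel()

        stage = "grid generation"
        grids = {
            m: generate_dose_grid(
                config.source, params, m, config.grid_shape, config.voxel_size_mm
            )
            for m in config.media
        }

        stage = "depth-dose extraction"
        depth_dose = {
            m: extract_depth_dose(grids[m], g_radii) for m in config.media
        }

        stage = "conversion-function derivation"
        cf = derive_cf(depth_dose["water"], depth_dose["abs"])

        stage = "TG-43 extraction (grid path)"
        d_ref_abs = float(
            np.interp(config.r0_cm, depth_dose["abs"].radii, depth_dose["abs"].doses)
        )
        lambda_abs = dose_rate_constant(d_ref_abs)
        g_abs = radial_dose_function(depth_dose["abs"], r0=config.r0_cm)
        g_water_direct = radial_dose_function(depth_dose["water"], r0=config.r0_cm)
        samples_water = polar_samples_from_grid(
            grids["water"], f_radii, config.f_thetas_deg
        )
        f_water = anisotropy_function(samples_water, theta0=config.theta0_deg)

        stage = "TG-43 extraction (film-plane path)"
        film_plane = sample_film_plane(grids["abs"], offset_cm=config.film_offset_cm)
        film_samples = map_film_plane_to_polar(
            film_plane, min_theta_deg=config.film_theta_min_deg
        )
        film_binned = bin_polar_samples(
            film_samples,
            f_radii,
            [t for t in config.f_thetas_deg],
        )
        # the reach rule applies to the lattice points themselves: a cell
        # with r*sin(theta) < offset only collects one-sided edge pixels
        reach = film_binned.r_cm * np.sin(np.radians(film_binned.theta_deg))
        film_binned.valid &= reach >= config.film_offset_cm - 1e-9
        import warnings as _warnings

        with _warnings.catch_warnings():
            # radii whose transverse point is off the film plane mask themselves
            _warnings.simplefilter("ignore")
            f_film = anisotropy_function(film_binned, theta0=config.theta0_deg)

        stage = "azimuthal extraction"
        phi = np.asarray(config.azimuth_deg, dtype=float)
        pts = np.column_stack(
            [
                config.r0_cm * np.cos(np.radians(phi)),
                config.r0_cm * np.sin(np.radians(phi)),
                np.zeros_like(phi),
            ]
        )
        azimuth_doses = grids["abs"].interpolate(pts)
        azimuth = azimuthal_ratios(list(zip(phi, azimuth_doses)))

        stage = "water conversion"
        lambda_water = apply_cf(lambda_abs, cf, r=config.r0_cm)
        g_water_converted = apply_cf(g_abs, cf, r0=config.r0_cm)

        stage = "comparison statistics"
        ref = fixtures.radial_dose.set_index("r_cm")
        extracted = g_water_converted.set_index("r_cm")["g"]
        comparison_g_water = compare_tables(
            extracted, ref["g_water_mc"].reindex(extracted.index), mode="difference"
        )
        comparison_g_ratio = compare_tables(
            g_water_direct.set_index("r_cm")["g"],
            g_abs.set_index("r_cm")["g"],
            mode="ratio",
        )

        stage = "uncertainty budget"
        budget = combine_budget(default_components())
        ring1 = transverse_ring_doses(grids["water"], 1.0)
        ring3 = transverse_ring_doses(grids["water"], 3.0)
        rel_err_pct = np.full(grids["water"].values.size, 100.0 * params.noise_sd)
        doses_flat = np.nan_to_num(grids["water"].values.ravel(), nan=0.0)
        mc_unc = {
            "geometric_1cm_percent": mc_geometric_uncertainty(ring1),
            "geometric_3cm_percent": mc_geometric_uncertainty(ring3),
            "statistical_percent": mc_statistical_uncertainty(rel_err_pct, doses_flat),
        }

        parameters_water = Tg43ParameterSet(
            dose_rate_constant=lambda_water,
            g_table=g_water_converted,
            f_table=f_water,
            azimuthal=azimuth,
            medium="water",
            provenance="simulated",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        grids=grids,
        depth_dose=depth_dose,
        cf=cf,
        lambda_abs=lambda_abs,
        lambda_water=lambda_water,
        parameters_water=parameters_water,
        g_abs=g_abs,
        g_water_direct=g_water_direct,
        f_film=f_film,
        azimuthal=azimuth,
        comparison_g_water=comparison_g_water,
        comparison_g_ratio=comparison_g_ratio,
        budget=budget,
        mc_uncertainty=mc_unc,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


# -- report bundle ---------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the report bundle: CSV tables plus a markdown summary.

    The file set and bytes are identical for identical configurations and
    seeds (no timestamps; fixed float formatting); provenance carries the
    seed, a configuration hash and the package version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _to_csv(df, path)
        written.append(path)

    for medium, curve in result.depth_dose.items():
        emit(
            f"depth_dose_{medium}.csv",
            pd.DataFrame({"r_cm": curve.radii, "dose_cGy_per_h_per_uA": curve.doses}),
        )
    emit("conversion_function.csv", result.cf.to_frame())
    emit("g_water.csv", result.parameters_water.g_table)
    emit("g_abs.csv", result.g_abs)
    emit("f_water.csv", result.parameters_water.f_table)
    emit("f_film.csv", result.f_film)
    emit("azimuthal_ratios.csv", result.azimuthal.table)
    emit("uncertainty_budget.csv", result.budget.to_frame())
    comp = result.comparison_g_water.values.rename("difference").reset_index()
    emit("comparison_g_water.csv", comp)

    lines = [
        "# TG-43 characterization report",
        "",
        f"- package version: {__version__}",
        f"- seed: {cfg.seed}",
        f"- config hash: {cfg.config_hash()}",
        f"- grid: {cfg.grid_shape} voxels at {cfg.voxel_size_mm} mm",
        "",
        "## Headline parameters",
        "",
        f"- dose-rate constant (ABS, per uA): {result.lambda_abs:.2f} cGy/h/uA",
        f"- dose-rate constant (water, per uA): {result.lambda_water:.2f} cGy/h/uA",
        f"- CF(1 cm) = {float(result.cf(1.0)):.4f}; CF(5 cm) = {float(result.cf(5.0)):.4f};"
        f" conversion RMSE = {result.cf.rmse:.4g}",
        f"- azimuthal max ratio {result.azimuthal.max_ratio:.3f}"
        f" at {result.azimuthal.argmax_phi_deg:.0f} deg",
        "",
        "## Agreement with the reference tables",
        "",
        f"- water g(r), converted vs reference: mean diff "
        f"{result.comparison_g_water.mean:+.4f}, SD {result.comparison_g_water.sd:.4f}, "
        f"max |diff| {result.comparison_g_water.max_abs:.4f} at r = "
        f"{result.comparison_g_water.argmax} cm",
        f"- extracted water/ABS g ratio: mean {result.comparison_g_ratio.mean:.4f}",
        "",
        "## Uncertainty",
        "",
        f"- Type A quadrature: {result.budget.quadrature_sum_a:.2f}%",
        f"- Type B quadrature: {result.budget.quadrature_sum_b:.2f}%",
        f"- total (strict quadrature): {result.budget.total:.2f}%",
        f"- grid geometric uncertainty: "
        f"{result.mc_uncertainty['geometric_1cm_percent']:.2f}% at 1 cm, "
        f"{result.mc_uncertainty['geometric_3cm_percent']:.2f}% at 3 cm",
        f"- grid statistical uncertainty (dose-weighted): "
        f"{result.mc_uncertainty['statistical_percent']:.2f}%",
        "",
    ]
    summary = out / "summary.md"
    summary.write_text("\n".join(lines), encoding="utf-8")
    written.append(summary)
    return written


# -- fixture regression ----------------------------------------------------


def regression_report(fixtures: FixtureTables | None = None) -> pd.DataFrame:
    """Recompute the headline summary statistics from the raw fixture columns.

    Returns a table with one row per statistic: the value recomputed from
    the packaged columns, the printed value, the comparison tolerance
    (half a unit of the printed precision unless noted), whether they
    agree, and whether the row is asserted by the test suite.  Rows with
    ``asserted=False`` document known discrepancies of the printed
    source tables (see FIXTURE_NOTES.md); they are reported, not hidden.
    """
    ft = fixtures if fixtures is not None else load_fixtures()
    t1 = ft.radial_dose
    s = ft.summary
    rows: list[tuple[str, float, float, float, bool]] = []

    def add(name, computed, printed, tol=0.005, asserted=True):
        rows.append((name, float(computed), float(printed), float(tol), asserted))

    ratio = t1["g_water_mc"] / t1["g_abs_mc"]
    add("g ratio water/ABS: mean", ratio.mean(), s["g_ratio_water_abs_mean"])
    add("g ratio water/ABS: printed-column mean", t1["ratio_water_abs_mc"].mean(),
        s["g_ratio_water_abs_mean"])
    add("g ratio water/ABS: SD", ratio.std(ddof=1), s["g_ratio_water_abs_sd"],
        tol=0.01)

    dw = (t1["g_water_mc"] - t1["g_water_ebt"]).iloc[1:]
    add("water g diff MC-film: signed mean", dw.mean(), s["g_water_diff_mean"])
    da = (t1["g_abs_mc"] - t1["g_abs_ebt"]).iloc[1:]
    idx = t1.set_index("r_cm")
    for r in (2.0, 3.0, 4.0, 5.0):
        add(
            f"ABS g diff MC-film at {r:g} cm",
            idx.loc[r, "g_abs_mc"] - idx.loc[r, "g_abs_ebt"],
            s[f"g_abs_diff_at_{r:g}cm"],
        )
    diffs = (t1["g_abs_mc"] - t1["g_abs_ebt"]).to_numpy()[1:]
    r_at = t1["r_cm"].to_numpy()[1:]
    add("ABS g diff MC-film: max", np.nanmax(diffs), s["g_abs_diff_max"])
    add("ABS g diff MC-film: argmax radius", r_at[int(np.nanargmax(diffs))],
        s["g_abs_diff_argmax_r_cm"], tol=0.05)
    # printed column mean is 0.07 while the source text rounds to 0.06
    add("ABS g diff MC-film: signed mean", da.mean(), s["g_abs_diff_mean"])

    xr = ft.xr_radial_dose.set_index("r_cm")["g_abs_xr"]
    for r in (2.0, 3.0, 4.0, 5.0):
        add(
            f"XR-film g diff at {r:g} cm",
            xr.loc[r] - idx.loc[r, "g_abs_ebt"],
            s[f"xr_ebt_diff_at_{r:g}cm"],
        )

    az = ft.azimuthal
    imax = int(az["ratio"].idxmax())
    add("azimuthal max ratio", az.loc[imax, "ratio"], s["azimuthal_max_ratio"])
    add("azimuthal argmax angle", az.loc[imax, "phi_deg"],
        s["azimuthal_argmax_phi_deg"], tol=0.5)

    fr = ft.anisotropy_ratio
    jmax = int(fr["value"].idxmax())
    jmin = int(fr["value"].idxmin())
    add("F ratio film/MC: max", fr.loc[jmax, "value"], s["f_ratio_max"])
    add("F ratio film/MC: argmax r", fr.loc[jmax, "r_cm"], s["f_ratio_argmax_r_cm"],
        tol=0.05)
    add("F ratio film/MC: argmax theta", fr.loc[jmax, "theta_deg"],
        s["f_ratio_argmax_theta_deg"], tol=0.5)
    add("F ratio film/MC: min", fr.loc[jmin, "value"], s["f_ratio_min"])
    add("F ratio film/MC: argmin r", fr.loc[jmin, "r_cm"], s["f_ratio_argmin_r_cm"],
        tol=0.05)
    add("F ratio film/MC: argmin theta", fr.loc[jmin, "theta_deg"],
        s["f_ratio_argmin_theta_deg"], tol=0.5)

    comps = ft.uncertainty_components
    b_sum = float(
        np.sqrt((comps.loc[comps["type"] == "B", "value_percent"] ** 2).sum())
    )
    a_sum = float(
        np.sqrt((comps.loc[comps["type"] == "A", "value_percent"] ** 2).sum())
    )
    add("Type B quadrature sum", b_sum, s["type_b_quadrature_percent"])
    add("Type A quadrature sum", a_sum, s["type_a_quadrature_percent"])
    # strict quadrature vs the printed total: a known reporting discrepancy
    add("total uncertainty (strict quadrature vs printed)",
        float(np.hypot(a_sum, b_sum)), s["total_uncertainty_printed_percent"],
        asserted=False)
    # Lambda_water / Lambda_abs vs the printed rounded CF at 1 cm: known
    # rounding inconsistency of the source values
    add("implied conversion factor at 1 cm vs printed",
        s["lambda_water_cgy_h_ua"] / s["lambda_abs_cgy_h_ua"], s["cf_at_1cm"],
        asserted=False)

    df = pd.DataFrame(
        rows, columns=["statistic", "computed", "printed", "tol", "asserted"]
    )
    df["agrees"] = (df["computed"] - df["printed"]).abs() <= df["tol"]
    return df
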