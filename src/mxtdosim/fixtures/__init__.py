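"""Packaged reference tables for the miniature X-ray tube source.

The CSVs under ``mxtdosim/fixtures/`` transcribe the published
characterization of this source: radial dose functions g(r) in ABS and
water (Monte Carlo, film, and XR multidetector), the anisotropy-function
blocks F(r, theta) with their validity masks, azimuthal ratios, the
measurement uncertainty budget, and the headline summary statistics.
``FIXTURE_NOTES.md`` in the same directory documents transcription
choices and the known internal inconsistencies of the printed tables.

Fixture values are immutable; every file is SHA-256 checksummed at load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTables", "load_fixtures", "FixtureIntegrityError"]


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


#: SHA-256 of each packaged CSV, frozen at transcription time.
_CHECKSUMS: dict[str, str] = {
    "anisotropy_ebt.csv": "35b6dc6c2baac868bd8011dad68c50986d0b9c263a7c7e00111dfe43773ad5ed",
    "anisotropy_mc.csv": "21de2ab8cca6c7fbe2b680cbb9750bb706b2ff3c417bd7b6da48019b1cd3e869",
    "anisotropy_ratio.csv": "92e495c76cc7a56a5f217ecd5c14e375d99e03dd513faf308629fb5610aadd36",
    "azimuthal.csv": "9e287866b7ee67510ef056fd2c89effd12c59bb5efc172f372d316b3f4590a26",
    "radial_dose.csv": "a26ace047e3f1391af69cd3ffb3dab52c92e03f2126741b223320880ca8c4a8f",
    "summary_stats.csv": "de83d129cc0e5783980e5e2e586ef8ab83c9d831f3e6f5acd81f8262941f533d",
    "uncertainty_components.csv": "542d071e54d6ac6b28dd2ae697e8f056b57868dfebedf95ca30376910a5cd5cc",
    "xr_radial_dose.csv": "6ef93fdf10fb8a24739c926d9d11146b590c52d7039af8d8bd3c2e1a875eac25",
}


@dataclass(frozen=True)
class FixtureTables:
    """Typed view of the packaged reference tables.

    Attributes
    ----------
    radial_dose
        22 radii (1.0-5.0 cm) with the four g(r) columns
        (ABS/water x MC/film), the printed water/ABS MC ratio column and
        the two printed difference columns.
    anisotropy_ebt, anisotropy_mc, anisotropy_ratio
        Long-format F(r, theta) blocks (film-measured in water, Monte
        Carlo in water, and their ratio) with an ``uncertain`` flag on
        cells whose radius assignment in the ragged printed rows is
        ambiguous.
    azimuthal
        Dose ratios versus azimuthal angle, normalized at 0 deg.
    uncertainty_components
        The published budget components (name, percent, Type A/B, source).
    xr_radial_dose
        g(r) in ABS measured with the XR multidetector at 2-5 cm.
    summary
        Headline printed statistics as a name -> value mapping.
    """

    radial_dose: pd.DataFrame
    anisotropy_ebt: pd.DataFrame
    anisotropy_mc: pd.DataFrame
    anisotropy_ratio: pd.DataFrame
    azimuthal: pd.DataFrame
    uncertainty_components: pd.DataFrame
    xr_radial_dose: pd.DataFrame
    summary: dict[str, float]


def _read(name: str, verify: bool = True) -> pd.DataFrame:
    ref = resources.files(__package__).joinpath(name)
    raw = ref.read_bytes()
    if verify:
        expected = _CHECKSUMS.get(name)
        digest = hashlib.sha256(raw).hexdigest()
        if expected is not None and digest != expected:
            raise FixtureIntegrityError(
                f"fixture {name} checksum {digest} != recorded {expected}"
            )
        if expected is None:
            raise FixtureIntegrityError(f"fixture {name} has no recorded checksum")
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_fixtures(verify: bool = True) -> FixtureTables:
    """Load all packaged reference tables, verifying checksums by default."""
    summary_df = _read("summary_stats.csv", verify)
    return FixtureTables(
        radial_dose=_read("radial_dose.csv", verify),
        anisotropy_ebt=_read("anisotropy_ebt.csv", verify),
        anisotropy_mc=_read("anisotropy_mc.csv", verify),
        anisotropy_ratio=_read("anisotropy_ratio.csv", verify),
        azimuthal=_read("azimuthal.csv", verify),
        uncertainty_components=_read("uncertainty_components.csv", verify),
        xr_radial_dose=_read("xr_radial_dose.csv", verify),
        summary=dict(zip(summary_df["name"], summary_df["value"].astype(float))),
    )
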