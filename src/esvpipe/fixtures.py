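"""Vendored study constants: coefficient table, published ESV table,
disturbance coefficients, and areas back-derived from the published values.

All files live under ``esvpipe/data`` as plain CSV with a SHA-256 manifest;
loading verifies the checksums so silent fixture corruption is caught at the
source rather than as a mysterious numeric drift downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .esv import EsvCoefficients

__all__ = [
    "PaperFixtures",
    "FixtureError",
    "load_fixtures",
    "load_reclass_mapping",
    "STANDARD_EQUIVALENT",
    "TOTAL_AREA_KM2",
    "STUDY_YEARS",
    "HORIZON_YEARS",
]

#: value of one standard ESV equivalent, yuan/hm² (2010 crop statistics)
STANDARD_EQUIVALENT: float = 1793.88
#: total study area, km²
TOTAL_AREA_KM2: float = 60_500.0
#: survey years of the land-use series
STUDY_YEARS: tuple[int, ...] = (2000, 2005, 2010, 2018)
#: length of the full study period, years
HORIZON_YEARS: int = 18

#: the published ESV table covers only these five classes (construction land
#: is valued at zero; unused land's contribution is negligible and omitted)
TABULATED_CLASSES: tuple[str, ...] = ("CL", "WO", "GL", "WA", "WL")


class FixtureError(RuntimeError):
    """A vendored fixture file is missing or fails its checksum."""


def _data_dir() -> Path:
    return Path(str(resources.files("esvpipe") / "data"))


def _read_verified(name: str) -> pd.DataFrame:
    data = _data_dir()
    manifest = data / "checksums.sha256"
    if not manifest.exists():
        raise FixtureError("fixture checksum manifest is missing")
    sums = dict(
        line.split()[::-1]
        for line in manifest.read_text().splitlines()
        if line.strip()
    )
    path = data / name
    if not path.exists():
        raise FixtureError(f"fixture file missing: {name}")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if name not in sums:
        raise FixtureError(f"fixture file not in manifest: {name}")
    if digest != sums[name]:
        raise FixtureError(f"fixture file corrupted (checksum mismatch): {name}")
    return pd.read_csv(path)


@dataclass
class PaperFixtures:
    """The full constant set of the study, in internal units (yuan, hm²)."""

    coefficients: EsvCoefficients
    esv_table: pd.DataFrame  # year, zone, class, function, yuan
    standard_equivalent: float
    pi: dict[str, float]
    total_area_km2: float
    study_years: tuple[int, ...]
    horizon: int
    implied_areas: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def load_fixtures() -> PaperFixtures:
    """Load and checksum-verify every vendored constant."""
    coef_df = (
        _read_verified("esv_coefficients.csv")
        .pivot(index="class", columns="function", values="yuan_per_hm2")
    )
    coefficients = EsvCoefficients(values=coef_df, eb=STANDARD_EQUIVALENT)

    table = _read_verified("esv_by_class_function.csv")
    esv = table.assign(
        zone="study_area", yuan=table["billion_yuan"] * 1e9
    )[["year", "zone", "class", "function", "yuan"]]
    esv.attrs["provenance"] = "fixture"

    pi_df = _read_verified("disturbance_coefficients.csv")
    pi = dict(zip(pi_df["class"], pi_df["pi"].astype(float)))

    implied = _read_verified("implied_areas.csv").assign(zone="study_area")[
        ["year", "zone", "class", "area_hm2"]
    ]

    return PaperFixtures(
        coefficients=coefficients,
        esv_table=esv,
        standard_equivalent=STANDARD_EQUIVALENT,
        pi=pi,
        total_area_km2=TOTAL_AREA_KM2,
        study_years=STUDY_YEARS,
        horizon=HORIZON_YEARS,
        implied_areas=implied,
    )


def load_reclass_mapping() -> dict[int, int]:
    """Default raw-survey-code → 7-class mapping (editable CSV)."""
    df = _read_verified("cnlucc_reclass.csv")
    return dict(zip(df["raw_code"].astype(int), df["class_code"].astype(int)))
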