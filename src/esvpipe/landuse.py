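"""Land-use accounting: reclassification, zonal area tables, transition
matrices and the single-land-use dynamic degree.

Grids are row-major integer rasters, origin top-left; zone maps must share the
grid shape exactly (no resampling). Areas are in hm²; one raster cell of the
source data is 1 km² = 100 hm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, HM2_PER_KM2

__all__ = [
    "LandUseGrid",
    "ZoneMap",
    "TransitionMatrix",
    "reclassify",
    "tabulate_areas",
    "transitions",
    "dynamic_degree",
    "DEFAULT_ZERO_FLOOR_HM2",
]

#: 1 km² in hm²; the area floor used when a class had (effectively) zero area
#: in the base year, so its dynamic degree stays finite.
DEFAULT_ZERO_FLOOR_HM2: float = 1.0 * HM2_PER_KM2

N_CLASSES = len(CLASS_ORDER)


@dataclass
class LandUseGrid:
    """A single-year categorical land-use raster.

    codes holds integer class codes 1..7 (``classes.CLASS_CODES``) with
    ``nodata`` marking unclassified cells; ``cell_area`` is hm² per cell.
    """

    codes: np.ndarray
    year: int
    cell_area: float = HM2_PER_KM2
    nodata: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        valid = self.codes[self.codes != self.nodata]
        if valid.size and (valid.min() < 1 or valid.max() > N_CLASSES):
            raise ValueError(
                f"class codes outside 1..{N_CLASSES}: "
                f"{sorted(set(valid[(valid < 1) | (valid > N_CLASSES)].tolist()))}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape


@dataclass
class ZoneMap:
    """Integer zone labels aligned to the land-use grids it partitions."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    nodata: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("zone map must be 2-D")

    @property
    def zone_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(z) for z in ids if z != self.nodata]


@dataclass
class TransitionMatrix:
    """Class-to-class area flows between two years (hm²).

    ``matrix`` is a 7×7 DataFrame indexed by source class (rows) and
    destination class (columns); the diagonal is unchanged area.
    """

    matrix: pd.DataFrame
    from_year: int
    to_year: int

    @property
    def row_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)


def reclassify(
    raw: np.ndarray,
    mapping: dict[int, int],
    year: int,
    cell_area: float = HM2_PER_KM2,
    nodata: int = 0,
) -> LandUseGrid:
    """Map raw survey codes onto the 7-class scheme.

    Every observed non-nodata code must appear in ``mapping``; otherwise a
    ValueError listing all offending codes is raised. Cell count and shape
    are preserved.
    """
    raw = np.asarray(raw)
    observed = np.unique(raw)
    missing = sorted(
        int(c) for c in observed if c != nodata and int(c) not in mapping
    )
    if missing:
        raise ValueError(f"unmapped raw codes: {missing}")

    out = np.full(raw.shape, nodata, dtype=np.int64)
    for code in observed:
        code = int(code)
        if code == nodata:
            continue
        out[raw == code] = mapping[code]
    return LandUseGrid(out, year=year, cell_area=cell_area, nodata=nodata)


def _check_aligned(grid: LandUseGrid, zones: ZoneMap) -> None:
    if grid.shape != zones.labels.shape:
        raise ValueError(
            f"grid shape {grid.shape} != zone map shape {zones.labels.shape}"
        )


def tabulate_areas(grid: LandUseGrid, zones: ZoneMap) -> pd.DataFrame:
    """Cross-tabulate class areas per zone.

    Returns a tidy frame with columns ``year, zone, class, area_hm2`` holding
    every (zone, class) pair, zeros included, so downstream joins never drop
    absent classes.
    """
    _check_aligned(grid, zones)
    valid = (grid.codes != grid.nodata) & (zones.labels != zones.nodata)
    zone_ids = zones.zone_ids
    zindex = {z: i for i, z in enumerate(zone_ids)}

    z = np.vectorize(zindex.get, otypes=[np.int64])(zones.labels[valid]) if valid.any() else np.array([], dtype=np.int64)
    c = grid.codes[valid] - 1
    counts = np.bincount(
        z * N_CLASSES + c, minlength=len(zone_ids) * N_CLASSES
    ).reshape(len(zone_ids), N_CLASSES)

    records = []
    for zi, zone in enumerate(zone_ids):
        for ci, abbr in enumerate(CLASS_ORDER):
            records.append(
                (grid.year, zone, abbr, counts[zi, ci] * grid.cell_area)
            )
    return pd.DataFrame(records, columns=["year", "zone", "class", "area_hm2"])


def transitions(
    a: LandUseGrid,
    b: LandUseGrid,
    zones: ZoneMap | None = None,
) -> TransitionMatrix | dict[int, TransitionMatrix]:
    """Cross-tabulate cellwise class flows from grid ``a`` to grid ``b``.

    With ``zones`` given, one matrix per zone is returned as a dict keyed by
    zone id. Cells that are nodata in either year are excluded.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if a.year >= b.year:
        raise ValueError("transitions require a.year < b.year")

    valid = (a.codes != a.nodata) & (b.codes != b.nodata)

    def _xtab(mask: np.ndarray) -> pd.DataFrame:
        src = a.codes[mask] - 1
        dst = b.codes[mask] - 1
        counts = np.bincount(
            src * N_CLASSES + dst, minlength=N_CLASSES * N_CLASSES
        ).reshape(N_CLASSES, N_CLASSES)
        return pd.DataFrame(
            counts * a.cell_area, index=CLASS_ORDER, columns=CLASS_ORDER
        )

    if zones is None:
        return TransitionMatrix(_xtab(valid), a.year, b.year)

    _check_aligned(a, zones)
    out: dict[int, TransitionMatrix] = {}
    for zone in zones.zone_ids:
        mask = valid & (zones.labels == zone)
        out[zone] = TransitionMatrix(_xtab(mask), a.year, b.year)
    return out


def dynamic_degree(
    la: float,
    lb: float,
    horizon: float,
    zero_floor: float = DEFAULT_ZERO_FLOOR_HM2,
) -> float:
    """Single land-use dynamic degree K, in percent per year.

    K = (Lb − La) / max(La, floor) × (1/H) × 100, where La, Lb are the class
    areas at the period's start and end and H the period length in years.
    The floor (default 100 hm² = 1 km²) keeps K finite for classes that were
    absent at the start, matching the convention of treating a vanished class
    as occupying one source cell.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if la < 0 or lb < 0:
        raise ValueError("areas must be non-negative")
    denom = max(la, zero_floor)
    return (lb - la) / denom / horizon * 100.0


def class_totals(areas: pd.DataFrame) -> pd.DataFrame:
    """Sum an area table over zones: (year, class) → hm²."""
    return (
        areas.groupby(["year", "class"], sort=False)["area_hm2"]
        .sum()
        .unstack("class")
        .reindex(columns=CLASS_ORDER)
        .fillna(0.0)
    )
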