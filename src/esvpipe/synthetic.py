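"""Synthetic multi-year landscapes and driver surfaces with known ground
truth.

The generator emulates the study region's data layout: a categorical 7-class
raster series (1 km² cells) over a few dozen contiguous county-like zones,
evolving by a cellwise Markov kernel dominated by cropland↔forest exchange,
plus zone-averaged driver covariates with planted correlations (GPP rises
with forest cover, population and GDP with construction cover, smooth climate
gradients, and a deliberately irrelevant PM2.5). Everything is a pure
function of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import CLASS_ORDER, HM2_PER_KM2
from .landuse import LandUseGrid, ZoneMap, tabulate_areas

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "default_transition_kernel",
    "generate_landscape",
    "generate_drivers",
    "planted_response",
    "zone_class_fractions",
]

N_CLASSES = len(CLASS_ORDER)

#: landscape composition resembling a lake-plain agricultural district:
#: cropland and forest dominate, construction and unused land small but
#: nonzero so the zero-floor path of the dynamic degree is exercised.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "CL": 0.42, "WO": 0.35, "GL": 0.02, "WA": 0.09,
    "CO": 0.035, "UL": 0.005, "WL": 0.08,
}

#: per-driver generation recipe. ``links`` maps land classes to linear
#: coefficients on the zone's class fraction; ``field_scale`` scales a
#: spatially smoothed noise surface; ``gradient`` adds a planar trend
#: (per normalized row, col); ``noise_sd`` is zone-level iid noise.
#: Smoothing widths are kept at or below the county scale (σ ≈ 4 cells for a
#: ~10-cell zone diameter) so every surface varies from zone to zone, as the
#: real county-averaged covariates do; each driver also carries its own
#: independent smooth component so no two drivers are near-duplicates.
DEFAULT_DRIVER_SPEC: dict[str, dict] = {
    "GPP":  {"base": 600.0, "links": {"WO": 900.0, "CL": 350.0, "WL": 250.0},
             "smoothness": 4.0, "field_scale": 60.0, "noise_sd": 40.0},
    "DEM":  {"base": 150.0, "links": {}, "smoothness": 4.0,
             "field_scale": 300.0, "noise_sd": 0.0, "static": True},
    "POP":  {"base": 150.0, "links": {"CO": 2500.0, "CL": 120.0},
             "smoothness": 4.0, "field_scale": 40.0, "noise_sd": 25.0},
    "GDP":  {"base": 30.0, "links": {"CO": 1200.0, "CL": 15.0},
             "smoothness": 4.0, "field_scale": 25.0, "noise_sd": 8.0},
    "Temp": {"base": 16.7, "links": {}, "gradient": (-0.5, 0.2),
             "smoothness": 4.0, "field_scale": 0.4, "noise_sd": 0.05},
    "Pre":  {"base": 1350.0, "links": {}, "gradient": (120.0, -60.0),
             "smoothness": 4.0, "field_scale": 80.0, "noise_sd": 10.0},
    "PM":   {"base": 45.0, "links": {}, "smoothness": 4.0,
             "field_scale": 8.0, "noise_sd": 2.0, "independent": True},
}

_SPEC_KEYS = {"base", "links", "smoothness", "field_scale", "noise_sd",
              "gradient", "static", "independent"}

#: ground-truth zone-level response coefficients on standardized features,
#: used by the attribution-recovery experiments: a dominant human-impact
#: term, a moderate productivity term, small everything else, no PM term.
DEFAULT_PLANTED_EFFECT: dict[str, float] = {
    "HAI": -6.0, "GPP": 2.0, "Slope": 0.5, "DEM": 0.5, "POP": 0.5,
    "Temp": 0.5, "GDP": 0.5, "Pre": 0.5, "PM": 0.0,
}


def default_transition_kernel() -> np.ndarray:
    """Row-stochastic 7×7 yearly-step kernel.

    Mostly persistent, with cropland↔forest exchange as the dominant flow,
    cropland loss to construction/water/wetland, and water↔wetland exchange —
    the qualitative flow structure of the study region.
    """
    K = np.eye(N_CLASSES)
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}

    def move(src: str, dst: str, p: float) -> None:
        K[idx[src], idx[dst]] += p
        K[idx[src], idx[src]] -= p

    move("CL", "WO", 0.020)
    move("CL", "CO", 0.008)
    move("CL", "WA", 0.003)
    move("CL", "WL", 0.003)
    move("CL", "UL", 0.0005)
    move("WO", "CL", 0.012)
    move("GL", "WO", 0.015)
    move("GL", "CL", 0.005)
    move("WA", "WL", 0.010)
    move("WA", "UL", 0.0005)
    move("WL", "WA", 0.006)
    move("WL", "UL", 0.0005)
    move("UL", "CL", 0.010)
    return K


@dataclass
class SyntheticScenario:
    """Full recipe for one synthetic study: landscape, zones and drivers."""

    seed: int
    grid_shape: tuple[int, int] = (80, 80)
    n_zones: int = 33
    years: tuple[int, ...] = (2000, 2005, 2010, 2018)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    transition_kernel: np.ndarray = field(default_factory=default_transition_kernel)
    driver_spec: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DRIVER_SPEC.items()}
    )
    planted_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_EFFECT)
    )
    cell_area: float = HM2_PER_KM2

    def __post_init__(self) -> None:
        self.transition_kernel = np.asarray(self.transition_kernel, dtype=float)
        if self.transition_kernel.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("transition kernel must be 7×7")
        if not np.allclose(self.transition_kernel.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition kernel rows must sum to 1")
        if (self.transition_kernel < 0).any():
            raise ValueError("transition kernel must be non-negative")
        props = np.array([self.class_proportions.get(c, 0.0) for c in CLASS_ORDER])
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.grid_shape) < 2:
            raise ValueError("grid must be at least 2×2")
        if self.n_zones < 1 or self.n_zones > np.prod(self.grid_shape):
            raise ValueError("n_zones out of range for this grid")


def default_scenario(seed: int, **overrides) -> SyntheticScenario:
    return replace(SyntheticScenario(seed=seed), **overrides)


def generate_landscape(
    scenario: SyntheticScenario,
) -> tuple[list[LandUseGrid], ZoneMap]:
    """Draw the multi-year raster series and a contiguous zone partition.

    Year 1 is iid multinomial from ``class_proportions``; each later listed
    year is one application of the Markov kernel to the previous one. Zones
    are a nearest-seed-point (Voronoi-on-grid) partition, labels 1..n_zones.
    """
    rng = np.random.default_rng(scenario.seed)
    rows, cols = scenario.grid_shape
    props = np.array(
        [scenario.class_proportions.get(c, 0.0) for c in CLASS_ORDER]
    )

    # zones first so the partition is independent of the year list
    seeds = np.column_stack(
        [rng.uniform(0, rows, scenario.n_zones), rng.uniform(0, cols, scenario.n_zones)]
    )
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    labels = d2.argmin(axis=-1) + 1
    zones = ZoneMap(
        labels=labels.astype(np.int64),
        names={i + 1: f"zone_{i + 1:02d}" for i in range(scenario.n_zones)},
    )

    cum0 = props.cumsum()
    first = cum0.searchsorted(rng.random((rows, cols)), side="right") + 1
    grids = [
        LandUseGrid(first.astype(np.int64), year=scenario.years[0],
                    cell_area=scenario.cell_area)
    ]
    cum = scenario.transition_kernel.cumsum(axis=1)
    for year in scenario.years[1:]:
        prev = grids[-1].codes
        u = rng.random((rows, cols))
        rows_cum = cum[prev - 1]  # (rows, cols, 7)
        nxt = (u[..., None] > rows_cum).sum(axis=-1) + 1
        grids.append(
            LandUseGrid(nxt.astype(np.int64), year=year,
                        cell_area=scenario.cell_area)
        )
    return grids, zones


def zone_class_fractions(grid: LandUseGrid, zones: ZoneMap) -> pd.DataFrame:
    """Zone × class area fractions for one year."""
    areas = tabulate_areas(grid, zones)
    wide = areas.pivot(index="zone", columns="class", values="area_hm2")
    return wide.div(wide.sum(axis=1), axis=0).reindex(columns=CLASS_ORDER)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  smoothness: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated surface: smoothed white noise."""
    white = rng.standard_normal(shape)
    if smoothness <= 0:
        field_ = white
    else:
        field_ = ndimage.gaussian_filter(white, sigma=smoothness, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_drivers(
    scenario: SyntheticScenario,
    grids: list[LandUseGrid],
    zones: ZoneMap,
) -> pd.DataFrame:
    """Per-(zone, year) driver covariates honoring the scenario's links.

    Returns columns zone, year, GPP, DEM, Slope, POP, GDP, Temp, Pre, PM.
    Slope is derived from the DEM surface by finite differences before zonal
    averaging; DEM (hence Slope) is static across years.
    """
    unknown = set(scenario.driver_spec) - set(DEFAULT_DRIVER_SPEC)
    if unknown:
        raise ValueError(f"unknown drivers in spec: {sorted(unknown)}")
    for name, spec in scenario.driver_spec.items():
        bad = set(spec) - _SPEC_KEYS
        if bad:
            raise ValueError(f"unknown keys in driver spec {name!r}: {sorted(bad)}")

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 104729]))
    rows, cols = scenario.grid_shape
    zone_ids = zones.zone_ids
    zmask = {z: zones.labels == z for z in zone_ids}

    fracs = {g.year: zone_class_fractions(g, zones) for g in grids}

    def zonal_mean(surface: np.ndarray) -> pd.Series:
        return pd.Series(
            {z: surface[zmask[z]].mean() for z in zone_ids}, name="value"
        )

    # DEM and slope: one static surface
    dem_spec = scenario.driver_spec.get("DEM", DEFAULT_DRIVER_SPEC["DEM"])
    dem_surface = dem_spec.get("base", 0.0) + dem_spec.get(
        "field_scale", 0.0
    ) * _smooth_field(rng, (rows, cols), dem_spec.get("smoothness", 0.0))
    gy, gx = np.gradient(dem_surface)
    slope_surface = np.hypot(gy, gx)
    dem_by_zone = zonal_mean(dem_surface)
    slope_by_zone = zonal_mean(slope_surface)

    surfaces = {}
    for name, spec in scenario.driver_spec.items():
        if name == "DEM":
            continue
        surf = np.full((rows, cols), float(spec.get("base", 0.0)))
        fs = float(spec.get("field_scale", 0.0))
        if fs:
            surf = surf + fs * _smooth_field(
                rng, (rows, cols), float(spec.get("smoothness", 0.0))
            )
        grad = spec.get("gradient")
        if grad:
            surf = surf + grad[0] * (np.linspace(0, 1, rows)[:, None]) \
                        + grad[1] * (np.linspace(0, 1, cols)[None, :])
        surfaces[name] = surf

    records = []
    for g in grids:
        frac = fracs[g.year]
        for z in zone_ids:
            rec = {"zone": z, "year": g.year,
                   "DEM": dem_by_zone[z], "Slope": slope_by_zone[z]}
            for name, spec in scenario.driver_spec.items():
                if name == "DEM":
                    continue
                val = float(surfaces[name][zmask[z]].mean())
                for cls, beta in spec.get("links", {}).items():
                    val += beta * float(frac.at[z, cls])
                sd = float(spec.get("noise_sd", 0.0))
                if sd:
                    val += rng.normal(0.0, sd)
                rec[name] = val
            records.append(rec)
    cols_out = ["zone", "year", "GPP", "DEM", "Slope", "POP", "GDP",
                "Temp", "Pre", "PM"]
    return pd.DataFrame(records)[cols_out]


def planted_response(
    table: pd.DataFrame,
    effect: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    intercept: float = 20.0,
    seed: int = 0,
    interactions: dict[tuple[str, str], float] | None = None,
) -> pd.Series:
    """Ground-truth response for recovery experiments.

    Linear in the z-scored feature columns of ``table`` with the planted
    coefficients plus iid Gaussian noise; features with coefficient 0 (PM by
    default) are genuinely irrelevant. ``interactions`` adds pairwise
    products of z-scored features, e.g. ``{("GPP", "HAI"): 2.0}`` makes the
    productivity effect stronger under high human impact.
    """
    effect = dict(DEFAULT_PLANTED_EFFECT if effect is None else effect)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))

    def zscore(name: str) -> np.ndarray:
        x = table[name].to_numpy(dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    y = np.full(len(table), float(intercept))
    for name, beta in effect.items():
        if beta == 0.0:
            continue
        y = y + beta * zscore(name)
    for (name_a, name_b), beta in (interactions or {}).items():
        y = y + beta * zscore(name_a) * zscore(name_b)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=len(table))
    return pd.Series(y, index=table.index, name="ESV")
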