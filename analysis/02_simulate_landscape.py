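"""Generate the default synthetic study landscape and account for its
land-use change.

Emits the per-zone area table, the year-to-year class transition matrices
and per-class dynamic degrees over the simulated period to results/; the
rasters themselves go to scratch/ (they are bulky and reproducible from the
seed).

Run from the repository root:  python analysis/02_simulate_landscape.py
"""

from pathlib import Path

import pandas as pd

from esvpipe import io, synthetic
from esvpipe.landuse import class_totals, dynamic_degree, tabulate_areas, transitions

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "synthetic_rasters"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    scenario = synthetic.default_scenario(SEED)
    grids, zones = synthetic.generate_landscape(scenario)
    io.write_zone_map(SCRATCH / "zones.tif", SCRATCH / "zones.csv", zones)
    for g in grids:
        io.write_raster(SCRATCH / f"landuse_{g.year}.tif", g.codes)

    areas = pd.concat(
        [tabulate_areas(g, zones) for g in grids], ignore_index=True
    )
    areas.to_csv(RESULTS / "synthetic_areas.csv", index=False)

    totals = class_totals(areas)
    horizon = scenario.years[-1] - scenario.years[0]
    k = {
        cls: dynamic_degree(
            totals.at[scenario.years[0], cls],
            totals.at[scenario.years[-1], cls],
            horizon=horizon,
        )
        for cls in totals.columns
    }
    pd.Series(k, name="dynamic_degree_pct_per_yr").round(3).to_csv(
        RESULTS / "synthetic_dynamic_degree.csv"
    )
    print(f"{scenario.n_zones} zones, {len(grids)} years, seed {SEED}")
    print("Per-class dynamic degree (%/yr) over the simulated period:")
    print(pd.Series(k).round(2).to_string())

    for a, b in zip(grids, grids[1:]):
        tm = transitions(a, b)
        io.write_transition_matrix(
            RESULTS / f"synthetic_transitions_{a.year}_{b.year}.csv", tm
        )
        flows = tm.matrix.copy()
        for c in flows.index:
            flows.at[c, c] = 0.0
        top = flows.stack().sort_values(ascending=False).head(3)
        print(f"\nLargest {a.year}->{b.year} flows (hm2):")
        print(top.to_string())


if __name__ == "__main__":
    main()
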