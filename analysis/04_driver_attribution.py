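"""Fit the tree-ensemble driver model on the synthetic study and attribute
zone ESV to its drivers with Shapley values.

Two runs: (a) the coherent pipeline response (computed ESV of the simulated
landscape), and (b) the planted-effect response with known ground truth,
where the recovery of the dominant driver and the irrelevance of PM2.5 can
be verified. Writes importance rankings and a GPP dependence table (colored
by HAI) under results/.

Run from the repository root:  python analysis/04_driver_attribution.py
"""

from pathlib import Path

import pandas as pd

from esvpipe import attribution, synthetic
from esvpipe.esv import compute_esv
from esvpipe.experiments import planted_recovery_trial
from esvpipe.fixtures import load_fixtures
from esvpipe.hai import compute_hai
from esvpipe.landuse import tabulate_areas

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fx = load_fixtures()

    # (a) coherent pipeline: response = computed ESV of the landscape
    scenario = synthetic.default_scenario(SEED)
    grids, zones = synthetic.generate_landscape(scenario)
    drivers = synthetic.generate_drivers(scenario, grids, zones)
    areas = pd.concat(
        [tabulate_areas(g, zones) for g in grids], ignore_index=True
    )
    esv = compute_esv(areas, fx.coefficients)
    hai = compute_hai(areas, fx.pi)
    table = attribution.assemble_table(esv, hai, drivers)
    table.to_csv(RESULTS / "synthetic_driver_table.csv", index=False)

    model = attribution.fit_model(table, seed=SEED)
    attr = attribution.shapley(model, table, table)
    ranking = attribution.importance_ranking(attr)
    ranking.to_csv(RESULTS / "synthetic_importance.csv", index=False)
    print(f"Pipeline response model: training R2 = {model.train_r2:.3f}")
    print("Importance ranking (mean |phi|, yuan):")
    print(ranking.to_string(index=False))

    dep = attribution.dependence_table(attr, table, "GPP", color_feature="HAI")
    dep.to_csv(RESULTS / "synthetic_gpp_dependence.csv", index=False)

    # (b) planted ground truth at the acceptance condition (60 zones)
    planted = planted_recovery_trial(SEED, n_zones=60)
    planted.to_csv(RESULTS / "planted_importance.csv", index=False)
    print("\nPlanted-effect run (60 zones): importance ranking")
    print(planted.to_string(index=False))
    first, last = planted["feature"].iloc[0], planted["feature"].iloc[-1]
    print(f"\nDominant planted driver recovered first: {first}; "
          f"least important: {last}.")


if __name__ == "__main__":
    main()
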