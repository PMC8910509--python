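"""Canned computations over the vendored study tables and the synthetic
generator: the desk-scale reproduction of the published summary numbers and
the planted-effect attribution-recovery experiment.

Everything here is assembled from the public module functions; these are the
entry points the analysis scripts, the acceptance checks and the CLI report
mode share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import attribution, synthetic
from .esv import compute_esv, infer_areas, summarize
from .fixtures import load_fixtures
from .hai import compute_hai
from .landuse import dynamic_degree

__all__ = [
    "published_summary",
    "planted_recovery_trial",
    "planted_recovery_rate",
]


def published_summary() -> dict[str, float]:
    """Recompute the study-period headline quantities from the vendored
    published ESV table.

    Monetary deltas are reported in billions of yuan, shares and growth
    rates in percent, the dynamic degree in percent per year, and the
    cropland+forest footprint as a percent of the district area.
    """
    fx = load_fixtures()
    s = summarize(fx.esv_table)
    y0, y1 = fx.study_years[0], fx.study_years[-1]

    class_delta = s.delta(y0, y1, by="class") / 1e9
    function_delta = s.delta(y0, y1, by="function") / 1e9
    total_delta = s.delta(y0, y1, by="total") / 1e9
    growth = s.growth_rate(y0, y1, by="class")

    # five dominant functions' combined contribution in the first year
    top5 = ["WS", "WD", "SFR", "BD", "CR"]
    top5_share_y0 = float(s.function_shares.loc[y0, top5].sum())

    # dynamic degree of cropland from the published-value ratio: within one
    # class the coefficients cancel, so the total-value ratio IS the area
    # ratio
    cl_totals = s.class_totals["CL"]
    k_cl = dynamic_degree(
        float(cl_totals[y0]), float(cl_totals[y1]), horizon=fx.horizon
    )

    # cropland+forest footprint from back-derived areas, as % of the district
    areas = infer_areas(fx.esv_table, fx.coefficients)
    wide = areas.pivot_table(
        index="year", columns="class", values="area_hm2", aggfunc="sum"
    )
    clwo_km2 = (wide["CL"] + wide["WO"]) / 100.0
    clwo_share = clwo_km2 / fx.total_area_km2 * 100.0

    return {
        "delta_CL_billion": float(class_delta["CL"]),
        "delta_WO_billion": float(class_delta["WO"]),
        "delta_WA_billion": float(class_delta["WA"]),
        "delta_WL_billion": float(class_delta["WL"]),
        "delta_total_billion": float(total_delta),
        "delta_WS_billion": float(function_delta["WS"]),
        "growth_WL_pct": float(growth["WL"]),
        "growth_GL_pct": float(growth["GL"]),
        "mean_share_WO_pct": float(s.mean_class_shares["WO"]),
        "mean_share_WA_pct": float(s.mean_class_shares["WA"]),
        "mean_share_CL_pct": float(s.mean_class_shares["CL"]),
        "mean_share_WL_pct": float(s.mean_class_shares["WL"]),
        "top5_function_share_2000_pct": top5_share_y0,
        "dynamic_degree_CL": k_cl,
        "min_clwo_area_share_pct": float(clwo_share.min()),
    }


def planted_recovery_trial(
    seed: int,
    n_zones: int = 60,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """One end-to-end attribution run on a planted-effect synthetic study.

    Generates a landscape and drivers, computes HAI from the land
    composition, builds the planted zone-level response (dominant HAI term,
    irrelevant PM), fits the tree ensemble and returns the Shapley importance
    ranking.
    """
    scenario = synthetic.default_scenario(seed, n_zones=n_zones)
    grids, zones = synthetic.generate_landscape(scenario)
    drivers = synthetic.generate_drivers(scenario, grids, zones)

    from .landuse import tabulate_areas

    areas = pd.concat(
        [tabulate_areas(g, zones) for g in grids], ignore_index=True
    )
    hai = compute_hai(areas, _default_pi())
    table = drivers.merge(
        hai[["zone", "year", "hai"]].rename(columns={"hai": "HAI"}),
        on=["zone", "year"],
    )
    table["ESV"] = synthetic.planted_response(
        table, scenario.planted_effect, seed=seed
    )
    model = attribution.fit_model(
        table, {"n_estimators": n_estimators}, seed=seed
    )
    attr = attribution.shapley(model, table, table)
    return attribution.importance_ranking(attr)


def _default_pi() -> dict[str, float]:
    return load_fixtures().pi


def planted_recovery_rate(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_zones: int = 60,
) -> dict[str, float]:
    """Fraction of seeds where HAI ranks first and PM ranks last."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    hai_first = 0
    pm_last = 0
    both = 0
    for s in seeds:
        ranking = planted_recovery_trial(int(s), n_zones=n_zones)
        first = ranking["feature"].iloc[0] == "HAI"
        last = ranking["feature"].iloc[-1] == "PM"
        hai_first += first
        pm_last += last
        both += first and last
    return {
        "hai_first": hai_first / n_seeds,
        "pm_last": pm_last / n_seeds,
        "both": both / n_seeds,
        "n_seeds": n_seeds,
    }
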