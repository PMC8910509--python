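"""Human impact index (HAI): area-weighted anthropogenic disturbance.

HAI for a zone is Σᵢ Bᵢ·Pᵢ / TA, where Bᵢ is the area of land class i, Pᵢ its
disturbance intensity coefficient (Delphi-elicited, fixed inputs here) and TA
the zone's total classified area. Zones are banded high (> 0.5), medium
(0.35 ≤ HAI ≤ 0.5, both boundaries inclusive) and low (< 0.35).
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["compute_hai", "classify_hai", "HAI_HIGH", "HAI_LOW"]

HAI_HIGH = 0.5
HAI_LOW = 0.35


def classify_hai(hai: float) -> str:
    """Band a HAI value: 'high', 'medium' or 'low'."""
    if not 0.0 <= hai <= 1.0:
        raise ValueError(f"HAI must lie in [0, 1], got {hai}")
    if hai > HAI_HIGH:
        return "high"
    if hai >= HAI_LOW:
        return "medium"
    return "low"


def compute_hai(areas: pd.DataFrame, pi: dict[str, float]) -> pd.DataFrame:
    """Per-(zone, year) human impact index from a tidy area table.

    ``areas`` has columns year, zone, class, area_hm2; ``pi`` maps every land
    class occurring with positive area to its disturbance coefficient. Zones
    with zero classified area are skipped with a warning. Returns columns
    zone, year, hai, band.
    """
    present = set(areas.loc[areas["area_hm2"] > 0, "class"])
    missing = present - set(pi)
    if missing:
        raise KeyError(f"no disturbance coefficient for classes: {sorted(missing)}")

    records = []
    for (year, zone), grp in areas.groupby(["year", "zone"], sort=True):
        ta = grp["area_hm2"].sum()
        if ta <= 0:
            warnings.warn(
                f"zone {zone} year {year} has zero classified area; skipped",
                stacklevel=2,
            )
            continue
        weighted = (grp["area_hm2"] * grp["class"].map(pi).fillna(0.0)).sum()
        h = weighted / ta
        records.append((zone, year, h, classify_hai(h)))
    return pd.DataFrame(records, columns=["zone", "year", "hai", "band"])
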