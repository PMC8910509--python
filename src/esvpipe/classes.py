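"""Land-class and service-function vocabulary shared across the pipeline.

Seven land-use classes (after reclassification of the raw survey codes) and
nine ecosystem service functions. Integer codes are fixed everywhere: rasters,
area tables, transition matrices.
"""

from __future__ import annotations

CLASS_ORDER: list[str] = ["CL", "WO", "GL", "WA", "CO", "UL", "WL"]

CLASS_CODES: dict[str, int] = {abbr: i + 1 for i, abbr in enumerate(CLASS_ORDER)}
CODE_TO_CLASS: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

CLASS_NAMES: dict[str, str] = {
    "CL": "cultivated land",
    "WO": "forestland",
    "GL": "grassland",
    "WA": "water area",
    "CO": "construction land",
    "UL": "unused land",
    "WL": "wetland",
}

FUNCTION_ORDER: list[str] = ["FP", "RM", "GR", "CR", "WS", "WD", "SFR", "BD", "EC"]

FUNCTION_NAMES: dict[str, str] = {
    "FP": "food production",
    "RM": "raw material",
    "GR": "gas regulation",
    "CR": "climate regulation",
    "WS": "water supply (water conservation)",
    "WD": "waste treatment",
    "SFR": "soil formation and retention",
    "BD": "biodiversity protection",
    "EC": "recreation and culture",
}

#: driver covariates for the attribution model, in fixed column order
DRIVER_FEATURES: list[str] = [
    "HAI", "GPP", "Slope", "DEM", "POP", "Temp", "GDP", "Pre", "PM",
]

#: hm2 per km2 — the only unit conversion in the package
HM2_PER_KM2: float = 100.0
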