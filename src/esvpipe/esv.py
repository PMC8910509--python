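"""Equivalence-factor ecosystem service valuation.

Each land class carries, for each of nine service functions, a coefficient in
yuan/hm² that is a multiple (the equivalence factor) of one standard
equivalent — the per-hectare economic value of average national grain output,
V. Zone-level ESV is then area × coefficient summed over classes and
functions. All internal monetary values are yuan and areas hm²; conversion to
billions happens only in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, FUNCTION_ORDER

__all__ = [
    "EsvCoefficients",
    "EsvSummary",
    "standard_equivalent",
    "build_coefficients",
    "compute_esv",
    "infer_areas",
    "summarize",
]


@dataclass
class EsvCoefficients:
    """Per-unit-area service values: 7 land classes × 9 functions, yuan/hm².

    ``eb`` is the monetary value of one standard equivalent (V); the implied
    equivalence factors are ``values / eb``. The construction-land row is all
    zero by assignment.
    """

    values: pd.DataFrame
    eb: float

    def __post_init__(self) -> None:
        self.values = self.values.reindex(
            index=CLASS_ORDER, columns=FUNCTION_ORDER
        ).astype(float)
        if self.values.isna().any().any():
            raise ValueError("coefficient table has missing class/function cells")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coefficients must be non-negative")
        if (self.values.loc["CO"] != 0).any():
            raise ValueError("construction-land coefficients must be zero")

    @property
    def factors(self) -> pd.DataFrame:
        """Equivalence factors (dimensionless), values / eb."""
        return self.values / self.eb

    def value(self, cls: str, function: str) -> float:
        return float(self.values.at[cls, function])

    def row_total(self, cls: str) -> float:
        return float(self.values.loc[cls].sum())


def standard_equivalent(
    shares: tuple[float, float, float],
    profits: tuple[float, float, float],
) -> float:
    """Value of one standard equivalent from crop statistics.

    V = R1·V1 + R2·V2 + R3·V3 with R the area shares of the three staple
    crops (wheat, corn, rice) and V their net profits in yuan/hm².
    """
    shares_arr = np.asarray(shares, dtype=float)
    profits_arr = np.asarray(profits, dtype=float)
    if (shares_arr < 0).any():
        raise ValueError("crop shares must be non-negative")
    total = shares_arr.sum()
    if not (0.99 <= total <= 1.01):
        raise ValueError(f"crop shares must sum to 1 (got {total:.4f})")
    return float(shares_arr @ profits_arr)


def build_coefficients(factors: pd.DataFrame, eb: float) -> EsvCoefficients:
    """Scale an equivalence-factor table by the standard equivalent."""
    factors = factors.reindex(index=CLASS_ORDER, columns=FUNCTION_ORDER)
    if (factors.fillna(0.0).to_numpy() < 0).any():
        raise ValueError("equivalence factors must be non-negative")
    return EsvCoefficients(values=factors.fillna(0.0) * eb, eb=eb)


def compute_esv(areas: pd.DataFrame, coef: EsvCoefficients) -> pd.DataFrame:
    """ESV per (year, zone, class, function) in yuan: area × coefficient.

    ``areas`` is a tidy table with columns year, zone, class, area_hm2.
    Classes present in the areas but absent from the coefficient table raise.
    """
    unknown = set(areas["class"]) - set(coef.values.index)
    if unknown:
        raise KeyError(f"classes without coefficients: {sorted(unknown)}")
    long_coef = (
        coef.values.rename_axis("class")
        .reset_index()
        .melt(id_vars="class", var_name="function", value_name="yuan_per_hm2")
    )
    out = areas.merge(long_coef, on="class")
    out["yuan"] = out["area_hm2"] * out["yuan_per_hm2"]
    out = out[["year", "zone", "class", "function", "yuan"]].sort_values(
        ["year", "zone", "class", "function"], ignore_index=True
    )
    out.attrs["provenance"] = "computed"
    return out


def infer_areas(esv: pd.DataFrame, coef: EsvCoefficients) -> pd.DataFrame:
    """Invert the valuation: recover class areas from an ESV table.

    For each (year, zone, class) the function with the largest monetary value
    is used (most robust to rounding in published tables); its area is
    value / coefficient. Classes whose coefficient row is all zero cannot be
    inverted and are skipped with a warning. ``infer_areas(compute_esv(A))``
    recovers A exactly.
    """
    records = []
    for (year, zone, cls), grp in esv.groupby(["year", "zone", "class"], sort=False):
        row = coef.values.loc[cls]
        if (row == 0).all():
            warnings.warn(
                f"class {cls} has an all-zero coefficient row; area not inferable",
                stacklevel=2,
            )
            continue
        grp = grp.set_index("function")["yuan"]
        if (grp == 0).all():
            records.append((year, zone, cls, 0.0))
            continue
        usable = grp[row.reindex(grp.index) > 0]
        fn = usable.idxmax()
        records.append((year, zone, cls, float(usable[fn] / row[fn])))
    return pd.DataFrame(records, columns=["year", "zone", "class", "area_hm2"])


@dataclass
class EsvSummary:
    """Aggregates of an ESV table (all monetary values in yuan).

    Shares are percentages; multi-year shares are unweighted means of the
    annual shares.
    """

    year_totals: pd.Series
    class_totals: pd.DataFrame  # year × class
    class_shares: pd.DataFrame  # year × class, percent
    function_totals: pd.DataFrame  # year × function
    function_shares: pd.DataFrame  # year × function, percent
    mean_class_shares: pd.Series
    mean_function_shares: pd.Series

    def _slice(self, kind: str) -> pd.Series | pd.DataFrame:
        if kind == "total":
            return self.year_totals
        if kind == "class":
            return self.class_totals
        if kind == "function":
            return self.function_totals
        raise ValueError(f"unknown summary kind: {kind}")

    def _check_year(self, *years: int) -> None:
        for y in years:
            if y not in self.year_totals.index:
                raise KeyError(f"year {y} not present in the ESV table")

    def delta(self, y0: int, y1: int, by: str = "class"):
        """Absolute change between two years, in yuan."""
        self._check_year(y0, y1)
        t = self._slice(by)
        return t.loc[y1] - t.loc[y0]

    def growth_rate(self, y0: int, y1: int, by: str = "class"):
        """Relative change between two years, percent of the first year."""
        self._check_year(y0, y1)
        t = self._slice(by)
        return (t.loc[y1] / t.loc[y0] - 1.0) * 100.0


def summarize(esv: pd.DataFrame) -> EsvSummary:
    """Totals, shares and multi-year means of an ESV table."""
    if esv.empty:
        raise ValueError("empty ESV table")
    class_totals = (
        esv.groupby(["year", "class"], sort=True)["yuan"].sum().unstack("class")
    )
    class_totals = class_totals.reindex(
        columns=[c for c in CLASS_ORDER if c in class_totals.columns]
    ).fillna(0.0)
    function_totals = (
        esv.groupby(["year", "function"], sort=True)["yuan"].sum().unstack("function")
    )
    function_totals = function_totals.reindex(
        columns=[f for f in FUNCTION_ORDER if f in function_totals.columns]
    ).fillna(0.0)
    year_totals = class_totals.sum(axis=1)
    class_shares = class_totals.div(year_totals, axis=0) * 100.0
    function_shares = function_totals.div(year_totals, axis=0) * 100.0
    return EsvSummary(
        year_totals=year_totals,
        class_totals=class_totals,
        class_shares=class_shares,
        function_totals=function_totals,
        function_shares=function_shares,
        mean_class_shares=class_shares.mean(axis=0),
        mean_function_shares=function_shares.mean(axis=0),
    )
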