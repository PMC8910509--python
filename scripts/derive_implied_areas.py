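"""Derive the implied-area fixture from the vendored published tables.

The published ESV table prints monetary values per (year, class, function) to
three decimal places of a billion yuan. Dividing any cell by its per-hectare
coefficient gives an implied class area; the largest cell of each class row is
the most rounding-robust choice. This script back-derives those areas and
writes them to ``src/esvpipe/data/implied_areas.csv``, then refreshes the
checksum manifest. Run from the repository root:

    python scripts/derive_implied_areas.py
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "esvpipe" / "data"


def main() -> None:
    coef = (
        pd.read_csv(DATA / "esv_coefficients.csv")
        .pivot(index="class", columns="function", values="yuan_per_hm2")
    )
    table = pd.read_csv(DATA / "esv_by_class_function.csv")

    records = []
    for (year, cls), grp in table.groupby(["year", "class"]):
        grp = grp.set_index("function")["billion_yuan"]
        usable = grp[coef.loc[cls].reindex(grp.index) > 0]
        fn = usable.idxmax()
        area_hm2 = usable[fn] * 1e9 / coef.at[cls, fn]
        records.append((year, cls, fn, round(area_hm2, 1)))

    out = pd.DataFrame(
        records, columns=["year", "class", "reference_function", "area_hm2"]
    ).sort_values(["year", "class"], ignore_index=True)
    out.to_csv(DATA / "implied_areas.csv", index=False)
    print(out.to_string(index=False))

    lines = []
    for path in sorted(DATA.glob("*.csv")):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        lines.append(f"{digest}  {path.name}")
    (DATA / "checksums.sha256").write_text("\n".join(lines) + "\n")
    print("manifest refreshed:", DATA / "checksums.sha256")


if __name__ == "__main__":
    main()
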