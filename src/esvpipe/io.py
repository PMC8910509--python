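"""File interfaces: single-band integer rasters (TIFF) and tidy CSV tables.

Rasters are written as single-band TIFF with nodata = 0 encoded as the fill
value; zone labels travel with a companion CSV (zone_id, name).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .landuse import LandUseGrid, TransitionMatrix, ZoneMap

__all__ = [
    "write_raster",
    "read_landuse_raster",
    "write_zone_map",
    "read_zone_map",
    "read_mapping_csv",
    "write_transition_matrix",
]


def write_raster(path: str | Path, codes: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(codes, dtype=np.int16))


def read_landuse_raster(
    path: str | Path, year: int, cell_area: float = 100.0, nodata: int = 0
) -> LandUseGrid:
    codes = np.asarray(tifffile.imread(str(path)), dtype=np.int64)
    return LandUseGrid(codes, year=year, cell_area=cell_area, nodata=nodata)


def write_zone_map(path_raster: str | Path, path_names: str | Path,
                   zones: ZoneMap) -> None:
    write_raster(path_raster, zones.labels)
    pd.DataFrame(
        sorted(zones.names.items()), columns=["zone_id", "name"]
    ).to_csv(path_names, index=False)


def read_zone_map(path_raster: str | Path,
                  path_names: str | Path | None = None) -> ZoneMap:
    labels = np.asarray(tifffile.imread(str(path_raster)), dtype=np.int64)
    names: dict[int, str] = {}
    if path_names is not None and Path(path_names).exists():
        df = pd.read_csv(path_names)
        names = dict(zip(df["zone_id"].astype(int), df["name"].astype(str)))
    return ZoneMap(labels=labels, names=names)


def read_mapping_csv(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path)
    return dict(zip(df["raw_code"].astype(int), df["class_code"].astype(int)))


def write_transition_matrix(path: str | Path, tm: TransitionMatrix) -> None:
    long = (
        tm.matrix.rename_axis("class_from")
        .reset_index()
        .melt(id_vars="class_from", var_name="class_to", value_name="area_hm2")
    )
    long.insert(0, "from_year", tm.from_year)
    long.insert(1, "to_year", tm.to_year)
    long.to_csv(path, index=False)
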