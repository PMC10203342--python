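"""File formats: GeoTIFF rasters, flat tables, NetCDF LST series, configs.

A city bundle is a directory with one single-band GeoTIFF per variable
(population, ndvi, water, days_day, days_night, core), grid geometry in the
raster geo-tags (ModelPixelScale / ModelTiepoint), a ``meta.json`` with city
metadata, the per-pixel table as CSV and Parquet, and the optional LST
series as ``lst.nc`` (netCDF3).  write_city -> read_city round-trips every
per-pixel value bit-exactly for integer fields and to full float precision
for real fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .grid import PIXEL_COLUMNS, CityGrid, GridSpec
from .lst import LSTSeries

__all__ = [
    "write_raster", "read_raster", "write_city", "read_city",
    "write_lst", "read_lst", "load_config",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922

_RASTER_LAYERS = {
    # column -> (dtype, fill for missing)
    "population": ("float64", 0.0),
    "ndvi": ("float64", np.nan),
    "D_w": ("float64", np.nan),
    "d_w": ("float64", np.nan),
    "days_day": ("float64", np.nan),
    "days_night": ("float64", np.nan),
    "is_water": ("uint8", 0),
    "in_urban_core": ("uint8", 0),
}
MANDATORY_LAYERS = ("population", "ndvi")


def write_raster(path, array: np.ndarray, spec: GridSpec) -> None:
    """Single-band GeoTIFF with the grid transform in geo-tags."""
    sx = sy = float(spec.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x0,
                                 spec.y0 + spec.n_rows * spec.cell_size, 0.0)),
    ]
    tifffile.imwrite(path, np.asarray(array), extratags=extratags)


def read_raster(path) -> tuple[np.ndarray, GridSpec]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    n_rows, n_cols = arr.shape
    cell = float(scale[0])
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=cell,
                    x0=float(tie[3]), y0=float(tie[4]) - n_rows * cell)
    return arr, spec


def write_city(grid: CityGrid, path, lst: LSTSeries | None = None) -> Path:
    """Write a city bundle directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for col, (dtype, _) in _RASTER_LAYERS.items():
        arr = grid.field_2d(col)
        if dtype == "uint8":
            arr = np.nan_to_num(arr).astype(np.uint8)
        write_raster(path / f"{col}.tif", arr, grid.spec)
    table = grid.pixels[PIXEL_COLUMNS]
    table.to_csv(path / "table.csv", index=False)
    table.to_parquet(path / "table.parquet", index=False)
    meta = {
        "city_name": grid.city_name,
        "climate_zone": grid.climate_zone,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_size": grid.cell_size,
        "x0": grid.spec.x0,
        "y0": grid.spec.y0,
        "dw_excluded": grid.dw_excluded,
        "extras": {k: v for k, v in grid.extras.items()
                   if isinstance(v, (int, float, str, bool))},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    if lst is not None:
        write_lst(path / "lst.nc", lst)
    return path


def read_city(path) -> tuple[CityGrid, LSTSeries | None]:
    """Read a city bundle written by :func:`write_city`.

    The per-pixel table is authoritative (full float precision); rasters
    are validated for shape consistency against the metadata.
    """
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    spec = GridSpec(n_rows=meta["n_rows"], n_cols=meta["n_cols"],
                    cell_size=meta["cell_size"], x0=meta["x0"], y0=meta["y0"])
    for layer in MANDATORY_LAYERS:
        f = path / f"{layer}.tif"
        if not f.exists():
            raise FileNotFoundError(f"missing mandatory layer: {layer}")
    shape = (spec.n_rows, spec.n_cols)
    for f in sorted(path.glob("*.tif")):
        arr, _ = read_raster(f)
        if arr.shape != shape:
            raise ValueError(
                f"raster shape mismatch in layer {f.stem!r}: "
                f"{arr.shape} vs {shape}"
            )
    pq = path / "table.parquet"
    table = pd.read_parquet(pq) if pq.exists() else pd.read_csv(path / "table.csv")
    table["is_water"] = table["is_water"].astype(bool)
    table["in_urban_core"] = table["in_urban_core"].astype(bool)
    grid = CityGrid(
        city_name=meta["city_name"], climate_zone=meta["climate_zone"],
        spec=spec, pixels=table, dw_excluded=meta.get("dw_excluded", False),
        extras=meta.get("extras", {}),
    )
    lst = read_lst(path / "lst.nc") if (path / "lst.nc").exists() else None
    return grid, lst


def grid_from_rasters(
    layers: dict[str, Path | str],
    city_name: str = "city",
    climate_zone: str = "Other",
) -> CityGrid:
    """Assemble a CityGrid from per-variable GeoTIFFs sharing one geometry."""
    for layer in MANDATORY_LAYERS:
        if layer not in layers:
            raise FileNotFoundError(f"missing mandatory layer: {layer}")
    arrays, spec0, name0 = {}, None, None
    for name, p in layers.items():
        arr, spec = read_raster(p)
        if spec0 is None:
            spec0, name0 = spec, name
        elif (spec.n_rows, spec.n_cols, spec.cell_size) != (
                spec0.n_rows, spec0.n_cols, spec0.cell_size):
            raise ValueError(
                f"raster geometry of layer {name!r} does not match {name0!r}"
            )
        arrays[name] = np.asarray(arr, dtype=float)
    n = spec0.n_rows * spec0.n_cols
    rows, cols = np.divmod(np.arange(n), spec0.n_cols)
    x, y = spec0.centroids()

    def flat(name, default):
        return arrays[name].ravel() if name in arrays else default

    table = pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "row": rows, "col": cols, "x": x, "y": y,
            "population": flat("population", 0.0),
            "ndvi": flat("ndvi", np.nan),
            "D_w": flat("D_w", np.nan),
            "d_w": flat("d_w", np.nan),
            "days_day": flat("days_day", np.nan),
            "days_night": flat("days_night", np.nan),
            "is_water": flat("is_water", 0.0).astype(bool),
            "in_urban_core": flat("in_urban_core", 1.0).astype(bool),
        }
    )
    return CityGrid(city_name=city_name, climate_zone=climate_zone,
                    spec=spec0, pixels=table)


def write_lst(path, lst: LSTSeries) -> None:
    ds = xr.Dataset(
        {
            "lst_day": (("pixel", "date"), lst.day),
            "lst_night": (("pixel", "date"), lst.night),
        },
        coords={"pixel": np.asarray(lst.pixel_ids), "date": lst.dates},
        attrs={"season_months": list(lst.season_months)},
    )
    ds.to_netcdf(path, engine="scipy")


def read_lst(path) -> LSTSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return LSTSeries(
        dates=pd.DatetimeIndex(ds["date"].values),
        day=ds["lst_day"].values,
        night=ds["lst_night"].values,
        pixel_ids=ds["pixel"].values,
        season_months=tuple(int(m) for m in ds.attrs.get("season_months", (6, 7, 8))),
    )


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
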