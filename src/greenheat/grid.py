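"""Gridded-city data model, aggregation and the water-distance feature.

A city is a regular planar grid of square cells (nominal 1 km).  Each cell
carries resident population (summed from finer-resolution points), mean
NDVI, the distance to the nearest water cell D_w and its normalized
inverse-square transform d_w, the mean warm-season day/night exceedance
counts, and water / urban-core flags.  The per-pixel table is a pandas
DataFrame with a fixed schema shared by all I/O formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CLIMATE_ZONES",
    "PIXEL_COLUMNS",
    "CityGrid",
    "PointObservations",
    "aggregate_to_grid",
    "distance_to_water",
    "dw_feature",
]

CLIMATE_ZONES = ("Arid", "Continental", "Temperate", "Tropical", "Other")

PIXEL_COLUMNS = [
    "pixel_id", "row", "col", "x", "y", "population", "ndvi",
    "D_w", "d_w", "days_day", "days_night", "is_water", "in_urban_core",
]

POINT_VARIABLES = ("population", "ndvi", "lst_day", "lst_night")


@dataclass
class GridSpec:
    """Geometry of a regular grid: shape, cell size and origin.

    ``x0, y0`` is the outer corner of cell (0, 0); cell centroids sit at
    ``x0 + (col + 0.5) * cell_size`` and ``y0 + (row + 0.5) * cell_size``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    x0: float = 0.0
    y0: float = 0.0

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.divmod(np.arange(self.n_rows * self.n_cols), self.n_cols)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 + (rows + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, inside) for point coordinates."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, inside


@dataclass
class CityGrid:
    """Per-pixel table of one city plus grid geometry and metadata."""

    city_name: str
    climate_zone: str
    spec: GridSpec
    pixels: pd.DataFrame
    dw_excluded: bool = False  # set when no water exists: d_w unusable
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(
                f"climate_zone must be one of {CLIMATE_ZONES}, got {self.climate_zone!r}"
            )
        self.validate()

    # -- geometry helpers ------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.spec.n_rows

    @property
    def n_cols(self) -> int:
        return self.spec.n_cols

    @property
    def cell_size(self) -> float:
        return self.spec.cell_size

    def field_2d(self, column: str, fill=np.nan) -> np.ndarray:
        """Per-pixel column as an (n_rows, n_cols) array."""
        out = np.full((self.n_rows, self.n_cols), fill, dtype=float)
        out[self.pixels["row"].to_numpy(), self.pixels["col"].to_numpy()] = \
            self.pixels[column].to_numpy(dtype=float)
        return out

    def land(self) -> pd.DataFrame:
        return self.pixels[~self.pixels["is_water"]]

    def model_frame(self) -> pd.DataFrame:
        """Land pixels with complete features, ready for model fitting.

        Pixels with missing NDVI (or missing d_w unless the d_w feature is
        excluded city-wide) are dropped; the number dropped is reported via
        a warning so it is visible in logs rather than silently imputed.
        """
        df = self.land()
        ok = df["ndvi"].notna()
        if not self.dw_excluded:
            ok &= df["d_w"].notna()
        n_dropped = int((~ok).sum())
        if n_dropped:
            warnings.warn(
                f"{self.city_name}: {n_dropped} pixels excluded from modelling "
                "(missing NDVI/d_w)", stacklevel=2,
            )
        return df[ok]

    # -- validation ------------------------------------------------------
    def validate(self, season_length: int | None = None) -> None:
        df = self.pixels
        missing = [c for c in PIXEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pixel table missing columns: {missing}")
        if df["pixel_id"].duplicated().any():
            raise ValueError("pixel_id not unique")
        if df.duplicated(subset=["row", "col"]).any():
            raise ValueError("(row, col) not unique")
        if (df["population"] < 0).any():
            raise ValueError("negative population")
        dw = df["d_w"].dropna()
        if len(dw) and ((dw < 0) | (dw > 1)).any():
            raise ValueError("d_w outside [0, 1]")
        Dw = df["D_w"].dropna()
        if len(Dw):
            on_water = df.loc[Dw.index, "is_water"].to_numpy(bool)
            zero = (Dw.to_numpy() == 0.0)
            if (zero != on_water).any():
                raise ValueError("D_w = 0 must hold exactly on water pixels")
        if season_length is not None:
            for c in ("days_day", "days_night"):
                v = df[c].dropna()
                if len(v) and ((v < 0) | (v > season_length)).any():
                    raise ValueError(f"{c} outside [0, {season_length}]")


@dataclass
class PointObservations:
    """Native-resolution point samples to be aggregated onto a grid."""

    table: pd.DataFrame  # columns: x, y, variable_name, value
    grid: GridSpec

    def __post_init__(self) -> None:
        need = {"x", "y", "variable_name", "value"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"point table needs columns {sorted(need)}")
        xy = self.table[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("point coordinates must be finite")
        unknown = set(self.table["variable_name"]) - set(POINT_VARIABLES)
        if unknown:
            raise ValueError(f"unknown variable_name(s): {sorted(unknown)}")


def _empty_pixel_table(spec: GridSpec) -> pd.DataFrame:
    n = spec.n_rows * spec.n_cols
    rows, cols = np.divmod(np.arange(n), spec.n_cols)
    x, y = spec.centroids()
    return pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "row": rows,
            "col": cols,
            "x": x,
            "y": y,
            "population": 0.0,
            "ndvi": np.nan,
            "D_w": np.nan,
            "d_w": np.nan,
            "days_day": np.nan,
            "days_night": np.nan,
            "is_water": False,
            "in_urban_core": True,
        }
    )


def aggregate_to_grid(
    points: PointObservations,
    city_name: str = "synthetic",
    climate_zone: str = "Other",
) -> tuple[CityGrid, int]:
    """Bin point observations onto the grid.

    Population points are *summed* per cell (the total population living in
    a cell); NDVI points are *averaged* (finer native resolution); LST
    points are assigned one-to-one.  Points outside the grid are rejected
    and counted, not silently dropped.

    Returns the CityGrid and the number of rejected out-of-grid points.
    """
    spec = points.grid
    df = points.table
    row, col, inside = spec.cell_of(df["x"].to_numpy(float), df["y"].to_numpy(float))
    n_rejected = int((~inside).sum())
    if n_rejected:
        warnings.warn(f"{n_rejected} points outside the grid rejected", stacklevel=2)
    df = df[inside].copy()
    df["_cell"] = row[inside] * spec.n_cols + col[inside]

    table = _empty_pixel_table(spec)

    pop = df[df["variable_name"] == "population"].groupby("_cell")["value"].sum()
    table.loc[pop.index, "population"] = pop.to_numpy()

    ndvi = df[df["variable_name"] == "ndvi"].groupby("_cell")["value"].mean()
    table.loc[ndvi.index, "ndvi"] = ndvi.to_numpy()

    grid = CityGrid(city_name=city_name, climate_zone=climate_zone,
                    spec=spec, pixels=table)
    return grid, n_rejected


def distance_to_water(water_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean centroid-to-centroid distance to the nearest water cell.

    Exact Euclidean distance transform scaled to metres; 0 on water cells.
    With no water cell anywhere the distance is undefined: an all-NaN field
    is returned (the caller flags the city so d_w is excluded from
    modelling).
    """
    mask = np.asarray(water_mask, dtype=bool)
    if not mask.any():
        warnings.warn("no water cell: D_w undefined everywhere", stacklevel=2)
        return np.full(mask.shape, np.nan)
    return ndimage.distance_transform_edt(~mask) * float(cell_size)


def dw_feature(D_w: np.ndarray, is_water: np.ndarray | None = None) -> np.ndarray:
    """Normalized inverse-square water-proximity feature.

    raw = 1 / D_w^2 on land; the transform diverges on water cells (D_w = 0),
    so water cells take the maximum raw *land* value — preserving the
    "closest to water = largest d_w" ordering without infinities.  The raw
    field is then divided by its maximum, giving d_w in [0, 1] per city
    (max exactly 1).  Scale-free: rescaling all distances leaves d_w
    unchanged.
    """
    D_w = np.asarray(D_w, dtype=float)
    if np.all(np.isnan(D_w)):
        return np.full(D_w.shape, np.nan)
    if is_water is None:
        is_water = D_w == 0.0
    is_water = np.asarray(is_water, dtype=bool)
    land = ~is_water & np.isfinite(D_w)
    raw = np.full(D_w.shape, np.nan)
    with np.errstate(divide="ignore"):
        raw[land] = 1.0 / D_w[land] ** 2
    if land.any():
        raw[is_water] = np.nanmax(raw[land])
    else:  # degenerate all-water grid
        raw[is_water] = 1.0
    return raw / np.nanmax(raw)
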