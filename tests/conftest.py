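import numpy as np
import pandas as pd
import pytest

from greenheat.grid import CityGrid, GridSpec


def make_grid(
    n_rows=5,
    n_cols=5,
    cell_size=1000.0,
    population=None,
    ndvi=None,
    water_mask=None,
    days_day=None,
    days_night=None,
    core_mask=None,
    climate_zone="Temperate",
):
    """Hand-assembled CityGrid for unit tests (all-land by default)."""
    n = n_rows * n_cols
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)
    rows, cols = np.divmod(np.arange(n), n_cols)
    x, y = spec.centroids()
    water = np.zeros(n, bool) if water_mask is None else np.asarray(water_mask).ravel()
    if water.any():
        from greenheat.grid import distance_to_water, dw_feature

        D = distance_to_water(water.reshape(n_rows, n_cols), cell_size).ravel()
        dw = dw_feature(D, is_water=water)
    else:
        D = np.full(n, np.nan)
        dw = np.full(n, np.nan)
    table = pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "row": rows, "col": cols, "x": x, "y": y,
            "population": (np.full(n, 100.0) if population is None
                           else np.asarray(population, float).ravel()),
            "ndvi": (np.full(n, 0.4) if ndvi is None
                     else np.asarray(ndvi, float).ravel()),
            "D_w": D, "d_w": dw,
            "days_day": (np.full(n, 5.0) if days_day is None
                         else np.asarray(days_day, float).ravel()),
            "days_night": (np.full(n, 3.0) if days_night is None
                           else np.asarray(days_night, float).ravel()),
            "is_water": water,
            "in_urban_core": (np.ones(n, bool) if core_mask is None
                              else np.asarray(core_mask).ravel()),
        }
    )
    return CityGrid(city_name="test", climate_zone=climate_zone, spec=spec,
                    pixels=table, dw_excluded=not water.any())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
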