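"""Exposure thresholds, exceedance counts, person-day exposure and SUHI.

A city's heat threshold is the q-th percentile (default 90) of the pooled
multi-year LST distribution — all pixels and all dates of the reference
period together — separately for the daytime and nighttime channels.
Exceedance is strict (LST > threshold) and is counted over the three
warmest months of each year; per-year counts averaged over years give the
mean seasonal day/night counts per pixel.

Exposure multiplies counts by resident population:

    TE_D = days_day * population        [person-days per season]
    TE_N = days_night * population
    TE_T = (TE_D + TE_N) / 2

City totals sum over pixels; per-capita exposure divides the total by the
city population.  SUHI (surface urban heat island) is the urban-core mean
LST minus the rural buffer-ring mean LST.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CityGrid
from .lst import LSTSeries

__all__ = [
    "ExposureThresholds",
    "ExposureResult",
    "SuhiResult",
    "compute_thresholds",
    "count_exceedances",
    "exposure_from_counts",
    "suhi",
]


@dataclass
class ExposureThresholds:
    t_day: float
    t_night: float
    q: float = 90.0
    reference_period: tuple[int, int] | None = None
    per_pixel: bool = False
    # populated when per_pixel=True: shape (n_pixels,)
    t_day_pixels: np.ndarray | None = None
    t_night_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.q < 100):
            raise ValueError("percentile q must be in (0, 100)")
        if not (np.isfinite(self.t_day) and np.isfinite(self.t_night)):
            raise ValueError("thresholds must be finite")


@dataclass
class ExposureResult:
    """Per-pixel and city-total exposure in person-days per warm season."""

    pixels: pd.DataFrame  # pixel_id, population, TE_D, TE_N, TE_T
    total_day: float
    total_night: float
    total: float
    per_capita: float  # days; NaN when the city population is zero
    thresholds: ExposureThresholds | None = None
    per_year: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "TE_D": self.total_day,
            "TE_N": self.total_night,
            "TE_T": self.total,
            "per_capita_days": self.per_capita,
        }
        if self.thresholds is not None:
            out["threshold_day"] = self.thresholds.t_day
            out["threshold_night"] = self.thresholds.t_night
            out["percentile"] = self.thresholds.q
        return out

    def save(self, pixels_csv, summary_json) -> None:
        self.pixels.to_csv(pixels_csv, index=False)
        with open(summary_json, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class SuhiResult:
    suhi: float  # degrees, core minus ring
    rural_ndvi_mean: float
    core_mean: float
    ring_mean: float


def compute_thresholds(
    lst: LSTSeries,
    q: float = 90.0,
    reference_period: tuple[int, int] | None = None,
    per_pixel: bool = False,
) -> ExposureThresholds:
    """q-th percentile of the pooled LST distribution per channel.

    Pooling runs over all pixels and all dates of the reference period
    (linear interpolation between order statistics).  ``per_pixel=True``
    computes one threshold per pixel instead (non-default variant).
    """
    if not (0 < q < 100):
        raise ValueError("percentile q must be in (0, 100)")
    pm = lst.period_mask(reference_period)
    if not pm.any():
        raise ValueError("empty reference period")

    def pooled(a: np.ndarray) -> float:
        v = a[:, pm]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("no valid LST observations in the reference period")
        return float(np.percentile(v, q))

    thr = ExposureThresholds(
        t_day=pooled(lst.day), t_night=pooled(lst.night),
        q=q, reference_period=reference_period, per_pixel=per_pixel,
    )
    if per_pixel:
        def per_pix(a: np.ndarray) -> np.ndarray:
            return np.nanpercentile(a[:, pm], q, axis=1)

        thr.t_day_pixels = per_pix(lst.day)
        thr.t_night_pixels = per_pix(lst.night)
    return thr


def count_exceedances(
    lst: LSTSeries,
    thr: ExposureThresholds,
    counting_period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Warm-season exceedance counts per pixel and year, plus year means.

    A day (night) counts when its LST is strictly greater than the day
    (night) threshold; NaN observations never count.  Years whose warm
    season has no dates are flagged and excluded from the mean.

    Returns a DataFrame indexed by pixel_id with columns
    ``days_day``, ``days_night`` (means over years) carrying a per-year
    table in ``.attrs['per_year']`` and the excluded years in
    ``.attrs['excluded_years']``.
    """
    season = lst.season_mask() & lst.period_mask(counting_period)
    years = np.asarray(lst.dates.year)
    uniq_years = np.unique(years[lst.period_mask(counting_period)])

    def channel_counts(values: np.ndarray, t_scalar: float,
                       t_pix: np.ndarray | None) -> pd.DataFrame:
        cols = {}
        for yr in uniq_years:
            sel = season & (years == yr)
            if not sel.any():
                continue
            v = values[:, sel]
            t = t_pix[:, None] if t_pix is not None else t_scalar
            with np.errstate(invalid="ignore"):
                cols[yr] = np.sum(v > t, axis=1)
        return pd.DataFrame(cols, index=lst.pixel_ids)

    td = thr.t_day_pixels if thr.per_pixel else None
    tn = thr.t_night_pixels if thr.per_pixel else None
    day_y = channel_counts(lst.day, thr.t_day, td)
    night_y = channel_counts(lst.night, thr.t_night, tn)
    excluded = sorted(set(uniq_years) - set(day_y.columns))

    out = pd.DataFrame(
        {
            "days_day": day_y.mean(axis=1),
            "days_night": night_y.mean(axis=1),
        }
    )
    out.index.name = "pixel_id"
    out.attrs["per_year_day"] = day_y
    out.attrs["per_year_night"] = night_y
    out.attrs["excluded_years"] = excluded
    return out


def exposure_from_counts(
    grid: CityGrid, thresholds: ExposureThresholds | None = None
) -> ExposureResult:
    """Person-day exposure from per-pixel counts and population."""
    df = grid.pixels
    for c in ("days_day", "days_night", "population"):
        if df[c].isna().all():
            raise ValueError(f"column {c} is entirely missing")
    pop = df["population"].to_numpy(float)
    dd = np.nan_to_num(df["days_day"].to_numpy(float))
    dn = np.nan_to_num(df["days_night"].to_numpy(float))
    te_d = dd * pop
    te_n = dn * pop
    te_t = 0.5 * (te_d + te_n)
    pixels = pd.DataFrame(
        {
            "pixel_id": df["pixel_id"].to_numpy(),
            "population": pop,
            "TE_D": te_d,
            "TE_N": te_n,
            "TE_T": te_t,
        }
    )
    total_pop = float(pop.sum())
    total = float(te_t.sum())
    return ExposureResult(
        pixels=pixels,
        total_day=float(te_d.sum()),
        total_night=float(te_n.sum()),
        total=total,
        per_capita=total / total_pop if total_pop > 0 else float("nan"),
        thresholds=thresholds,
    )


def suhi(grid: CityGrid, lst_mean: np.ndarray) -> SuhiResult:
    """Surface urban heat island: core mean LST minus buffer-ring mean LST.

    ``lst_mean`` is the per-pixel time-mean LST aligned with
    ``grid.pixels``.  The rural reference also reports its mean NDVI, the
    quantity SUHI correlates with across cities.
    """
    lst_mean = np.asarray(lst_mean, dtype=float)
    core = grid.pixels["in_urban_core"].to_numpy(bool)
    ring = ~core
    if not core.any() or not ring.any():
        raise ValueError("SUHI needs a non-empty urban core and buffer ring")
    core_mean = float(np.nanmean(lst_mean[core]))
    ring_mean = float(np.nanmean(lst_mean[ring]))
    return SuhiResult(
        suhi=core_mean - ring_mean,
        rural_ndvi_mean=float(np.nanmean(grid.pixels["ndvi"].to_numpy(float)[ring])),
        core_mean=core_mean,
        ring_mean=ring_mean,
    )
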