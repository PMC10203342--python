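"""Per-pixel daily land-surface-temperature series.

LST is the radiometric skin temperature retrieved twice a day (daytime and
nighttime overpasses).  The container keeps two (n_pixels, n_dates) arrays
aligned on a shared date axis, plus helpers to select the warm season (the
three warmest months of each year) and a reference period for threshold
computation.  Missing observations are NaN and never count as exceedances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LSTSeries"]


@dataclass
class LSTSeries:
    """Daily daytime/nighttime LST for every pixel of a city.

    Attributes
    ----------
    dates : pandas.DatetimeIndex, length n_dates
    day, night : ndarray of shape (n_pixels, n_dates)
        LST in degrees Celsius (any consistent unit works; thresholds
        inherit it).
    pixel_ids : ndarray of shape (n_pixels,)
    season_months : tuple of int
        The three warmest months (default June-August).
    """

    dates: pd.DatetimeIndex
    day: np.ndarray
    night: np.ndarray
    pixel_ids: np.ndarray
    season_months: tuple[int, ...] = (6, 7, 8)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.day = np.asarray(self.day, dtype=float)
        self.night = np.asarray(self.night, dtype=float)
        if self.day.shape != self.night.shape:
            raise ValueError("day and night arrays must share a shape")
        if self.day.shape != (len(self.pixel_ids), len(self.dates)):
            raise ValueError("LST arrays must be (n_pixels, n_dates)")

    @property
    def n_pixels(self) -> int:
        return self.day.shape[0]

    def channel(self, name: str) -> np.ndarray:
        if name not in ("day", "night"):
            raise ValueError("channel must be 'day' or 'night'")
        return getattr(self, name)

    def season_mask(self) -> np.ndarray:
        """Boolean date mask selecting the warm-season months."""
        return np.isin(self.dates.month, self.season_months)

    def period_mask(self, years: tuple[int, int] | None) -> np.ndarray:
        """Boolean date mask for an inclusive year range (None = all)."""
        if years is None:
            return np.ones(len(self.dates), dtype=bool)
        y0, y1 = years
        return (self.dates.year >= y0) & (self.dates.year <= y1)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)
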