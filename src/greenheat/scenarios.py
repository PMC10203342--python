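"""Counterfactual urban-greening scenarios.

Given fitted day/night spatial lag models, the engine predicts the total
exposure TE_T under modified NDVI surfaces while population, the
water-distance feature and the water mask stay at their observed values:

* Scenario "uniform": NDVI raised by a fixed increment delta at every pixel
  whose observed NDVI is below the cap (default 0.85), clipped at the cap.
* Scenario "targeted": the same cap rule applied only on the minimal set of
  highest-population pixels holding a given share (default 80%) of the city
  population, with the increment sized by bisection so the relative
  exposure change Delta TE_T(%) matches a reference reduction (typically
  the uniform scenario's).

The headline comparison statistic is the relative NDVI saving

    100 * (sum NDVI_targeted_after - sum NDVI_uniform_after) / sum NDVI_uniform_after

which is negative when targeting adds less total greenness for the same
exposure reduction; summaries additionally report its magnitude as
"savings".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CityGrid
from .slm import SpatialLagRegressor, slm_predict
from .weights import SpatialWeights

__all__ = [
    "ScenarioResult",
    "SweepTable",
    "apply_uniform_increment",
    "select_top_population",
    "predicted_total_exposure",
    "delta_te",
    "solve_targeted_increment",
    "ndvi_savings",
    "sweep_increments",
]

NDVI_CAP = 0.85
DEFAULT_SWEEP = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ScenarioResult:
    mode: str  # observed | uniform | targeted
    delta_applied: float
    ndvi_cap: float
    target_pixels: np.ndarray  # pixel ids; empty for uniform/observed
    te0: float
    te1: float
    delta_te_pct: float
    ndvi_sum_before: float
    ndvi_sum_after: float
    global_increment_pct: float
    feasible: bool = True
    best_achievable_delta_te_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "delta_applied": self.delta_applied,
            "ndvi_cap": self.ndvi_cap,
            "n_target_pixels": int(len(self.target_pixels)),
            "TE0": self.te0,
            "TE1": self.te1,
            "delta_te_pct": self.delta_te_pct,
            "ndvi_sum_before": self.ndvi_sum_before,
            "ndvi_sum_after": self.ndvi_sum_after,
            "global_increment_pct": self.global_increment_pct,
            "feasible": self.feasible,
            "best_achievable_delta_te_pct": self.best_achievable_delta_te_pct,
        }


@dataclass
class SweepTable:
    rows: pd.DataFrame  # delta_global, delta_te_pct, delta_local, savings...

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def apply_uniform_increment(
    grid: CityGrid, delta: float, cap: float = NDVI_CAP,
    target_pixels: np.ndarray | None = None,
) -> CityGrid:
    """Raise NDVI by ``delta`` up to ``cap`` on eligible pixels.

    Eligible pixels are land pixels with observed NDVI < cap (pixels
    already at or above the cap are untouched, as are water pixels);
    ``target_pixels`` restricts the increment to a pixel-id subset.
    Population, D_w/d_w and the water mask are never modified.
    """
    if delta < 0:
        raise ValueError("NDVI decrements are not modelled")
    if not (0 < cap <= 1):
        raise ValueError("cap must be in (0, 1]")
    out = grid.pixels.copy()
    ndvi = out["ndvi"].to_numpy(float)
    eligible = (~out["is_water"].to_numpy(bool)) & (ndvi < cap) & np.isfinite(ndvi)
    if target_pixels is not None:
        eligible &= out["pixel_id"].isin(np.asarray(target_pixels)).to_numpy()
    ndvi = ndvi.copy()
    ndvi[eligible] = np.minimum(ndvi[eligible] + delta, cap)
    out["ndvi"] = ndvi
    return CityGrid(
        city_name=grid.city_name, climate_zone=grid.climate_zone,
        spec=grid.spec, pixels=out, dw_excluded=grid.dw_excluded,
        extras=dict(grid.extras),
    )


def select_top_population(grid: CityGrid, share: float = 0.8) -> np.ndarray:
    """Minimal descending-population pixel prefix holding ``share`` of people.

    Pixels are sorted by population descending (ties by pixel_id ascending)
    and the shortest prefix whose cumulative population reaches
    ``share * total`` is returned as a pixel-id array.
    """
    if not (0 < share <= 1):
        raise ValueError("share must be in (0, 1]")
    df = grid.pixels
    total = float(df["population"].sum())
    if total <= 0:
        raise ValueError("total population must be positive")
    order = df.sort_values(["population", "pixel_id"],
                           ascending=[False, True], kind="stable")
    csum = order["population"].cumsum().to_numpy()
    n_keep = int(np.searchsorted(csum, share * total) + 1)
    return order["pixel_id"].to_numpy()[:n_keep]


def predicted_total_exposure(
    model_day: SpatialLagRegressor,
    model_night: SpatialLagRegressor,
    grid: CityGrid,
    W: SpatialWeights,
    season_length: float = 92.0,
) -> float:
    """Model-predicted TE_T (person-days) on the grid's current features.

    Features and population are taken on the pixels W was built over
    (``W.ids``); predicted counts are clipped to [0, season_length].
    """
    df = grid.pixels.set_index("pixel_id").loc[W.ids]
    feats = [df["ndvi"].to_numpy(float)]
    if not grid.dw_excluded:
        feats.append(df["d_w"].to_numpy(float))
    X = np.column_stack(feats)
    pop = df["population"].to_numpy(float)
    yd = slm_predict(model_day, X, W, clip=(0.0, season_length))
    yn = slm_predict(model_night, X, W, clip=(0.0, season_length))
    return float(np.sum(pop * 0.5 * (yd + yn)))


def delta_te(te0: float, te1: float) -> float:
    """Relative exposure change in percent: 100 (TE1 - TE0) / TE0.

    Signed — reductions come out negative; summaries report the magnitude.
    NaN when TE0 is zero.
    """
    if te0 == 0:
        return float("nan")
    return 100.0 * (te1 - te0) / te0


def _scenario_result(
    mode, delta, cap, targets, te0, te1, grid_before, grid_after, **kw
) -> ScenarioResult:
    nb = float(grid_before.pixels["ndvi"].sum())
    na = float(grid_after.pixels["ndvi"].sum())
    return ScenarioResult(
        mode=mode, delta_applied=delta, ndvi_cap=cap,
        target_pixels=np.asarray(targets), te0=te0, te1=te1,
        delta_te_pct=delta_te(te0, te1),
        ndvi_sum_before=nb, ndvi_sum_after=na,
        global_increment_pct=100.0 * (na - nb) / nb if nb else float("nan"),
        **kw,
    )


def run_uniform_scenario(
    model_day, model_night, grid: CityGrid, W: SpatialWeights,
    delta: float, cap: float = NDVI_CAP, season_length: float = 92.0,
) -> ScenarioResult:
    """Scenario 1: homogeneous NDVI increment on every below-cap pixel."""
    te0 = predicted_total_exposure(model_day, model_night, grid, W, season_length)
    after = apply_uniform_increment(grid, delta, cap)
    te1 = predicted_total_exposure(model_day, model_night, after, W, season_length)
    return _scenario_result("uniform", delta, cap, [], te0, te1, grid, after)


def solve_targeted_increment(
    model_day,
    model_night,
    grid: CityGrid,
    W: SpatialWeights,
    target_pixels: np.ndarray,
    target_delta_te: float,
    cap: float = NDVI_CAP,
    season_length: float = 92.0,
    rtol: float = 1e-6,
) -> tuple[float, ScenarioResult]:
    """Scenario 2: size the targeted increment to hit a reference reduction.

    Finds the increment delta applied only on ``target_pixels`` (cap rule
    unchanged) whose relative exposure change equals ``target_delta_te``
    (negative, in percent), by bisection on [0, cap].  TE1(delta) is
    monotone non-increasing, so the root is unique up to cap-saturated flat
    stretches; the smallest root is returned.  An unreachable target yields
    a ``feasible=False`` result carrying the best achievable change instead
    of raising.
    """
    if target_delta_te > 0:
        raise ValueError("target_delta_te must be a reduction (<= 0)")
    te0 = predicted_total_exposure(model_day, model_night, grid, W, season_length)

    def change(delta: float) -> tuple[float, CityGrid]:
        after = apply_uniform_increment(grid, delta, cap, target_pixels=target_pixels)
        te1 = predicted_total_exposure(model_day, model_night, after, W,
                                       season_length)
        return delta_te(te0, te1), after

    if target_delta_te == 0:
        dte, after = change(0.0)
        return 0.0, _scenario_result("targeted", 0.0, cap, target_pixels,
                                     te0, te0, grid, after)

    dte_cap, after_cap = change(cap)
    if dte_cap > target_delta_te:  # even full greening falls short
        te1_cap = te0 * (1 + dte_cap / 100)
        res = _scenario_result(
            "targeted", cap, cap, target_pixels, te0, te1_cap,
            grid, after_cap, feasible=False, best_achievable_delta_te_pct=dte_cap,
        )
        return cap, res

    lo, hi = 0.0, cap  # dte(lo) = 0 >= target >= dte(hi)
    while hi - lo > rtol * max(cap, 1.0):
        mid = 0.5 * (lo + hi)
        dte_mid, _ = change(mid)
        if dte_mid <= target_delta_te:
            hi = mid  # keep the smallest root: shrink from above
        else:
            lo = mid
    delta_local = hi
    dte, after = change(delta_local)
    res = _scenario_result("targeted", delta_local, cap, target_pixels,
                           te0, te0 * (1 + dte / 100), grid, after)
    return delta_local, res


def ndvi_savings(grid_uniform_after: CityGrid, grid_targeted_after: CityGrid) -> float:
    """Relative NDVI saving: 100 (NDVI_80 - NDVI_all) / NDVI_all.

    NDVI_all and NDVI_80 are city-wide NDVI sums after the uniform and the
    targeted intervention respectively; negative when targeting commits
    less total greenness.  NaN when NDVI_all is zero.
    """
    ndvi_all = float(grid_uniform_after.pixels["ndvi"].sum())
    ndvi_80 = float(grid_targeted_after.pixels["ndvi"].sum())
    if ndvi_all == 0:
        return float("nan")
    return 100.0 * (ndvi_80 - ndvi_all) / ndvi_all


def sweep_increments(
    model_day,
    model_night,
    grid: CityGrid,
    W: SpatialWeights,
    deltas: tuple[float, ...] = DEFAULT_SWEEP,
    share: float = 0.8,
    cap: float = NDVI_CAP,
    season_length: float = 92.0,
) -> SweepTable:
    """Uniform-versus-targeted comparison across a range of increments.

    For each global increment delta: the uniform-scenario exposure change,
    the targeted increment matching it, the NDVI saving, and the
    local-minus-global increment difference.  Infeasible targeted solves
    are marked explicitly rather than silently NaN'd.
    """
    if any(d <= 0 or d > cap for d in deltas):
        raise ValueError("sweep increments must lie in (0, cap]")
    targets = select_top_population(grid, share=share)
    rows = []
    for d in deltas:
        uni = run_uniform_scenario(model_day, model_night, grid, W, d, cap,
                                   season_length)
        uni_after = apply_uniform_increment(grid, d, cap)
        d_loc, tgt = solve_targeted_increment(
            model_day, model_night, grid, W, targets, uni.delta_te_pct,
            cap=cap, season_length=season_length,
        )
        tgt_after = apply_uniform_increment(grid, d_loc, cap,
                                            target_pixels=targets)
        sav = ndvi_savings(uni_after, tgt_after)
        rows.append(
            {
                "city": grid.city_name,
                "climate_zone": grid.climate_zone,
                "delta_global": d,
                "delta_te_pct": uni.delta_te_pct,
                "delta_local": d_loc,
                "feasible": tgt.feasible,
                "savings_pct": sav,
                "savings_magnitude_pct": abs(sav),
                "local_minus_global": d_loc - d,
            }
        )
    return SweepTable(rows=pd.DataFrame(rows))
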