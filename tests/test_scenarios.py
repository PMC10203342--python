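"""Counterfactual greening: increments, targeting, solver, savings, sweeps."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from greenheat.scenarios import (
    apply_uniform_increment,
    delta_te,
    ndvi_savings,
    predicted_total_exposure,
    run_uniform_scenario,
    select_top_population,
    solve_targeted_increment,
    sweep_increments,
)
from greenheat.slm import SpatialLagRegressor
from greenheat.synth import SyntheticConfig, make_city
from greenheat.weights import knn_weights


def model(intercept, coef, rho):
    m = SpatialLagRegressor()
    m.intercept_ = intercept
    m.coef_ = np.asarray(coef, float)
    m.rho_ = rho
    m.sigma2_ = 1.0
    m.loglik_ = 0.0
    m.converged_ = True
    return m


def fitted_city(seed=3, n=25, ndvi_range=(0.1, 0.8)):
    """Synthetic monocentric city with models fixed at the DGP truth."""
    cfg = SyntheticConfig(n_rows=n, n_cols=n, seed=seed,
                          ndvi_range=ndvi_range)
    grid, _ = make_city(cfg)
    df = grid.model_frame()
    W = knn_weights(df[["x", "y"]].to_numpy(float), k=8,
                    ids=df["pixel_id"].to_numpy())
    md = model(*(cfg.dgp_beta_day[0], cfg.dgp_beta_day[1:], cfg.dgp_rho))
    mn = model(*(cfg.dgp_beta_night[0], cfg.dgp_beta_night[1:], cfg.dgp_rho))
    return grid, W, md, mn


class TestApplyUniformIncrement:
    @pytest.mark.parametrize(
        "ndvi0, expected", [(0.50, 0.80), (0.70, 0.85), (0.90, 0.90)]
    )
    def test_cap_rule(self, ndvi0, expected):
        grid = make_grid(1, 3, ndvi=[ndvi0, 0.1, 0.1])
        out = apply_uniform_increment(grid, 0.3, cap=0.85)
        assert out.pixels["ndvi"].iloc[0] == pytest.approx(expected)

    def test_water_pixels_untouched(self):
        water = np.zeros((2, 2), bool)
        water[0, 0] = True
        grid = make_grid(2, 2, water_mask=water, ndvi=[0.0, 0.3, 0.3, 0.3])
        out = apply_uniform_increment(grid, 0.3)
        assert out.pixels["ndvi"].iloc[0] == 0.0

    def test_population_dw_and_water_never_modified(self):
        water = np.zeros((3, 3), bool)
        water[0, 0] = True
        grid = make_grid(3, 3, water_mask=water)
        out = apply_uniform_increment(grid, 0.4)
        for col in ("population", "D_w", "d_w", "is_water"):
            pd.testing.assert_series_equal(out.pixels[col], grid.pixels[col])

    def test_decrement_rejected(self):
        with pytest.raises(ValueError, match="decrement"):
            apply_uniform_increment(make_grid(2, 2), -0.1)

    def test_targeted_on_all_pixels_equals_uniform(self):
        grid = make_grid(3, 3, ndvi=np.linspace(0.1, 0.9, 9))
        uni = apply_uniform_increment(grid, 0.25)
        tgt = apply_uniform_increment(
            grid, 0.25, target_pixels=grid.pixels["pixel_id"].to_numpy()
        )
        pd.testing.assert_frame_equal(uni.pixels, tgt.pixels)


class TestSelectTopPopulation:
    def test_hand_cumulative(self):
        grid = make_grid(2, 2, population=[60, 25, 10, 5])
        ids = select_top_population(grid, share=0.8)
        assert sorted(ids) == [0, 1]  # 60 + 25 = 85 >= 80

    def test_uniform_population_proportionality(self):
        grid = make_grid(2, 5, population=np.full(10, 7.0))
        assert len(select_top_population(grid, share=0.8)) == 8

    def test_minimal_descending_prefix_oracle(self, rng):
        pop = rng.integers(0, 1000, 30).astype(float)
        grid = make_grid(5, 6, population=pop)
        ids = select_top_population(grid, share=0.8)
        # exhaustive check: the returned set is the minimal descending prefix
        order = sorted(range(30), key=lambda i: (-pop[i], i))
        csum = np.cumsum([pop[i] for i in order])
        m = int(np.searchsorted(csum, 0.8 * pop.sum()) + 1)
        assert list(ids) == order[:m]
        assert csum[m - 1] >= 0.8 * pop.sum()
        if m > 1:
            assert csum[m - 2] < 0.8 * pop.sum()

    def test_invalid_share_rejected(self):
        with pytest.raises(ValueError, match="share"):
            select_top_population(make_grid(2, 2), share=1.5)


class TestPredictedTotalExposure:
    def test_zero_population_annihilates(self):
        grid = make_grid(3, 3, population=np.zeros(9))
        W = knn_weights(grid.pixels[["x", "y"]].to_numpy(float), k=4,
                        ids=grid.pixels["pixel_id"].to_numpy())
        te = predicted_total_exposure(model(5, [1.0], 0.3), model(3, [1.0], 0.3),
                                      grid, W)
        assert te == 0.0

    def test_rho_zero_matches_longhand_arithmetic(self):
        grid = make_grid(2, 2, population=[10, 20, 30, 40],
                         ndvi=[0.1, 0.2, 0.3, 0.4])
        W = knn_weights(grid.pixels[["x", "y"]].to_numpy(float), k=3,
                        ids=grid.pixels["pixel_id"].to_numpy())
        md, mn = model(6.0, [-4.0], 0.0), model(4.0, [-2.0], 0.0)
        te = predicted_total_exposure(md, mn, grid, W)
        expect = 0.0
        for pop, v in [(10, 0.1), (20, 0.2), (30, 0.3), (40, 0.4)]:
            yd = 6.0 - 4.0 * v
            yn = 4.0 - 2.0 * v
            expect += pop * (yd + yn) / 2
        assert te == pytest.approx(expect, abs=1e-9)

    def test_te_strictly_decreasing_in_any_pixels_ndvi(self):
        grid, W, md, mn = fitted_city(n=12)
        te0 = predicted_total_exposure(md, mn, grid, W)
        bumped = grid.pixels.copy()
        target = bumped.index[~bumped["is_water"]][5]
        bumped.loc[target, "ndvi"] += 0.05
        grid.pixels = bumped
        te1 = predicted_total_exposure(md, mn, grid, W)
        assert te1 < te0


class TestDeltaTe:
    def test_reference_city_totals(self):
        # the two headline city totals: 164 -> 144 million person-days
        assert delta_te(164e6, 144e6) == pytest.approx(-12.195, abs=0.001)

    def test_identity_and_plain_arithmetic(self):
        assert delta_te(200.0, 200.0) == 0.0
        assert delta_te(200.0, 150.0) == -25.0

    def test_zero_baseline_undefined(self):
        assert np.isnan(delta_te(0.0, 5.0))


class TestSolveTargetedIncrement:
    def test_null_target_gives_zero_increment(self):
        grid, W, md, mn = fitted_city(n=10)
        targets = select_top_population(grid, 0.8)
        d, res = solve_targeted_increment(md, mn, grid, W, targets, 0.0)
        assert d == 0.0 and res.delta_te_pct == 0.0

    def test_closed_form_linear_case(self):
        """rho = 0, no cap binding: delta TE is linear in the increment, so
        the required increment follows in closed form."""
        grid = make_grid(2, 2, population=[100, 50, 10, 5],
                         ndvi=[0.2, 0.2, 0.2, 0.2])
        W = knn_weights(grid.pixels[["x", "y"]].to_numpy(float), k=3,
                        ids=grid.pixels["pixel_id"].to_numpy())
        md, mn = model(8.0, [-4.0], 0.0), model(6.0, [-2.0], 0.0)
        te0 = predicted_total_exposure(md, mn, grid, W)
        targets = np.array([0])  # the 100-person pixel only
        target_pct = -2.0
        d, res = solve_targeted_increment(md, mn, grid, W, targets, target_pct)
        # each unit of NDVI on pixel 0 removes 100 * (4 + 2)/2 person-days
        expect = (-target_pct / 100 * te0) / (100 * (4.0 + 2.0) / 2)
        assert d == pytest.approx(expect, abs=2e-6)
        assert res.delta_te_pct == pytest.approx(target_pct, abs=1e-4)

    def test_matches_dense_scan(self):
        grid, W, md, mn = fitted_city(n=12)
        targets = select_top_population(grid, 0.8)
        target_pct = -6.0
        d, _ = solve_targeted_increment(md, mn, grid, W, targets, target_pct)
        te0 = predicted_total_exposure(md, mn, grid, W)
        scan = np.arange(0.0, 0.85 + 1e-12, 1e-4)
        best = next(
            s for s in scan
            if delta_te(te0, predicted_total_exposure(
                md, mn, apply_uniform_increment(grid, s, target_pixels=targets),
                W)) <= target_pct
        )
        assert abs(d - best) <= 2e-4

    def test_achieved_change_hits_target_when_feasible(self):
        grid, W, md, mn = fitted_city(n=15)
        targets = select_top_population(grid, 0.8)
        uni = run_uniform_scenario(md, mn, grid, W, 0.3)
        d, res = solve_targeted_increment(md, mn, grid, W, targets,
                                          uni.delta_te_pct)
        assert res.feasible
        assert res.delta_te_pct == pytest.approx(uni.delta_te_pct, abs=1e-4)

    def test_unreachable_target_reports_infeasible(self):
        grid, W, md, mn = fitted_city(n=10)
        targets = select_top_population(grid, 0.8)
        d, res = solve_targeted_increment(md, mn, grid, W, targets, -95.0)
        assert not res.feasible
        assert res.best_achievable_delta_te_pct > -95.0
        assert d == res.ndvi_cap


class TestNdviSavings:
    def test_identity_and_arithmetic(self):
        grid = make_grid(2, 2, ndvi=[0.5, 0.5, 0.5, 0.5])
        assert ndvi_savings(grid, grid) == 0.0
        a = make_grid(2, 2, ndvi=np.full(4, 50.0))  # sums 200 vs 160
        b = make_grid(2, 2, ndvi=np.full(4, 40.0))
        assert ndvi_savings(a, b) == pytest.approx(-20.0)

    def test_targeting_commits_less_greenness_on_monocentric_city(self):
        grid, W, md, mn = fitted_city(n=15)
        targets = select_top_population(grid, 0.8)
        uni = run_uniform_scenario(md, mn, grid, W, 0.3)
        uni_after = apply_uniform_increment(grid, 0.3)
        d, _ = solve_targeted_increment(md, mn, grid, W, targets,
                                        uni.delta_te_pct)
        tgt_after = apply_uniform_increment(grid, d, target_pixels=targets)
        sav = ndvi_savings(uni_after, tgt_after)
        assert abs(sav) > 0
        assert sav < 0  # targeted adds less total NDVI


class TestSweep:
    def test_single_delta_consistent_with_individual_ops(self):
        grid, W, md, mn = fitted_city(n=10)
        table = sweep_increments(md, mn, grid, W, deltas=(0.1,)).rows
        assert len(table) == 1
        uni = run_uniform_scenario(md, mn, grid, W, 0.1)
        assert table["delta_te_pct"].iloc[0] == pytest.approx(uni.delta_te_pct)

    def test_exposure_reduction_monotone_in_increment(self):
        grid, W, md, mn = fitted_city(n=15)
        table = sweep_increments(md, mn, grid, W).rows
        dte = table["delta_te_pct"].to_numpy()
        assert np.all(np.diff(np.abs(dte)) >= -1e-9)  # stronger greening helps more

    def test_exposure_response_near_linear_below_the_cap(self):
        # moderate greenness leaves headroom below the 0.85 cap for every
        # sweep increment, the regime where the response stays linear
        grid, W, md, mn = fitted_city(n=15, ndvi_range=(0.1, 0.5))
        table = sweep_increments(md, mn, grid, W).rows
        dte = table["delta_te_pct"].to_numpy()
        coef = np.polyfit(table["delta_global"], dte, 1)
        resid = dte - np.polyval(coef, table["delta_global"])
        r2 = 1 - resid @ resid / ((dte - dte.mean()) @ (dte - dte.mean()))
        assert r2 > 0.99

    def test_invalid_delta_rejected(self):
        grid, W, md, mn = fitted_city(n=10)
        with pytest.raises(ValueError, match="increments"):
            sweep_increments(md, mn, grid, W, deltas=(0.9,))
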