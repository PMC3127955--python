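import itertools

import numpy as np
import pandas as pd
import pytest

from anisosmooth import (
    DesignSchedule,
    KernelSpec,
    ObserverSpec,
    aggregate_conditions,
    aggregate_pairs,
    explained_variance,
    fit_model,
    make_glp,
    nested_f_test,
    predict_bias,
    simulate_experiment,
    systematic_ceiling,
    wls_objective,
)
from anisosmooth.bias_model import ConditionGrid, ModelSpec
from anisosmooth.fitting import (
    VARIANCE_FLOOR,
    AggregationError,
    FitResult,
    trial_wrss,
)


def tiny_table(rows):
    """rows: (participant, orientation, ratio, bias)"""
    return pd.DataFrame(
        {
            "participant": [r[0] for r in rows],
            "frame": "circular",
            "block": 0,
            "trial": range(len(rows)),
            "orientation_deg": [r[1] for r in rows],
            "aspect_ratio": [r[2] for r in rows],
            "response_deg": [(r[1] + r[3]) % 180 for r in rows],
            "bias_deg": [r[3] for r in rows],
        }
    )


class TestAggregatePairs:
    def test_perfectly_antisymmetric_pair(self):
        table = tiny_table(
            [(0, 7.5, 0.5, 2.0), (0, 7.5, 0.5, 2.0), (0, 172.5, 0.5, -2.0), (0, 172.5, 0.5, -2.0)]
        )
        agg = aggregate_pairs(table)
        assert len(agg) == 1
        assert agg.loc[0, "orientation_deg"] == pytest.approx(7.5)
        assert agg.loc[0, "mean_bias"] == pytest.approx(2.0)
        assert agg.loc[0, "n"] == 4

    def test_sign_flip_then_average(self):
        table = tiny_table(
            [(0, 22.5, 0.5, 3.0), (0, 22.5, 0.5, 3.0), (0, 157.5, 0.5, -1.0), (0, 157.5, 0.5, -1.0)]
        )
        agg = aggregate_pairs(table)
        assert agg.loc[0, "mean_bias"] == pytest.approx(2.0)

    def test_unpaired_orientation_rejected(self):
        table = tiny_table([(0, 7.5, 0.5, 1.0), (0, 22.5, 0.5, 1.0)])
        with pytest.raises(AggregationError):
            aggregate_pairs(table)

    def test_variance_floor_applied(self):
        table = tiny_table(
            [(0, 7.5, 0.5, 1.0), (0, 7.5, 0.5, 1.0), (0, 172.5, 0.5, -1.0), (0, 172.5, 0.5, -1.0)]
        )
        agg = aggregate_pairs(table)
        assert agg.loc[0, "variance"] == VARIANCE_FLOOR

    def test_design_collapses_to_six_orientations(self, simulated_table):
        agg = aggregate_pairs(simulated_table)
        assert len(agg) == 18
        assert (agg["n"] == 60).all()
        # 30 measurements per raw condition feed each pair cell
        raw = aggregate_conditions(simulated_table)
        assert (raw["n"] == 30).all()

    def test_circular_mean_near_wrap(self):
        # responses straddling +/-90: arithmetic mean would be ~0, circular ~+89.5
        table = tiny_table(
            [(0, 7.5, 0.5, 89.0), (0, 7.5, 0.5, -90.0), (0, 172.5, 0.5, -89.0), (0, 172.5, 0.5, 90.0)]
        )
        agg = aggregate_pairs(table)
        assert abs(agg.loc[0, "mean_bias"]) > 85.0


class TestWLSObjective:
    @pytest.fixture()
    def conditions(self):
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid("homogeneous", grid)
        model.params = np.array([0.84, 2.08])
        from anisosmooth import predict_grid

        preds = predict_grid(model, grid)
        return pd.DataFrame(
            {
                "orientation_deg": [c[0] for c in grid.cells],
                "aspect_ratio": [c[1] for c in grid.cells],
                "mean_bias": preds,
                "variance": 4.0,
                "n": 60,
                "within_ss": 4.0 * 59,
            }
        )

    def test_zero_at_exact_predictions(self, conditions):
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid("homogeneous", grid)
        assert wls_objective(model, np.array([0.84, 2.08]), conditions) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_isotropic_gives_total_weighted_signal(self, conditions):
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid("isotropic", grid)
        expected = np.sum(conditions["mean_bias"] ** 2 / conditions["variance"])
        assert wls_objective(model, np.empty(0), conditions) == pytest.approx(expected)

    def test_infeasible_parameters_penalized(self, conditions):
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid("homogeneous_oriented", grid)
        feasible = wls_objective(model, np.array([0.8, 2.0, 0.1]), conditions)
        penalty = wls_objective(model, np.array([0.8, 2.0, 5.0]), conditions)
        assert penalty > 1e10 > feasible

    def test_grid_search_oracle_brackets_fit(self, conditions):
        """A dense search over the covariance difference cannot beat the fit."""
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid("homogeneous", grid)
        fit = fit_model("homogeneous", conditions, select_scale=False)
        best_grid = min(
            wls_objective(model, np.array([ah, av]), conditions)
            for ah, av in itertools.product(
                np.linspace(0.1, 3.0, 30), np.linspace(0.5, 4.0, 36)
            )
        )
        assert fit.cell_wrss <= best_grid + 1e-12


class TestFitModel:
    def test_noiseless_recovery_of_covariance_difference(self):
        """The bias data pin a_v**2 - a_h**2 (the identifiable combination)."""
        design = DesignSchedule(participants=1)
        obs = ObserverSpec(sigma_base=1e-9, seed=42)
        table = simulate_experiment(design, [obs], quantize=False)
        fit = fit_model("homogeneous", aggregate_pairs(table), select_scale=False)
        delta = fit.params[1] ** 2 - fit.params[0] ** 2
        assert fit.cell_wrss < 1e-6
        assert delta == pytest.approx(2.08**2 - 0.84**2, abs=1e-3)

    def test_zero_bias_data_flagged_non_identifiable(self):
        table = tiny_table(
            [
                (0, theta, ratio, 0.0)
                for theta in (7.5, 37.5, 67.5, 112.5, 142.5, 172.5)
                for ratio in (0.5, 0.8)
                for _ in range(3)
            ]
        )
        fit = fit_model("homogeneous", aggregate_pairs(table))
        assert fit.cell_wrss == pytest.approx(0.0, abs=1e-12)
        assert not fit.identifiable

    def test_two_stage_fit_keeps_wrss(self, simulated_table):
        """Scale selection moves along the flat ridge: radii change, WRSS not."""
        agg = aggregate_pairs(simulated_table)
        free = fit_model("homogeneous", agg, select_scale=False)
        scaled = fit_model("homogeneous", agg, select_scale=True)
        assert scaled.wrss == pytest.approx(free.wrss, rel=1e-9)
        assert scaled.params[1] ** 2 - scaled.params[0] ** 2 == pytest.approx(
            free.params[1] ** 2 - free.params[0] ** 2, rel=1e-6
        )

    def test_monotone_nesting_of_wrss(self, simulated_table):
        agg = aggregate_pairs(simulated_table)
        fits = {
            kind: fit_model(kind, agg)
            for kind in (
                "isotropic",
                "homogeneous",
                "homogeneous_oriented",
                "radial_heterogeneous",
                "angular_heterogeneous",
            )
        }
        assert fits["isotropic"].wrss >= fits["homogeneous"].wrss
        assert fits["homogeneous"].wrss >= fits["radial_heterogeneous"].wrss
        assert fits["homogeneous_oriented"].wrss >= fits["angular_heterogeneous"].wrss

    def test_median_recovery_across_many_participants(self):
        """Median recovered radii across 20 synthetic participants land
        within 15% of the generating kernel (0.84, 2.08)."""
        design = DesignSchedule(participants=1)
        a_h, a_v = [], []
        for s in range(20):
            table = simulate_experiment(design, [ObserverSpec(seed=90_000 + s)])
            fit = fit_model("homogeneous", aggregate_pairs(table), seed=0)
            a_h.append(fit.params[0])
            a_v.append(fit.params[1])
        assert np.median(a_h) == pytest.approx(0.84, rel=0.15)
        assert np.median(a_v) == pytest.approx(2.08, rel=0.15)

    def test_json_roundtrip(self, simulated_table):
        fit = fit_model("homogeneous", aggregate_pairs(simulated_table))
        back = FitResult.from_json(fit.to_json())
        assert back.wrss == pytest.approx(fit.wrss)
        np.testing.assert_allclose(back.params, fit.params)
        assert back.n_obs == fit.n_obs


class TestNestedFTest:
    @staticmethod
    def make_fit(kind, wrss, n_free, n_obs=1080):
        grid = ConditionGrid.default(aggregated=True)
        model = ModelSpec.for_grid(kind, grid)
        return FitResult(
            model=model,
            params=np.empty(0),
            wrss=wrss,
            n_free=n_free,
            n_obs=n_obs,
            converged=True,
            n_starts=0,
        )

    def test_direct_formula_arithmetic(self):
        restricted = self.make_fit("isotropic", 110.0, 0)
        full = self.make_fit("homogeneous", 100.0, 2)
        res = nested_f_test(restricted, full)
        assert res.F == pytest.approx((10.0 / 2.0) / (100.0 / 1078.0))
        assert (res.df1, res.df2) == (2, 1078)
        assert 0.0 < res.p_value < 1e-6

    def test_identical_fits_give_zero(self):
        res = nested_f_test(
            self.make_fit("homogeneous", 50.0, 2),
            self.make_fit("radial_heterogeneous", 50.0, 6),
        )
        assert res.F == 0.0 and res.p_value == pytest.approx(1.0)

    def test_optimizer_failure_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = nested_f_test(
                self.make_fit("homogeneous", 50.0, 2),
                self.make_fit("radial_heterogeneous", 60.0, 6),
            )
        assert res.F == 0.0

    def test_non_nested_kinds_rejected(self):
        with pytest.raises(ValueError):
            nested_f_test(
                self.make_fit("radial_heterogeneous", 50.0, 6),
                self.make_fit("homogeneous_oriented", 40.0, 3),
            )

    def test_invariant_under_weight_rescaling(self, simulated_table):
        agg = aggregate_pairs(simulated_table)
        # rescaling the weights means rescaling 1/variance; within_ss is data
        scaled = agg.copy()
        scaled["variance"] *= 7.0
        f1 = nested_f_test(
            fit_model("homogeneous", agg), fit_model("radial_heterogeneous", agg)
        )
        f2 = nested_f_test(
            fit_model("homogeneous", scaled),
            fit_model("radial_heterogeneous", scaled),
        )
        assert f2.F == pytest.approx(f1.F, rel=1e-6)


class TestExplainedVariance:
    def test_condition_means_reach_the_ceiling(self, simulated_table):
        """The saturated-mean model attains the systematic ceiling exactly."""
        agg = aggregate_conditions(simulated_table)
        grid = ConditionGrid.default()
        model = ModelSpec.for_grid("homogeneous", grid)
        fit = fit_model("homogeneous", agg)
        ceiling = systematic_ceiling(simulated_table)
        assert explained_variance(fit, simulated_table) <= ceiling + 1e-12

        # substituting the condition (circular) means as predictions gives
        # the ceiling
        from scipy.stats import circmean

        means = simulated_table.groupby(["orientation_deg", "aspect_ratio"])[
            "bias_deg"
        ].transform(lambda x: circmean(x, low=-90, high=90))
        from anisosmooth.fitting import _r_squared

        r2 = _r_squared(
            simulated_table,
            simulated_table["bias_deg"].to_numpy(),
            means.to_numpy(),
            weighted=False,
        )
        assert r2 == pytest.approx(ceiling, abs=1e-6)

    def test_zero_predictions_on_zero_mean_data(self):
        rows = []
        for theta in (7.5, 172.5):
            for b in (-1.0, 1.0):
                rows.append((0, theta, 0.5, b))
        table = tiny_table(rows * 3)
        grid = ConditionGrid(cells=((7.5, 0.5), (172.5, 0.5)))
        model = ModelSpec.for_grid("isotropic", grid)
        fit = FitResult(
            model=model, params=np.empty(0), wrss=0.0, n_free=0, n_obs=12,
            converged=True, n_starts=0,
        )
        assert explained_variance(fit, table) == pytest.approx(0.0, abs=1e-12)

    def test_trial_wrss_adds_within_cell_scatter(self, simulated_table):
        agg = aggregate_pairs(simulated_table)
        grid_model = ModelSpec.for_grid(
            "isotropic", ConditionGrid.default(aggregated=True)
        )
        cell = wls_objective(grid_model, np.empty(0), agg)
        trial = trial_wrss(grid_model, np.empty(0), agg)
        within = float((agg["within_ss"] / agg["variance"]).sum())
        mean_term = float(
            (agg["n"] * agg["mean_bias"] ** 2 / agg["variance"]).sum()
        )
        assert trial == pytest.approx(mean_term + within, rel=1e-12)
        assert trial > cell
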