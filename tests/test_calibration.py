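import numpy as np
import pandas as pd
import pytest

from lakeshift import calibration as cal
from lakeshift.forcing import DAYS_PER_YEAR
from lakeshift.model import LAYER_DIAGS, SCALAR_DIAGS, RunResult
from lakeshift.state import N_VARS, LakeState


class TestFitMetrics:
    def test_perfect_fit(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        m = cal.fit_metrics(o, o)
        assert (m.r2, m.mare, m.re, m.rmse, m.bias) == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_ten_percent_overprediction(self):
        o = np.array([1.0, 2.0, 5.0, 10.0])
        m = cal.fit_metrics(1.1 * o, o)
        assert m.bias == pytest.approx(10.0)
        assert m.re == pytest.approx(0.1)
        assert m.mare == pytest.approx(0.1)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        o = rng.uniform(1, 10, 20)
        s = o + rng.normal(0, 1, 20)
        perm = rng.permutation(20)
        m1, m2 = cal.fit_metrics(s, o), cal.fit_metrics(s[perm], o[perm])
        for f in ("r2", "mare", "re", "rmse", "bias"):
            assert getattr(m1, f) == pytest.approx(getattr(m2, f))

    def test_scale_behaviour(self):
        rng = np.random.default_rng(4)
        o = rng.uniform(1, 10, 30)
        s = o * rng.uniform(0.8, 1.2, 30)
        m1, m2 = cal.fit_metrics(s, o), cal.fit_metrics(5 * s, 5 * o)
        assert m2.rmse == pytest.approx(5 * m1.rmse)
        for f in ("r2", "mare", "re", "bias"):
            assert getattr(m2, f) == pytest.approx(getattr(m1, f))

    def test_near_zero_observations_inflate_mare_over_re(self):
        """With many near-zero observations MARE is inflated while RE stays
        moderate — the pattern seen in nitrate fit statistics where a large
        MARE coexists with a small RE."""
        rng = np.random.default_rng(5)
        o = np.concatenate([np.full(20, 0.01), np.full(5, 4.0)])
        s = o + rng.normal(0, 0.05, 25)
        m = cal.fit_metrics(np.abs(s), o)
        assert m.mare > 5 * m.re
        assert m.re < 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_metrics(np.array([1.0]), np.array([1.0]))


class TestLogLikelihood:
    def make_pairs(self, resid, var="chl"):
        n = len(resid)
        obs = np.linspace(1, 10, n)
        return pd.DataFrame({"variable": var, "day": np.arange(n),
                             "sim": obs + resid, "obs": obs})

    def test_perfect_fit_capped(self):
        pairs = self.make_pairs(np.zeros(10))
        assert cal.log_likelihood(pairs) == cal.LL_CAP

    def test_doubling_residuals_lowers_by_n_ln2(self):
        rng = np.random.default_rng(6)
        r = rng.normal(0, 1, 25)
        l1 = cal.log_likelihood(self.make_pairs(r))
        l2 = cal.log_likelihood(self.make_pairs(2 * r))
        assert l1 - l2 == pytest.approx(25 * np.log(2))

    def test_extra_variable_shifts_by_constant(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 1, 20)
        extra = self.make_pairs(rng.normal(0, 0.5, 15), var="tp")
        base_a = cal.log_likelihood(self.make_pairs(r))
        base_b = cal.log_likelihood(self.make_pairs(2 * r))
        full_a = cal.log_likelihood(pd.concat([self.make_pairs(r), extra]))
        full_b = cal.log_likelihood(pd.concat([self.make_pairs(2 * r), extra]))
        assert full_a - base_a == pytest.approx(full_b - base_b)
        assert (full_a > full_b) == (base_a > base_b)


class TestDifferentialEvolution:
    def test_sphere_benchmark(self):
        res = cal.differential_evolution(
            lambda x: -np.sum(x ** 2), np.array([[-5.0, 5.0]] * 5),
            pop_size=50, generations=200, seed=3)
        assert -res.best_objective < 1e-2
        assert np.all(np.abs(res.best) < 0.1)

    def test_optimum_at_bound_edge(self):
        res = cal.differential_evolution(
            lambda x: -(x[0] - 10.0) ** 2, np.array([[-1.0, 1.0]]),
            pop_size=10, generations=60, seed=0)
        assert res.best[0] == pytest.approx(1.0, abs=1e-6)

    def test_seeded_determinism(self):
        def f(x):
            return -np.sum((x - 0.3) ** 2)

        bounds = np.array([[-2.0, 2.0]] * 3)
        r1 = cal.differential_evolution(f, bounds, pop_size=12, generations=20, seed=9)
        r2 = cal.differential_evolution(f, bounds, pop_size=12, generations=20, seed=9)
        assert np.array_equal(r1.best, r2.best)
        assert np.array_equal(r1.history, r2.history)

    def test_best_objective_non_decreasing(self):
        res = cal.differential_evolution(
            lambda x: -np.sum(np.abs(x)), np.array([[-3.0, 3.0]] * 2),
            pop_size=8, generations=30, seed=2)
        assert np.all(np.diff(res.history) >= 0)

    def test_candidates_respect_bounds(self):
        bounds = np.array([[0.0, 1.0], [5.0, 6.0]])
        res = cal.differential_evolution(
            lambda x: float(x.sum()), bounds, pop_size=8, generations=25, seed=4)
        assert np.all(res.population >= bounds[:, 0])
        assert np.all(res.population <= bounds[:, 1])

    def test_nonfinite_objective_rejected(self):
        def f(x):
            return np.nan if x[0] > 0 else float(x[0])

        res = cal.differential_evolution(f, np.array([[-1.0, 1.0]]),
                                         pop_size=6, generations=10, seed=1)
        assert np.isfinite(res.best_objective)


class TestNarrowRanges:
    def test_top_decile_hand_selection(self):
        rng = np.random.default_rng(11)
        pop = rng.uniform(0, 10, (40, 2))
        obj = -np.sum((pop - 5.0) ** 2, axis=1)
        old = np.array([[0.0, 10.0], [0.0, 10.0]])
        new = cal.narrow_ranges(pop, obj, old, keep_frac=0.1, expand_frac=0.0)
        top4 = pop[np.argsort(obj)[::-1][:4]]
        assert new[:, 0] == pytest.approx(top4.min(axis=0))
        assert new[:, 1] == pytest.approx(top4.max(axis=0))

    def test_new_range_subset_of_old(self):
        rng = np.random.default_rng(12)
        pop = rng.uniform(-1, 1, (30, 3))
        obj = rng.normal(size=30)
        old = np.array([[-1.0, 1.0]] * 3)
        new = cal.narrow_ranges(pop, obj, old, keep_frac=0.3, expand_frac=5.0)
        assert np.all(new[:, 0] >= old[:, 0])
        assert np.all(new[:, 1] <= old[:, 1])

    def test_degenerate_population_expanded_point(self):
        pop = np.full((20, 1), 0.4)
        obj = np.zeros(20)
        old = np.array([[0.0, 1.0]])
        new = cal.narrow_ranges(pop, obj, old, expand_frac=0.1)
        assert new[0, 0] < 0.4 < new[0, 1]

    def test_keep_all_with_large_expansion_returns_old(self):
        rng = np.random.default_rng(13)
        pop = rng.uniform(0, 1, (25, 2))
        old = np.array([[0.0, 1.0]] * 2)
        new = cal.narrow_ranges(pop, rng.normal(size=25), old,
                                keep_frac=1.0, expand_frac=100.0)
        assert new == pytest.approx(old)


def two_layer_result(grid2):
    n_days = 5
    layers = {k: np.zeros((n_days, 2)) for k in LAYER_DIAGS}
    scalars = {k: np.zeros(n_days) for k in SCALAR_DIAGS}
    layers["po4"][:] = [10.0, 20.0]  # bottom layer 10, surface 20
    days = np.arange(n_days)
    return RunResult(grid=grid2, day_index=days, doy=days, layers=layers,
                     scalars=scalars, final_state=LakeState(np.zeros((N_VARS, 2))),
                     n_days=n_days)


@pytest.fixture(scope="module")
def grid2(hyps):
    from lakeshift.grid import build_grid

    return build_grid(hyps, 2, zoom=0.0)


class TestDepthMatching:
    def test_uniform_column_any_depth(self, grid2):
        res = two_layer_result(grid2)
        res.layers["po4"][:] = 4.2
        for depth in (0.1, 1.0, 2.6):
            assert cal.depth_matched_extract(res, "po4", 2, depth) == pytest.approx(4.2)

    def test_full_depth_equals_column_mean(self, grid2):
        res = two_layer_result(grid2)
        v = grid2.volumes
        expected = (10.0 * v[0] + 20.0 * v[1]) / v.sum()
        assert cal.depth_matched_extract(res, "po4", 0, 2.6) == pytest.approx(expected)

    def test_two_layer_pool_hand_calculation(self, grid2):
        """A sample pooled over the surface layer plus half of the bottom
        layer weights the layers by their overlapped volumes."""
        res = two_layer_result(grid2)
        h_bottom = grid2.heights[0]
        depth = grid2.heights[1] + 0.5 * h_bottom
        v_top = grid2.volumes[1]
        v_bot_half = grid2.volumes[0] * 0.5
        expected = (20.0 * v_top + 10.0 * v_bot_half) / (v_top + v_bot_half)
        assert cal.depth_matched_extract(res, "po4", 1, depth) == pytest.approx(expected)

    def test_day_outside_window_raises(self, grid2):
        res = two_layer_result(grid2)
        with pytest.raises(KeyError):
            cal.depth_matched_extract(res, "po4", 99, 1.0)

    def test_extract_pairs_skips_out_of_window(self, grid2):
        from lakeshift.synthetic import ObservationSet

        res = two_layer_result(grid2)
        obs = ObservationSet(pd.DataFrame({
            "variable": ["po4", "po4", "po4"],
            "day": [1, 3, 400],
            "sample_depth_m": [2.6, 2.6, 2.6],
            "value": [15.0, 15.0, 15.0],
            "error_fraction": [0.15] * 3,
        }))
        pairs = cal.extract_pairs(res, obs)
        assert len(pairs) == 2


class TestStepwise:
    def test_unknown_parameter_rejected_before_any_run(self):
        from lakeshift.parameters import default_parameters
        from lakeshift.synthetic import ObservationSet

        steps = [cal.CalibrationStep(1, "bad", ("chl",), ("no_such_param",), 10)]
        obs = ObservationSet(pd.DataFrame({
            "variable": ["chl", "chl"], "day": [0, 1],
            "sample_depth_m": [1.0, 1.0], "value": [1.0, 2.0],
            "error_fraction": [0.2, 0.2]}))

        def runner(p):  # pragma: no cover - must not be called
            raise AssertionError("runner should not run")

        with pytest.raises(KeyError):
            cal.stepwise_calibrate(runner, default_parameters(), steps, obs)

    def test_consecutive_steps_narrow_search_space(self, grid1, params, forcing_2yr):
        """A repeated step searches within the previous step's narrowed
        range (monotone narrowing invariant)."""
        from lakeshift.model import LakeModel
        from lakeshift.synthetic import (SyntheticLakeSpec, gen_observations)

        model = LakeModel(grid1, params, dt=1.0)
        res = model.run(forcing_2yr, initial="turbid", n_days=365)
        obs = gen_observations(res, SyntheticLakeSpec(), seed=5, variables=["chl"])
        step = dict(variables=("chl",), parameters=("dia_mu_max",), budget=16)
        steps = [cal.CalibrationStep(1, "a", **step), cal.CalibrationStep(2, "b", **step)]

        def runner(p):
            return LakeModel(grid1, p, dt=1.0).run(forcing_2yr, initial="turbid",
                                                   n_days=365)

        _, reports = cal.stepwise_calibrate(runner, params, steps, obs, seed=2)
        b1 = reports[0].bounds_after["dia_mu_max"]
        b2 = reports[1].bounds_after["dia_mu_max"]
        assert b2[0] >= b1[0] - 1e-12
        assert b2[1] <= b1[1] + 1e-12
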