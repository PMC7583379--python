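import numpy as np
import pandas as pd
import pytest

from lakeshift import scenario as sc
from lakeshift.forcing import DAYS_PER_YEAR
from lakeshift.model import LAYER_DIAGS, SCALAR_DIAGS, RunResult
from lakeshift.state import LakeState


class TestMultiplierGrid:
    def test_default_grid_has_75_multipliers(self):
        m = sc.multiplier_grid()
        assert len(m) == 75
        assert m[0] == pytest.approx(0.02)
        assert m[-1] == pytest.approx(1.50)

    def test_degenerate_single_baseline(self):
        assert sc.multiplier_grid(0, 0, 2) == pytest.approx([1.0])

    def test_small_enumeration(self):
        assert sc.multiplier_grid(-4, 4, 2) == pytest.approx(
            [0.96, 0.98, 1.00, 1.02, 1.04])

    def test_non_divisible_range_rejected(self):
        with pytest.raises(ValueError):
            sc.multiplier_grid(-98, 50, 3)


class TestForcingConstruction:
    def test_loop_baseline_duration_and_repetition(self, forcing_2yr):
        f = forcing_2yr.tile(3)  # 6 years of history
        window = (DAYS_PER_YEAR, DAYS_PER_YEAR * 2)  # one-year baseline
        looped = sc.loop_baseline(f, window, 12)
        assert looped.n_days == 12 * DAYS_PER_YEAR
        base = f.slice(*window)
        assert np.array_equal(looped.discharge[:DAYS_PER_YEAR], base.discharge)
        assert np.array_equal(looped.discharge[5 * DAYS_PER_YEAR:6 * DAYS_PER_YEAR],
                              base.discharge)
        assert looped.discharge.sum() == pytest.approx(12 * base.discharge.sum())

    def test_loop_baseline_identity(self, forcing_2yr):
        window = (0, DAYS_PER_YEAR)
        once = sc.loop_baseline(forcing_2yr, window, 1)
        assert np.array_equal(once.air_temp, forcing_2yr.air_temp[:DAYS_PER_YEAR])

    def test_p_multiplier_scales_load_exactly(self, forcing_2yr, lake_spec):
        base_load = forcing_2yr.areal_p_load(lake_spec.surface_area)
        for mult in (0.02, 0.5, 1.0, 1.5):
            scaled = sc.apply_p_multiplier(forcing_2yr, mult)
            load = scaled.areal_p_load(lake_spec.surface_area)
            assert load == pytest.approx(mult * base_load, rel=1e-12)
            # nitrogen load untouched
            assert scaled.areal_n_load(lake_spec.surface_area) == pytest.approx(
                forcing_2yr.areal_n_load(lake_spec.surface_area), rel=1e-12)

    def test_branch_forcing_lengths(self, forcing_2yr):
        history = forcing_2yr.tile(8)  # 16 yr of history
        window = (11 * DAYS_PER_YEAR, 16 * DAYS_PER_YEAR)
        turbid = sc.build_branch_forcing(history, sc.ScenarioSpec(
            branch="turbid", multiplier=0.5, baseline_start=window[0]))
        clear = sc.build_branch_forcing(history, sc.ScenarioSpec(
            branch="clear", multiplier=0.5, baseline_start=window[0],
            establishment_years=20))
        assert turbid.n_days == (16 + 60) * DAYS_PER_YEAR
        assert clear.n_days - turbid.n_days == 20 * DAYS_PER_YEAR

    def test_turbid_baseline_is_exact_copies(self, forcing_2yr):
        history = forcing_2yr.tile(8)
        spec = sc.ScenarioSpec(branch="turbid", multiplier=1.0,
                               baseline_start=11 * DAYS_PER_YEAR)
        f = sc.build_branch_forcing(history, spec)
        scen = f.slice(16 * DAYS_PER_YEAR, f.n_days)
        base = history.slice(11 * DAYS_PER_YEAR, 16 * DAYS_PER_YEAR)
        for rep in range(12):
            seg = scen.slice(rep * 5 * DAYS_PER_YEAR, (rep + 1) * 5 * DAYS_PER_YEAR)
            assert np.array_equal(seg.concentrations["po4"], base.concentrations["po4"])

    def test_default_grid_yields_150_scenarios(self):
        mults = sc.multiplier_grid()
        specs = [sc.ScenarioSpec(branch=b, multiplier=m, baseline_start=0,
                                 establishment_years=20 if b == "clear" else 0)
                 for b in ("turbid", "clear") for m in mults]
        assert len(specs) == 150


def fabricate_result(grid, values_by_doy, n_years=6, var="chl"):
    """RunResult with a prescribed day-of-year pattern for one variable."""
    n_days = n_years * DAYS_PER_YEAR
    days = np.arange(n_days)
    doy = days % DAYS_PER_YEAR
    nl = grid.n_layers
    layers = {k: np.zeros((n_days, nl)) for k in LAYER_DIAGS}
    scalars = {k: np.zeros(n_days) for k in SCALAR_DIAGS}
    layers[var][:] = values_by_doy(doy)[:, None]
    from lakeshift.state import N_VARS

    return RunResult(grid=grid, day_index=days, doy=doy, layers=layers,
                     scalars=scalars, final_state=LakeState(np.zeros((N_VARS, nl))),
                     n_days=n_days)


class TestExtraction:
    def test_constant_diagnostic_summer_mean(self, grid1):
        res = fabricate_result(grid1, lambda d: np.full_like(d, 7.0, dtype=float))
        pt = sc.run_and_extract(res, grid1, b_cov=120.0)
        assert pt.summer_means["chl"] == pytest.approx(7.0)

    def test_winter_only_signal_has_zero_summer_mean(self, grid1):
        res = fabricate_result(
            grid1, lambda d: np.where((d < sc.SUMMER_DOY[0]) | (d > sc.SUMMER_DOY[1]),
                                      5.0, 0.0))
        pt = sc.run_and_extract(res, grid1, b_cov=120.0)
        assert pt.summer_means["chl"] == 0.0

    def test_hand_built_monthly_series_mean(self, grid1):
        """Summer mean equals the hand average of a piecewise-constant
        day-of-year pattern over May 1 - Sep 30."""
        def pattern(doy):
            return np.where(doy < 180, 2.0, 10.0).astype(float)

        res = fabricate_result(grid1, pattern)
        lo, hi = sc.SUMMER_DOY
        n_low = 180 - lo
        n_high = hi - 180 + 1
        expected = (2.0 * n_low + 10.0 * n_high) / (n_low + n_high)
        pt = sc.run_and_extract(res, grid1, b_cov=120.0)
        assert pt.summer_means["chl"] == pytest.approx(expected)

    def test_short_run_rejected(self, grid1):
        res = fabricate_result(grid1, lambda d: d.astype(float), n_years=3)
        res.n_days = 3 * DAYS_PER_YEAR
        with pytest.raises(ValueError):
            sc.run_and_extract(res, grid1, b_cov=120.0)


def make_points(branch, loads, values, var="chl"):
    pts = []
    for ld, v in zip(loads, values):
        means = {k: 0.0 for k in sc.RESPONSE_VARIABLES}
        means[var] = v
        pts.append(sc.LoadResponsePoint(
            load=ld, branch=branch, multiplier=ld / 10.0, summer_means=means,
            lake_coverage=0.0, depth_limit_august=0.0, stability_change=0.0))
    return pts


class TestCurvesAndHysteresis:
    def test_shuffled_points_sorted_by_load(self):
        pts = make_points("turbid", [5.0, 1.0, 3.0], [50, 10, 30])
        curve = sc.load_response(pts)
        chl = curve[curve["variable"] == "chl"]
        assert list(chl["load_mgP_m2_d"]) == [1.0, 3.0, 5.0]
        assert list(chl["value"]) == [10, 30, 50]

    def test_monotone_synthetic_response_preserved(self):
        loads = np.linspace(1, 9, 9)
        pts = make_points("turbid", loads[::-1], (loads ** 2)[::-1])
        curve = sc.load_response(pts)
        chl = curve[curve["variable"] == "chl"]
        assert np.all(np.diff(chl["value"].to_numpy()) > 0)

    def test_identical_curves_no_hysteresis(self):
        loads = [1.0, 2.0, 3.0, 4.0]
        pts = (make_points("turbid", loads, [10, 20, 30, 40])
               + make_points("clear", loads, [10, 20, 30, 40]))
        assert sc.hysteresis_range(sc.load_response(pts)) is None

    def test_constructed_disagreement_interval_detected(self):
        loads = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        turbid = [10, 10, 30, 30, 30, 60]
        clear = [10, 10, 10, 10, 30, 60]  # differ at loads 3-4
        pts = make_points("turbid", loads, turbid) + make_points("clear", loads, clear)
        lo, hi = sc.hysteresis_range(sc.load_response(pts))
        assert (lo, hi) == (3.0, 4.0)

    def test_interval_shrinks_with_tolerance(self):
        loads = np.linspace(1, 10, 10)
        turbid = np.linspace(10, 100, 10)
        clear = turbid * np.array([1, 1, 1.3, 1.5, 2.0, 1.5, 1.3, 1, 1, 1])
        pts = make_points("turbid", loads, turbid) + make_points("clear", loads, clear)
        curve = sc.load_response(pts)
        widths = []
        for tol in (0.2, 0.35, 0.6):
            rng = sc.hysteresis_range(curve, rel_tol=tol)
            widths.append(0.0 if rng is None else rng[1] - rng[0])
        assert widths[0] >= widths[1] >= widths[2]

    def test_mismatched_grids_rejected(self):
        pts = (make_points("turbid", [1.0, 2.0], [1, 2])
               + make_points("clear", [1.0, 3.0], [1, 2]))
        with pytest.raises(ValueError):
            sc.hysteresis_range(sc.load_response(pts))
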