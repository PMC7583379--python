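import numpy as np
import pandas as pd
import pytest

from lakeshift import synthetic as syn
from lakeshift.forcing import build_forcing, partition_inflow_nutrients
from lakeshift.grid import build_grid
from lakeshift.model import LakeModel
from lakeshift.physics import meteo_to_daily


class TestHypsographGenerator:
    def test_defaults_reproduce_morphometry(self, lake_spec, hyps):
        assert hyps.surface_area == pytest.approx(0.91e6)
        assert hyps.max_depth == pytest.approx(2.6)
        assert hyps.volume / hyps.surface_area == pytest.approx(1.2, rel=1e-6)

    def test_area_zero_at_deepest_point(self, hyps):
        assert hyps.areas[0] == 0.0

    def test_infeasible_mean_depth_rejected(self):
        with pytest.raises(ValueError):
            syn.SyntheticLakeSpec(mean_depth=2.6, max_depth=2.6)


class TestMeteorologyGenerator:
    def test_noise_free_seasonal_means_exact(self, lake_spec):
        met = syn.gen_meteorology(lake_spec, 1, seed=0, noise=False)
        df = met.set_index(pd.DatetimeIndex(met["time"]))
        summer = df[df.index.month.isin(syn.SUMMER_MONTHS)]["air_temp"].mean()
        winter = df[df.index.month.isin(syn.WINTER_MONTHS)]["air_temp"].mean()
        assert summer == pytest.approx(14.5, abs=0.02)
        assert winter == pytest.approx(3.7, abs=0.02)

    def test_seeded_ten_year_means_within_tolerance(self, lake_spec):
        met = syn.gen_meteorology(lake_spec, 10, seed=42)
        df = met.set_index(pd.DatetimeIndex(met["time"]))
        summer = df[df.index.month.isin(syn.SUMMER_MONTHS)]["air_temp"].mean()
        winter = df[df.index.month.isin(syn.WINTER_MONTHS)]["air_temp"].mean()
        assert abs(summer - 14.5) < 0.3
        assert abs(winter - 3.7) < 0.3

    def test_different_seeds_different_series_same_climate(self, lake_spec):
        m1 = syn.gen_meteorology(lake_spec, 5, seed=1)
        m2 = syn.gen_meteorology(lake_spec, 5, seed=2)
        assert not np.allclose(m1["air_temp"], m2["air_temp"])
        assert abs(m1["air_temp"].mean() - m2["air_temp"].mean()) < 1.0

    def test_determinism_and_validity(self, lake_spec):
        m1 = syn.gen_meteorology(lake_spec, 2, seed=9)
        m2 = syn.gen_meteorology(lake_spec, 2, seed=9)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1["cloud"].between(0, 1).all()


class TestInflowGenerator:
    def test_organic_partition_exact(self):
        """75% of total P and 90% of total N enter as organic pools."""
        species = partition_inflow_nutrients(np.array([2.0]), np.array([0.2]))
        org_p = species["dom_p"] + species["pom_p"] + species["phy_p"] + species["zoo_p"]
        org_n = species["dom_n"] + species["pom_n"] + species["phy_n"] + species["zoo_n"]
        assert org_p[0] == pytest.approx(0.15)
        assert species["po4"][0] == pytest.approx(0.05)
        assert org_n[0] == pytest.approx(1.8)
        assert (species["nh4"] + species["no3"])[0] == pytest.approx(0.2)

    def test_annual_loads_near_targets(self, lake_spec):
        inflow = syn.gen_inflow(lake_spec, 4, seed=7)
        f = build_forcing(meteo_to_daily(syn.gen_meteorology(lake_spec, 4, seed=7)),
                          inflow)
        p_load = f.areal_p_load(lake_spec.surface_area)  # mg P/m2/d
        annual_p = p_load * 365 * lake_spec.surface_area / 1e9  # Mg P/yr
        assert abs(annual_p - 3.0) / 3.0 < 0.10
        n_load = f.areal_n_load(lake_spec.surface_area)
        annual_n = n_load * 365 * lake_spec.surface_area / 1e9
        assert abs(annual_n - 120.0) / 120.0 < 0.10

    def test_zero_discharge_month_zero_load(self, lake_spec):
        inflow = syn.gen_inflow(lake_spec, 1, seed=3)
        inflow.loc[inflow["time"].dt.month == 6, "discharge_m3s"] = 0.0
        f = build_forcing(meteo_to_daily(syn.gen_meteorology(lake_spec, 1, seed=3)),
                          inflow)
        june = pd.DatetimeIndex(syn.canonical_dates(lake_spec.start_year, 1)).month == 6
        assert np.all(f.discharge[june] == 0.0)
        assert float((f.discharge * f.total_p_conc())[june].sum()) == 0.0

    def test_residence_time_seasonality(self, lake_spec):
        inflow = syn.gen_inflow(lake_spec, 1, seed=5)
        q = inflow.groupby(inflow["time"].dt.month)["discharge_m3s"].sum() * 86400
        res_jan = lake_spec.volume / q[1]
        res_jul = lake_spec.volume / q[7]
        assert res_jan == pytest.approx(16.0, rel=1e-6)
        assert res_jul == pytest.approx(32.0, rel=1e-6)


class TestSamplingSchedule:
    def test_winter_one_summer_two_per_month(self):
        days, stamps = syn.sampling_days(1, 1990)
        months = pd.DatetimeIndex(stamps).month
        counts = pd.Series(1, index=months).groupby(level=0).sum()
        for m in syn.WINTER_MONTHS:
            assert counts[m] == 1
        for m in syn.SUMMER_MONTHS:
            assert counts[m] == 2
        assert len(days) == 7 + 10


@pytest.fixture(scope="module")
def truth_run(lake_spec, params, forcing_2yr, grid1):
    model = LakeModel(grid1, params, dt=1.0)
    return model.run(forcing_2yr, initial="turbid")


class TestObservations:
    def test_sampling_depth_within_band(self, truth_run, lake_spec):
        obs = syn.gen_observations(truth_run, lake_spec, seed=1)
        d = obs.records["sample_depth_m"]
        assert d.between(0.2, 1.0).all()

    def test_noise_magnitude_matches_error_fraction(self, truth_run, lake_spec):
        """Pooled across many noise realizations, the scatter of observed
        over true values matches the declared analytical error fraction."""
        ratios = []
        for seed in range(40):
            obs = syn.gen_observations(truth_run, lake_spec, seed=seed,
                                       variables=["chl"])
            rec = obs.records
            truth = np.array([
                truth_run.depth_pooled("chl", d)[int(t)]
                for d, t in zip(rec["sample_depth_m"], rec["day"])
            ])
            ok = truth > 1.0
            ratios.append(rec["value"].to_numpy()[ok] / truth[ok])
        ratios = np.concatenate(ratios)
        cv = ratios.std() / ratios.mean()
        assert len(ratios) > 500
        assert abs(cv - 0.20) / 0.20 < 0.20

    def test_determinism(self, truth_run, lake_spec):
        o1 = syn.gen_observations(truth_run, lake_spec, seed=4)
        o2 = syn.gen_observations(truth_run, lake_spec, seed=4)
        pd.testing.assert_frame_equal(o1.records, o2.records)


class TestTwinFixture:
    def test_deterministic_and_perturbed(self):
        fx1 = syn.make_twin_fixture(seed=42)
        fx2 = syn.make_twin_fixture(seed=42)
        assert np.array_equal(fx1.truth_run.final_state.x, fx2.truth_run.final_state.x)
        pd.testing.assert_frame_equal(fx1.observations.records,
                                      fx2.observations.records)
        for name in syn.TWIN_PARAMETERS:
            assert fx1.start_params[name] == fx2.start_params[name]
            assert fx1.start_params[name] != fx1.truth_params[name]

    def test_truth_objective_beats_perturbed_start(self):
        """By construction the truth parameters fit the generated
        observations at least as well as the perturbed starting point."""
        from lakeshift.calibration import extract_pairs, log_likelihood

        fx = syn.make_twin_fixture(seed=42)

        def objective(p):
            model = LakeModel(fx.grid, p, dt=fx.dt)
            res = model.run(fx.forcing, initial="turbid", record_start=fx.warmup_days)
            return log_likelihood(extract_pairs(res, fx.observations))

        assert objective(fx.truth_params) > objective(fx.start_params)
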