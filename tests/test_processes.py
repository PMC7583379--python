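import numpy as np
import pytest
from scipy.integrate import quad

from lakeshift import processes
from lakeshift.grid import build_grid
from lakeshift.parameters import default_parameters


@pytest.fixture(scope="module")
def dia_spec(params):
    return params.phyto_specs()[0]


class TestTemperatureFactors:
    def test_abiotic_reference_and_identity(self):
        assert processes.temp_factor_abiotic(20.0, 1.07) == 1.0
        assert processes.temp_factor_abiotic(5.0, 1.0) == 1.0

    def test_abiotic_direct_evaluation(self):
        assert processes.temp_factor_abiotic(30.0, 1.07) == pytest.approx(1.07 ** 10)

    def test_abiotic_rejects_nonpositive_theta(self):
        with pytest.raises(ValueError):
            processes.temp_factor_abiotic(10.0, 0.0)

    def test_biotic_optimum_and_symmetry(self):
        assert processes.temp_factor_biotic(18.0, 18.0, 5.0) == 1.0
        lo = processes.temp_factor_biotic(13.0, 18.0, 5.0)
        hi = processes.temp_factor_biotic(23.0, 18.0, 5.0)
        assert lo == pytest.approx(np.exp(-0.5))
        assert lo == pytest.approx(hi)

    def test_biotic_integral_matches_gaussian_closed_form(self):
        t_opt, sig = 15.0, 6.0
        val, _ = quad(lambda t: processes.temp_factor_biotic(t, t_opt, sig), -200, 200)
        assert val == pytest.approx(np.sqrt(2 * np.pi) * sig, rel=1e-8)


class TestDroop:
    def test_growth_zero_at_subsistence_quota(self, dia_spec):
        dm = 5.0
        out = processes.droop_growth(dm, dm * dia_spec.q_min_n, dm * dia_spec.q_max_p,
                                     1.0, 1.0, dia_spec)
        assert out == 0.0

    def test_replete_limit(self, dia_spec):
        dm = 2.0
        out = processes.droop_growth(dm, dm * dia_spec.q_max_n, dm * dia_spec.q_max_p,
                                     1.0, 1.0, dia_spec)
        expected = dia_spec.mu_max * min(1 - dia_spec.q_min_n / dia_spec.q_max_n,
                                         1 - dia_spec.q_min_p / dia_spec.q_max_p) * dm
        assert out == pytest.approx(expected)

    def test_min_law_equals_elementwise_brute_force(self, dia_spec):
        rng = np.random.default_rng(0)
        for _ in range(50):
            dm = rng.uniform(0.1, 20)
            qn = rng.uniform(dia_spec.q_min_n, dia_spec.q_max_n)
            qp = rng.uniform(dia_spec.q_min_p, dia_spec.q_max_p)
            out = processes.droop_growth(dm, dm * qn, dm * qp, 1.0, 1.0, dia_spec)
            brute = dia_spec.mu_max * dm * min(1 - dia_spec.q_min_n / qn,
                                               1 - dia_spec.q_min_p / qp)
            assert out == pytest.approx(brute)

    def test_growth_non_decreasing_in_quota(self, dia_spec):
        dm = 3.0
        qs = np.linspace(dia_spec.q_min_n, dia_spec.q_max_n, 40)
        growth = [processes.droop_growth(dm, dm * q, dm * dia_spec.q_max_p,
                                         1.0, 1.0, dia_spec) for q in qs]
        assert np.all(np.diff(growth) >= -1e-12)


class TestUptake:
    def test_zero_at_full_stores(self, dia_spec):
        dm = 4.0
        u = processes.nutrient_uptake(dm, dm * dia_spec.q_max_n, dm * dia_spec.q_max_p,
                                      1.0, 1.0, 1.0, dia_spec)
        assert all(x == pytest.approx(0.0, abs=1e-14) for x in u)

    def test_saturation_limit(self, dia_spec):
        dm = 4.0
        u_nh4, u_no3, u_po4 = processes.nutrient_uptake(
            dm, dm * dia_spec.q_min_n, dm * dia_spec.q_min_p, 1e9, 0.0, 1e9, dia_spec)
        assert u_nh4 + u_no3 == pytest.approx(dia_spec.v_max_n * dm, rel=1e-6)
        assert u_po4 == pytest.approx(dia_spec.v_max_p * dm, rel=1e-6)

    def test_half_saturation_at_subsistence(self, dia_spec):
        dm = 1.0
        _, _, u_po4 = processes.nutrient_uptake(
            dm, dm * dia_spec.q_min_n, dm * dia_spec.q_min_p,
            0.0, 0.0, dia_spec.k_p, dia_spec)
        assert u_po4 == pytest.approx(dia_spec.v_max_p * dm / 2)

    def test_negative_concentration_rejected(self, dia_spec):
        with pytest.raises(ValueError):
            processes.nutrient_uptake(1.0, 0.03, 0.003, -0.1, 0.0, 0.0, dia_spec)


class TestChla:
    def test_ratio_limits_and_zero_biomass(self, params):
        specs = params.phyto_specs()
        dms = [2.0, 1.0, 0.5]
        total_sat, per = processes.chla(dms, [1.0, 1.0, 1.0], specs)
        assert total_sat == pytest.approx(sum(d * s.chl_dm_min
                                              for d, s in zip(dms, specs)))
        total_lim, _ = processes.chla(dms, [0.0, 0.0, 0.0], specs)
        assert total_lim == pytest.approx(sum(d * s.chl_dm_max
                                              for d, s in zip(dms, specs)))
        total_zero, _ = processes.chla([0.0, 0.0, 0.0], [0.5] * 3, specs)
        assert total_zero == 0.0


class TestGrazing:
    def test_no_food_no_flux(self):
        out = processes.zoo_grazing([0.0, 0.0], [1.0, 0.5], 2.0, 1.0, 0.4, 0.8)
        assert all(g == 0.0 for g in out)

    def test_total_intake_saturates(self):
        """Hyperbolic filtration: total intake approaches F_max*f_T*h_food
        per unit grazer as food becomes abundant."""
        f_max, h = 0.4, 0.8
        big = processes.zoo_grazing([1e7], [1.0], 1.0, 1.0, f_max, h)
        assert sum(big) == pytest.approx(f_max * h, rel=1e-5)

    def test_preference_ranking_orders_flux_shares(self, params):
        """At equal concentrations the grazing flux follows the preference
        ranking: diatoms >= other algae >= cyanobacteria >= POM."""
        prefs = [params["zoo_pref_dia"], params["zoo_pref_oth"],
                 params["zoo_pref_cya"], params["zoo_pref_pom"]]
        fluxes = processes.zoo_grazing([5.0] * 4, prefs, 1.0, 1.0,
                                       params["zoo_f_max"], params["zoo_h_food"])
        assert fluxes[0] >= fluxes[1] >= fluxes[2] >= fluxes[3]


class TestMacrophytes:
    KW = dict(p_max=0.35, c_prod=0.014, resp=0.03, c_resp=0.074,
              h_light=10.0, b_max=400.0)

    def test_no_spontaneous_generation(self):
        assert processes.macrophyte_net_growth(15.0, 50.0, 0.0, **self.KW) == 0.0

    def test_dark_respiration_negative(self):
        assert processes.macrophyte_net_growth(15.0, 0.0, 10.0, **self.KW) < 0

    def test_interior_temperature_optimum(self):
        """With the respiration exponent above the production exponent the
        net rate peaks at a finite interior temperature that matches the
        analytic stationary point."""
        b, par = 10.0, 200.0
        ts = np.arange(-5.0, 45.0, 0.1)
        net = processes.macrophyte_net_growth(ts, par, b, **self.KW)
        t_star = ts[np.argmax(net)]
        # d/dT [p_eff e^{cp(T-20)} - r e^{cr(T-20)}] = 0
        p_eff = self.KW["p_max"] * par / (par + self.KW["h_light"]) * (1 - b / 400.0)
        cp, cr = self.KW["c_prod"], self.KW["c_resp"]
        t_analytic = 20.0 + np.log(p_eff * cp / (self.KW["resp"] * cr)) / (cr - cp)
        assert 0 < t_star < 44.0
        assert t_star == pytest.approx(t_analytic, abs=0.11)

    def test_piscivory_factor_monotone(self):
        covs = np.linspace(0, 100, 30)
        f = processes.piscivory_coverage_factor(covs, 0.1, 15.0)
        assert np.all(np.diff(f) > 0)
        assert f[0] == pytest.approx(0.1)
        with pytest.raises(ValueError):
            processes.piscivory_coverage_factor(120.0, 0.1, 15.0)


class TestCoverage:
    def test_zero_biomass(self, grid16):
        cov, lake, dlim = processes.coverage_and_depth_limit(
            np.zeros(16), grid16, b_cov=120.0)
        assert lake == 0.0 and dlim == 0.0

    def test_single_shallow_layer_weighting(self, grid16):
        b = np.zeros(16)
        b[-1] = 500.0  # top (shallowest) layer only
        cov, lake, dlim = processes.coverage_and_depth_limit(b, grid16, b_cov=120.0)
        share = grid16.benthic_areas[-1] / grid16.benthic_areas.sum()
        assert lake == pytest.approx(cov[-1] * share)
        assert dlim == pytest.approx(grid16.center_depths[-1])

    def test_uniform_biomass_reaches_max_depth(self, grid16):
        cov, lake, dlim = processes.coverage_and_depth_limit(
            np.full(16, 50.0), grid16, b_cov=120.0, threshold=0.1)
        assert dlim == pytest.approx(grid16.center_depths[0])
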