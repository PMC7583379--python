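"""The lake model kernel: process assembly, time stepping, diagnostics.

One :class:`LakeModel` couples the physical environment (temperature,
light, mixing, shear) to the biogeochemical/food-web process network on a
vertical grid.  Within each step the order of operations is: physics
(temperature, light) -> biological/chemical rates assembled as a
production-destruction flux network -> positivity-preserving conservative
update (modified Patankar) -> transport (settling with benthic deposition,
vertical mixing, inflow/outflow through the surface layer) -> calendar
events and diagnostics.

Nitrogen and phosphorus are fully closed: every internal transfer has an
explicit destination pool (denitrified N2 and buried matter are per-layer
ledger pools), and the only true boundary fluxes are inflow and outflow,
accumulated in the state's boundary ledger so the budget is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from scipy.linalg import solve_banded

from lakeshift import physics, processes
from lakeshift.forcing import ForcingBundle
from lakeshift.grid import VerticalGrid
from lakeshift.parameters import ParameterSet
from lakeshift.patankar import emp_step_batched
from lakeshift.state import (
    MOBILE_VARS, N_CONTENT, N_VARS, P_CONTENT, LakeState, V, conversion_matrix,
)

__all__ = ["LakeModel", "RunResult"]

#: diagnostics recorded per layer, daily
LAYER_DIAGS = [
    "temp", "chl", "chl_dia", "chl_cya", "chl_oth", "tn", "tp", "po4", "no3",
    "nh4", "o2", "pom_dm", "im", "zoo_dm", "dia_dm", "cya_dm", "oth_dm",
    "juv_dm", "adu_dm", "pis_dm", "zb_dm", "mac_dm", "coverage", "kd",
]
SCALAR_DIAGS = ["lake_coverage", "depth_limit", "p_load", "total_n", "total_p",
                "inflow_n", "inflow_p", "outflow_n", "outflow_p"]

_WATER_N = [V.NH4, V.NO3, V.DOM_N, V.POM_N, V.DIA_N, V.CYA_N, V.OTH_N, V.ZOO_N]
_WATER_P = [V.PO4, V.DOM_P, V.POM_P, V.DIA_P, V.CYA_P, V.OTH_P, V.ZOO_P]


@dataclass
class RunResult:
    """Daily diagnostics of a simulation window plus the final state."""

    grid: VerticalGrid
    day_index: np.ndarray               # simulation day of each record
    doy: np.ndarray                     # 0-based day of year
    layers: dict                        # name -> (n_rec, L)
    scalars: dict                       # name -> (n_rec,)
    final_state: LakeState
    n_days: int

    def column_mean(self, name: str) -> np.ndarray:
        """Volume-weighted whole-column mean of a per-layer diagnostic."""
        w = self.grid.volumes / self.grid.volume
        return self.layers[name] @ w

    def depth_pooled(self, name: str, sample_depth: float) -> np.ndarray:
        """Volume-weighted mean over layers within ``sample_depth`` of the surface.

        Emulates depth-pooled sampling from the surface down to the given
        depth: each layer contributes the volume of its overlap with the
        sampled slab.
        """
        g = self.grid
        z_cut = max(g.max_depth - sample_depth, 0.0)
        top = g.interfaces[1:]
        bot = g.interfaces[:-1]
        overlap = np.clip((top - np.maximum(bot, z_cut)) / (top - bot), 0.0, 1.0)
        w = g.volumes * overlap
        if w.sum() <= 0:
            w = g.volumes * 0 + 1e-12
            w[-1] = 1.0
        return self.layers[name] @ (w / w.sum())

    def to_frame(self):
        """Tidy (time, layer, variable, value) DataFrame of layer diagnostics."""
        import pandas as pd

        n_rec, nl = next(iter(self.layers.values())).shape
        frames = []
        for name, arr in self.layers.items():
            frames.append(pd.DataFrame({
                "day": np.repeat(self.day_index, nl),
                "layer": np.tile(np.arange(nl), n_rec),
                "variable": name,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


class LakeModel:
    """A parameterized lake on a vertical grid, ready to run."""

    def __init__(self, grid: VerticalGrid, params: ParameterSet, *, dt: float = 0.25):
        if dt <= 0 or dt > 1.0:
            raise ValueError("dt must be in (0, 1] days")
        if round(1.0 / dt) != 1.0 / dt:
            raise ValueError("dt must divide one day evenly")
        self.grid = grid
        self.params = params
        self.dt = dt
        self.p = params.flat()
        self.specs = params.phyto_specs()
        self.conv = conversion_matrix(grid, sediment_depth=self.p.sed_depth,
                                      porosity=self.p.sed_porosity)
        L = grid.n_layers
        self._F = np.zeros((L, N_VARS, N_VARS))
        self._src = np.zeros((L, N_VARS))
        self._bnd = np.zeros((L, N_VARS))
        self._vol = grid.volumes
        self._ben = grid.benthic_areas
        self._atop = grid.interface_areas[1:]
        self._pwvol = self._ben * self.p.sed_depth * self.p.sed_porosity
        self._depths = grid.center_depths
        # settling: per-variable velocities and sediment destinations
        p = self.p
        self._settle_vars = np.array([
            V.POM_DM, V.POM_N, V.POM_P, V.IM,
            V.DIA_DM, V.DIA_N, V.DIA_P,
            V.CYA_DM, V.CYA_N, V.CYA_P,
            V.OTH_DM, V.OTH_N, V.OTH_P,
        ])
        self._settle_vel = np.array(
            [p.pom_settling] * 3 + [p.im_settling] + [p.dia_settling] * 3
            + [p.cya_settling] * 3 + [p.oth_settling] * 3)[:, None]
        self._settle_dst = np.array([
            V.SPOM_DM, V.SPOM_N, V.SPOM_P, V.SIM,
            V.SPOM_DM, V.SPOM_N, V.SPOM_P,
            V.SPOM_DM, V.SPOM_N, V.SPOM_P,
            V.SPOM_DM, V.SPOM_N, V.SPOM_P,
        ])
        # packed phytoplankton trait arrays, shape (3, 1), for the vectorized
        # inner loop (groups x layers)
        self._phy_dm_idx = np.array([V.DIA_DM, V.CYA_DM, V.OTH_DM])
        self._phy_n_idx = self._phy_dm_idx + 1
        self._phy_p_idx = self._phy_dm_idx + 2
        s = self.specs

        def pk(attr):
            return np.array([[getattr(sp, attr)] for sp in s])

        self._phy = SimpleNamespace(
            mu_max=pk("mu_max"), t_opt=pk("t_opt"), t_sigma=pk("t_sigma"),
            q_min_n=pk("q_min_n"), q_max_n=pk("q_max_n"),
            q_min_p=pk("q_min_p"), q_max_p=pk("q_max_p"),
            v_max_n=pk("v_max_n"), v_max_p=pk("v_max_p"),
            k_n=pk("k_n"), k_p=pk("k_p"), h_light=pk("h_light"),
            resp=pk("resp"), mort=pk("mort"),
            chl_min=pk("chl_dm_min"), chl_max=pk("chl_dm_max"))

    # ------------------------------------------------------------------
    # initial conditions
    # ------------------------------------------------------------------
    def initial_state(self, mode: str = "turbid") -> LakeState:
        """A plausible starting state for a eutrophic shallow lake.

        ``turbid``: phytoplankton-dominated, macrophytes reduced to a
        propagule-bank seed.  ``clear``: macrophyte-dominated with low
        algal biomass.  Sediment pools reflect a loading history in both.
        """
        if mode not in ("turbid", "clear"):
            raise ValueError("mode must be 'turbid' or 'clear'")
        L = self.grid.n_layers
        x = np.zeros((N_VARS, L))
        x[V.NH4] = 0.1
        x[V.NO3] = 2.0
        x[V.DOM_N] = 0.3
        x[V.DOM_P] = 0.02
        x[V.POM_DM] = 5.0
        x[V.POM_N] = 0.2
        x[V.POM_P] = 0.02
        x[V.IM] = 5.0
        x[V.O2] = 10.0
        qn, qp = 0.03, 0.003  # mid-range quotas
        if mode == "turbid":
            x[V.PO4] = 0.05
            phyto = {"dia": 4.0, "cya": 2.0, "oth": 2.0}
            x[V.ZOO_DM] = 0.3
            mac = 0.05
        else:
            x[V.PO4] = 0.01
            phyto = {"dia": 0.5, "cya": 0.1, "oth": 0.3}
            x[V.ZOO_DM] = 1.0
            mac = 60.0
        for g, idm in [("dia", V.DIA_DM), ("cya", V.CYA_DM), ("oth", V.OTH_DM)]:
            x[idm] = phyto[g]
            x[idm + 1] = phyto[g] * qn
            x[idm + 2] = phyto[g] * qp
        x[V.ZOO_N] = x[V.ZOO_DM] * 0.07
        x[V.ZOO_P] = x[V.ZOO_DM] * 0.007
        for idm, dm in [(V.JUV_DM, 2.0), (V.ADU_DM, 3.0), (V.PIS_DM, 0.2)]:
            x[idm] = dm
            x[idm + 1] = dm * 0.09
            x[idm + 2] = dm * 0.015
        x[V.SPOM_DM] = 1500.0
        x[V.SPOM_N] = 45.0
        x[V.SPOM_P] = 2.0
        x[V.HUM_DM] = 6000.0
        x[V.HUM_N] = 120.0
        x[V.HUM_P] = 8.0
        x[V.SIM] = 5000.0
        x[V.PAIMS] = 5.0
        x[V.PNH4] = 2.0
        x[V.PNO3] = 0.3
        x[V.PPO4] = 0.5
        x[V.ZB_DM] = 5.0
        x[V.ZB_N] = 0.35
        x[V.ZB_P] = 0.035
        x[V.MAC_DM] = mac
        x[V.MAC_N] = mac * self.p.mac_q_n
        x[V.MAC_P] = mac * self.p.mac_q_p
        return LakeState(x)

    # ------------------------------------------------------------------
    # rate assembly
    # ------------------------------------------------------------------
    def _assemble(self, x: np.ndarray, temps: np.ndarray, par_mean: np.ndarray,
                  par_bot: np.ndarray, f_light: list, wind: float):
        """Fill the flux matrix, sources, and boundary sinks (mass g/d)."""
        p = self.p
        vol, ben, pwv = self._vol, self._ben, self._pwvol
        F, src, bnd = self._F, self._src, self._bnd
        F[:] = 0.0
        src[:] = 0.0
        bnd[:] = 0.0
        T = temps

        f_min = p.theta_min ** (T - 20.0)
        f_nit = p.theta_nit ** (T - 20.0)
        f_dif = p.theta_dif ** (T - 20.0)
        o2 = x[V.O2]
        o2_sink_dm = np.zeros_like(o2)     # DM-equivalents mineralized, conc g/m3/d
        o2_sink_dm_areal = np.zeros_like(o2)  # sediment DM mineralized, g/m2/d

        # --- phytoplankton (vectorized over the three groups) ---
        ph = self._phy
        dm3 = x[self._phy_dm_idx]    # (3, L)
        nst3 = x[self._phy_n_idx]
        pst3 = x[self._phy_p_idx]
        dm_safe = np.maximum(dm3, 1e-12)
        q_n = np.clip(nst3 / dm_safe, ph.q_min_n, ph.q_max_n)
        q_p = np.clip(pst3 / dm_safe, ph.q_min_p, ph.q_max_p)
        zt = (T - ph.t_opt) / ph.t_sigma
        f_t3 = np.exp(-0.5 * zt * zt)
        lim = np.maximum(np.minimum(1.0 - ph.q_min_n / q_n, 1.0 - ph.q_min_p / q_p), 0.0)
        growth3 = ph.mu_max * f_t3 * f_light * lim * dm3       # gDM/m3/d
        src[:, self._phy_dm_idx] += (growth3 * vol).T
        growth_tot = growth3.sum(axis=0)
        # quota-regulated Michaelis-Menten uptake; NH4 preferred over NO3
        din = x[V.NH4] + x[V.NO3]
        v_n = (ph.v_max_n * (ph.q_max_n - q_n) / (ph.q_max_n - ph.q_min_n)
               * din / (din + ph.k_n) * dm3)
        w = p.nh4_pref * x[V.NH4]
        frac_nh4 = w / np.maximum(w + x[V.NO3], 1e-30)
        v_p = (ph.v_max_p * (ph.q_max_p - q_p) / (ph.q_max_p - ph.q_min_p)
               * x[V.PO4] / (x[V.PO4] + ph.k_p) * dm3)
        F[:, V.NH4, self._phy_n_idx] += (v_n * frac_nh4 * vol).T
        F[:, V.NO3, self._phy_n_idx] += (v_n * (1.0 - frac_nh4) * vol).T
        F[:, V.PO4, self._phy_p_idx] += (v_p * vol).T
        r3 = ph.resp * f_min
        bnd[:, self._phy_dm_idx] += (r3 * dm3 * vol).T
        o2_sink_dm += (r3 * dm3).sum(axis=0)
        F[:, self._phy_n_idx, V.NH4] += (r3 * nst3 * vol).T
        F[:, self._phy_p_idx, V.PO4] += (r3 * pst3 * vol).T
        F[:, self._phy_dm_idx, V.POM_DM] += (ph.mort * dm3 * vol).T
        F[:, self._phy_n_idx, V.POM_N] += (ph.mort * nst3 * vol).T
        F[:, self._phy_p_idx, V.POM_P] += (ph.mort * pst3 * vol).T

        # --- zooplankton ---
        zoo = x[V.ZOO_DM]
        ztz = (T - p.zoo_t_opt) / p.zoo_t_sigma
        f_tz = np.exp(-0.5 * ztz * ztz)
        foods = [x[V.DIA_DM], x[V.OTH_DM], x[V.CYA_DM], x[V.POM_DM]]
        prefs = [p.zoo_pref_dia, p.zoo_pref_oth, p.zoo_pref_cya, p.zoo_pref_pom]
        eff_food = sum(pr * c for pr, c in zip(prefs, foods))
        filt = p.zoo_f_max * f_tz / (1.0 + eff_food / p.zoo_h_food)
        graz = [filt * pr * c * zoo for pr, c in zip(prefs, foods)]
        ez = p.zoo_assim
        food_idx = [V.DIA_DM, V.OTH_DM, V.CYA_DM, V.POM_DM]
        for g, idm in zip(graz, food_idx):
            i_n, i_p = idm + 1, idm + 2
            dm = x[idm]
            safe = np.maximum(dm, 1e-30)
            q_n = x[i_n] / safe
            q_p = x[i_p] / safe
            gv = g * vol
            if idm == V.POM_DM:
                F[:, V.POM_DM, V.ZOO_DM] += ez * gv
                F[:, V.POM_N, V.ZOO_N] += ez * gv * q_n
                F[:, V.POM_P, V.ZOO_P] += ez * gv * q_p
            else:
                F[:, idm, V.ZOO_DM] += ez * gv
                F[:, idm, V.POM_DM] += (1 - ez) * gv
                F[:, i_n, V.ZOO_N] += ez * gv * q_n
                F[:, i_n, V.POM_N] += (1 - ez) * gv * q_n
                F[:, i_p, V.ZOO_P] += ez * gv * q_p
                F[:, i_p, V.POM_P] += (1 - ez) * gv * q_p
        rz = p.zoo_resp * f_min
        bnd[:, V.ZOO_DM] += rz * zoo * vol
        o2_sink_dm += rz * zoo
        F[:, V.ZOO_N, V.NH4] += rz * x[V.ZOO_N] * vol
        F[:, V.ZOO_P, V.PO4] += rz * x[V.ZOO_P] * vol
        m_zoo = p.zoo_mort + p.zoo_mort2 * zoo  # linear + closure mortality
        F[:, V.ZOO_DM, V.POM_DM] += m_zoo * zoo * vol
        F[:, V.ZOO_N, V.POM_N] += m_zoo * x[V.ZOO_N] * vol
        F[:, V.ZOO_P, V.POM_P] += m_zoo * x[V.ZOO_P] * vol

        # --- macrophyte coverage (needed by fish and resuspension) ---
        cov = 100.0 * (1.0 - np.exp(-x[V.MAC_DM] / p.mac_b_cov))

        # --- fish (layer-bound) ---
        ztf = (T - p.fish_t_opt) / p.fish_t_sigma
        f_tf = np.exp(-0.5 * ztf * ztf)
        ef = p.fish_assim

        def _predate(prey_idm, prey_conc, intake, pred_idm, egest_dm, egest_n, egest_p):
            """Holling-II predation flux with egestion routing."""
            i_n, i_p = prey_idm + 1, prey_idm + 2
            safe = np.maximum(prey_conc, 1e-30)
            q_n = x[i_n] / safe
            q_p = x[i_p] / safe
            F[:, prey_idm, pred_idm] += ef * intake
            F[:, prey_idm, egest_dm] += (1 - ef) * intake
            F[:, i_n, pred_idm + 1] += ef * intake * q_n
            F[:, i_n, egest_n] += (1 - ef) * intake * q_n
            F[:, i_p, pred_idm + 2] += ef * intake * q_p
            F[:, i_p, egest_p] += (1 - ef) * intake * q_p

        juv = x[V.JUV_DM]
        i_juv = p.juv_uptake * f_tf * zoo / (zoo + p.juv_h_food) * juv * vol
        _predate(V.ZOO_DM, zoo, i_juv, V.JUV_DM, V.POM_DM, V.POM_N, V.POM_P)

        adu = x[V.ADU_DM]
        zb = x[V.ZB_DM]
        i_adu = p.adu_uptake * f_tf * zb / (zb + p.adu_h_food) * adu * vol
        _predate(V.ZB_DM, zb, i_adu, V.ADU_DM, V.POM_DM, V.POM_N, V.POM_P)

        pis = x[V.PIS_DM]
        prey = juv + adu
        f_cov = p.cCovVegMin + (1.0 - p.cCovVegMin) * cov / (cov + p.hDVegPisc)
        i_pis = p.pis_uptake * f_tf * f_cov * prey / (prey + p.pis_h_food) * pis * vol
        w_juv = juv / np.maximum(prey, 1e-30)
        _predate(V.JUV_DM, juv, i_pis * w_juv, V.PIS_DM, V.POM_DM, V.POM_N, V.POM_P)
        _predate(V.ADU_DM, adu, i_pis * (1 - w_juv), V.PIS_DM, V.POM_DM, V.POM_N, V.POM_P)

        for idm in (V.JUV_DM, V.ADU_DM, V.PIS_DM):
            i_n, i_p = idm + 1, idm + 2
            rf = p.fish_resp * f_min
            bnd[:, idm] += rf * x[idm] * vol
            o2_sink_dm += rf * x[idm]
            F[:, i_n, V.NH4] += rf * x[i_n] * vol
            F[:, i_p, V.PO4] += rf * x[i_p] * vol
            F[:, idm, V.POM_DM] += p.fish_mort * x[idm] * vol
            F[:, i_n, V.POM_N] += p.fish_mort * x[i_n] * vol
            F[:, i_p, V.POM_P] += p.fish_mort * x[i_p] * vol

        # --- water-column chemistry ---
        hyd = p.k_hyd_pom * f_min
        F[:, V.POM_N, V.DOM_N] += hyd * x[V.POM_N] * vol
        F[:, V.POM_P, V.DOM_P] += hyd * x[V.POM_P] * vol
        bnd[:, V.POM_DM] += hyd * x[V.POM_DM] * vol
        o2_sink_dm += hyd * x[V.POM_DM]
        dom_min = p.k_min_dom * f_min
        F[:, V.DOM_N, V.NH4] += dom_min * x[V.DOM_N] * vol
        F[:, V.DOM_P, V.PO4] += dom_min * x[V.DOM_P] * vol
        nit = p.k_nit * f_nit * o2 / (o2 + p.h_o2_nit) * x[V.NH4]
        F[:, V.NH4, V.NO3] += nit * vol
        den = p.k_den_wat * f_min * p.h_o2_den / (o2 + p.h_o2_den) * x[V.NO3]
        F[:, V.NO3, V.DENIT_N] += den * vol

        # --- sediment ---
        smin = p.k_min_sed * f_min
        F[:, V.SPOM_N, V.PNH4] += smin * x[V.SPOM_N] * ben
        F[:, V.SPOM_P, V.PPO4] += smin * x[V.SPOM_P] * ben
        bnd[:, V.SPOM_DM] += smin * x[V.SPOM_DM] * ben
        o2_sink_dm_areal += smin * x[V.SPOM_DM]
        F[:, V.SPOM_DM, V.HUM_DM] += p.k_humif * x[V.SPOM_DM] * ben
        F[:, V.SPOM_N, V.HUM_N] += p.k_humif * x[V.SPOM_N] * ben
        F[:, V.SPOM_P, V.HUM_P] += p.k_humif * x[V.SPOM_P] * ben
        hmin = p.k_min_hum * f_min
        F[:, V.HUM_N, V.PNH4] += hmin * x[V.HUM_N] * ben
        F[:, V.HUM_P, V.PPO4] += hmin * x[V.HUM_P] * ben
        bnd[:, V.HUM_DM] += hmin * x[V.HUM_DM] * ben
        o2_sink_dm_areal += hmin * x[V.HUM_DM]
        snit = p.k_nit_sed * f_nit * o2 / (o2 + p.h_o2_nit) * x[V.PNH4]
        F[:, V.PNH4, V.PNO3] += snit * pwv
        sden = p.k_den_sed * f_min * x[V.PNO3]
        F[:, V.PNO3, V.DENIT_N] += sden * pwv
        for i_src, i_dst in [(V.HUM_DM, V.BUR_DM), (V.HUM_N, V.BUR_N),
                             (V.HUM_P, V.BUR_P), (V.SIM, V.BUR_DM)]:
            F[:, i_src, i_dst] += p.k_bur * x[i_src] * ben

        # porewater <-> water diffusion
        kd = p.k_diff * f_dif
        for i_w, i_pw in [(V.NH4, V.PNH4), (V.NO3, V.PNO3), (V.PO4, V.PPO4)]:
            grad = kd * (x[i_pw] - x[i_w]) * ben  # g/d, positive = to water
            F[:, i_pw, i_w] += np.maximum(grad, 0.0)
            F[:, i_w, i_pw] += np.maximum(-grad, 0.0)

        # phosphate sorption to iron-bearing inorganic matter
        f_ox = o2 / (o2 + p.h_o2_sorb)
        paims_eq = (p.q_sorb_max * x[V.SIM] * x[V.PPO4] / (x[V.PPO4] + p.h_sorb) * f_ox)
        d_sorb = p.k_sorp * (paims_eq - x[V.PAIMS]) * ben
        F[:, V.PPO4, V.PAIMS] += np.maximum(d_sorb, 0.0)
        F[:, V.PAIMS, V.PPO4] += np.maximum(-d_sorb, 0.0)

        # resuspension (damped by macrophyte cover)
        tau = physics.bottom_shear(wind, p.fetch, self._depths,
                                   c_tau=p.c_tau, depth_scale=p.shear_depth_scale)
        excess = np.maximum(tau - p.tau_crit, 0.0)
        protect = 1.0 - p.mac_protect * cov / 100.0
        r_res = p.k_resus * excess * protect
        F[:, V.SPOM_DM, V.POM_DM] += r_res * x[V.SPOM_DM] * ben
        F[:, V.SPOM_N, V.POM_N] += r_res * x[V.SPOM_N] * ben
        F[:, V.SPOM_P, V.POM_P] += r_res * x[V.SPOM_P] * ben
        F[:, V.SIM, V.IM] += r_res * x[V.SIM] * ben

        # --- zoobenthos ---
        zzb = (T - p.zb_t_opt) / p.zb_t_sigma
        f_tzb = np.exp(-0.5 * zzb * zzb)
        spom = x[V.SPOM_DM]
        i_zb = p.zb_uptake * f_tzb * spom / (spom + p.zb_h_food) * zb * ben
        safe = np.maximum(spom, 1e-30)
        qn_s = x[V.SPOM_N] / safe
        qp_s = x[V.SPOM_P] / safe
        ezb = p.zb_assim
        F[:, V.SPOM_DM, V.ZB_DM] += ezb * i_zb
        F[:, V.SPOM_N, V.ZB_N] += ezb * i_zb * qn_s
        F[:, V.SPOM_P, V.ZB_P] += ezb * i_zb * qp_s
        rzb = p.zb_resp * f_min
        bnd[:, V.ZB_DM] += rzb * zb * ben
        o2_sink_dm_areal += rzb * zb
        F[:, V.ZB_N, V.PNH4] += rzb * x[V.ZB_N] * ben
        F[:, V.ZB_P, V.PPO4] += rzb * x[V.ZB_P] * ben
        m_zb = p.zb_mort + p.zb_mort2 * zb
        F[:, V.ZB_DM, V.SPOM_DM] += m_zb * zb * ben
        F[:, V.ZB_N, V.SPOM_N] += m_zb * x[V.ZB_N] * ben
        F[:, V.ZB_P, V.SPOM_P] += m_zb * x[V.ZB_P] * ben

        # --- macrophytes (root + shoot nutrient uptake) ---
        mac = x[V.MAC_DM]
        fs = p.mac_f_shoot
        pw_n = x[V.PNH4] + x[V.PNO3]
        wc_n = x[V.NH4] + x[V.NO3]
        avail_n = fs * wc_n + (1.0 - fs) * pw_n
        avail_p = fs * x[V.PO4] + (1.0 - fs) * x[V.PPO4]
        f_n = avail_n / (avail_n + p.mac_h_n)
        f_p = avail_p / (avail_p + p.mac_h_p)
        f_nut = np.minimum(f_n, f_p)
        gross = (p.mac_p_max * np.exp(p.mac_c_prod * (T - 20.0))
                 * par_bot / (par_bot + p.mac_h_light)
                 * np.maximum(1.0 - mac / p.mac_b_max, 0.0) * f_nut * mac)
        loss_rate = p.mac_resp * np.exp(p.mac_c_resp * (T - 20.0))
        src[:, V.MAC_DM] += gross * ben
        bnd[:, V.MAC_DM] += loss_rate * mac * ben
        o2_sink_dm_areal += loss_rate * mac
        F[:, V.MAC_N, V.PNH4] += loss_rate * x[V.MAC_N] * ben
        F[:, V.MAC_P, V.PPO4] += loss_rate * x[V.MAC_P] * ben
        upt_n = gross * p.mac_q_n * ben
        upt_p = gross * p.mac_q_p * ben
        w_nh4_pw = x[V.PNH4] / np.maximum(pw_n, 1e-30)
        w_nh4_wc = x[V.NH4] / np.maximum(wc_n, 1e-30)
        F[:, V.PNH4, V.MAC_N] += (1.0 - fs) * upt_n * w_nh4_pw
        F[:, V.PNO3, V.MAC_N] += (1.0 - fs) * upt_n * (1.0 - w_nh4_pw)
        F[:, V.NH4, V.MAC_N] += fs * upt_n * w_nh4_wc
        F[:, V.NO3, V.MAC_N] += fs * upt_n * (1.0 - w_nh4_wc)
        F[:, V.PPO4, V.MAC_P] += (1.0 - fs) * upt_p
        F[:, V.PO4, V.MAC_P] += fs * upt_p
        # loss slows in cold water (overwintering root/turion stock)
        m_mac = p.mac_mort * np.exp(p.mac_c_prod * (T - 20.0))
        F[:, V.MAC_DM, V.SPOM_DM] += m_mac * mac * ben
        F[:, V.MAC_N, V.SPOM_N] += m_mac * x[V.MAC_N] * ben
        F[:, V.MAC_P, V.SPOM_P] += m_mac * x[V.MAC_P] * ben

        # --- oxygen ---
        src[:, V.O2] += p.y_o2_dm * (growth_tot * vol + gross * ben)
        bnd[:, V.O2] += p.y_o2_dm * (o2_sink_dm * vol + o2_sink_dm_areal * ben)
        bnd[:, V.O2] += p.y_o2_nit * (nit * vol + snit * pwv)
        rea = physics.reaeration_flux(o2[-1], T[-1], wind, k0=p.rea_k0,
                                      kw=p.rea_kw, theta=p.theta_rea)
        rea_mass = rea * self.grid.surface_area
        if rea_mass >= 0:
            src[-1, V.O2] += rea_mass
        else:
            bnd[-1, V.O2] += -rea_mass
        return F, src, bnd

    # ------------------------------------------------------------------
    # transport
    # ------------------------------------------------------------------
    def _settle(self, x: np.ndarray) -> None:
        """Implicit upwind settling with benthic deposition, in place."""
        dt = self.dt
        vol, atop, ben = self._vol, self._atop, self._ben
        safe_ben = np.where(ben > 0, ben, 1.0)
        L = self.grid.n_layers
        idx, vel, dst = self._settle_vars, self._settle_vel, self._settle_dst
        g = dt * vel * atop  # (nv, L) m^3 swept per step
        c = x[idx]
        new = np.empty_like(c)
        # implicit upwind, solved top-down (influx uses the upper layer's
        # post-update concentration); unconditionally stable and positive
        new[:, L - 1] = c[:, L - 1] * vol[L - 1] / (vol[L - 1] + g[:, L - 1])
        for k in range(L - 2, -1, -1):
            new[:, k] = (c[:, k] * vol[k] + g[:, k] * new[:, k + 1]) / (vol[k] + g[:, k])
        x[idx] = new
        dep = dt * vel * new * ben / safe_ben  # areal g/m^2 deposited
        np.add.at(x, (dst, slice(None)), dep)

    def _mix(self, x: np.ndarray, wind: float) -> None:
        if self.grid.n_layers == 1:
            return
        d = physics.wind_diffusivity(wind, d0=self.p.mix_d0, cw=self.p.mix_cw)
        ab = physics.mixing_matrix(self.grid, d, self.dt)
        rhs = (x[MOBILE_VARS] * self._vol).T  # (L, nvars)
        sol = solve_banded((1, 1), ab, rhs).T
        x[MOBILE_VARS] = np.maximum(physics.apply_interface_fluxes(
            x[MOBILE_VARS], sol, self.grid, -ab[0, 1:]), 0.0)

    def _in_outflow(self, state: LakeState, q: float, cin: dict, t_top: float) -> None:
        """Exponential surface-layer flushing with exact boundary bookkeeping."""
        if q <= 0:
            return
        x = state.x
        v_top = self._vol[-1]
        f = np.exp(-q * self.dt / v_top)
        cin_vec = np.zeros(MOBILE_VARS.size)
        cin_vec[V.NH4] = cin["nh4"]
        cin_vec[V.NO3] = cin["no3"]
        cin_vec[V.PO4] = cin["po4"]
        cin_vec[V.DOM_N] = cin["dom_n"]
        cin_vec[V.DOM_P] = cin["dom_p"]
        cin_vec[V.POM_N] = cin["pom_n"]
        cin_vec[V.POM_P] = cin["pom_p"]
        cin_vec[V.POM_DM] = cin["pom_dm"]
        cin_vec[V.IM] = cin["im"]
        cin_vec[V.O2] = physics.oxygen_saturation(t_top)
        # stream-borne plankton re-seed the lake populations
        for idm in (V.DIA_DM, V.CYA_DM, V.OTH_DM):
            cin_vec[idm] = cin["phy_dm"] / 3.0
            cin_vec[idm + 1] = cin["phy_n"] / 3.0
            cin_vec[idm + 2] = cin["phy_p"] / 3.0
        cin_vec[V.ZOO_DM] = cin["zoo_dm"]
        cin_vec[V.ZOO_N] = cin["zoo_n"]
        cin_vec[V.ZOO_P] = cin["zoo_p"]
        c_old = x[MOBILE_VARS, -1]
        c_new = cin_vec + (c_old - cin_vec) * f
        x[MOBILE_VARS, -1] = c_new
        in_mass = q * self.dt * cin_vec
        out_mass = (c_old - c_new) * v_top + in_mass
        ncw = N_CONTENT[MOBILE_VARS]
        pcw = P_CONTENT[MOBILE_VARS]
        b = state.boundary
        b["inflow_N"] += float(ncw @ in_mass)
        b["inflow_P"] += float(pcw @ in_mass)
        b["outflow_N"] += float(ncw @ out_mass)
        b["outflow_P"] += float(pcw @ out_mass)

    def _events(self, state: LakeState, doy: int) -> None:
        """Calendar transfers: aging, spawning, optional winter fish kill."""
        p = self.p
        x = state.x
        if doy == 0 and p.fish_age_frac > 0:
            for off in range(3):
                moved = p.fish_age_frac * x[V.JUV_DM + off]
                x[V.JUV_DM + off] -= moved
                x[V.ADU_DM + off] += moved
        if doy == int(p.fish_spawn_day) and p.fish_spawn_frac > 0:
            for off in range(3):
                moved = p.fish_spawn_frac * x[V.ADU_DM + off]
                x[V.ADU_DM + off] -= moved
                x[V.JUV_DM + off] += moved
        if doy == int(p.winter_kill_day) and p.winter_kill_frac > 0:
            ratio = self._vol / self._ben  # m: converts conc removal to areal gain
            for idm in (V.JUV_DM, V.ADU_DM, V.PIS_DM):
                for off, tgt in [(0, V.SPOM_DM), (1, V.SPOM_N), (2, V.SPOM_P)]:
                    killed = p.winter_kill_frac * x[idm + off]
                    x[idm + off] -= killed
                    x[tgt] += killed * ratio

    # ------------------------------------------------------------------
    # run loop
    # ------------------------------------------------------------------
    def run(self, forcing: ForcingBundle, *, initial: LakeState | str = "turbid",
            n_days: int | None = None, record_start: int = 0,
            check_every: int = 200) -> RunResult:
        """Simulate ``n_days`` (default: the whole forcing) and record daily
        diagnostics from day ``record_start`` onward."""
        n_days = forcing.n_days if n_days is None else int(n_days)
        if n_days > forcing.n_days:
            raise ValueError("forcing does not cover the requested run length")
        state = self.initial_state(initial) if isinstance(initial, str) else initial.copy()
        if state.x.shape != (N_VARS, self.grid.n_layers):
            raise ValueError("initial state does not match the grid")

        grid = self.grid
        p = self.p
        L = grid.n_layers
        conv = self.conv
        dt = self.dt
        steps_per_day = round(1.0 / dt)
        temps = np.full(L, max(float(forcing.air_temp[0]), 4.0))

        n_rec = max(n_days - record_start, 0)
        layers = {k: np.empty((n_rec, L)) for k in LAYER_DIAGS}
        scalars = {k: np.empty(n_rec) for k in SCALAR_DIAGS}
        rec_days = np.arange(record_start, n_days)
        doys = forcing.doy(rec_days)

        lat = p.latitude
        area = grid.surface_area

        for d in range(n_days):
            doy = int(forcing.doy(d))
            air = float(forcing.air_temp[d])
            cloud = float(forcing.cloud[d])
            wind = float(forcing.wind[d])
            q = float(forcing.discharge[d])
            cin = {s: float(c[d]) for s, c in forcing.concentrations.items()}
            t_eq = air + p.solar_gain * (1.0 - 0.7 * cloud)
            par0 = float(physics.surface_par(doy + 1, cloud, latitude=lat))
            self._events(state, doy)

            for _ in range(steps_per_day):
                temps = physics.temperature_step(
                    temps, t_eq, grid, dt,
                    tau_surface=p.tau_temp_surface, tau_depth_scale=p.tau_temp_depth)
                x = state.x
                # Lambert-Beer light field (lean inline of physics.attenuation
                # and physics.light_profile)
                kd = (p.k_bg
                      + p.phy_k_ext * (x[V.DIA_DM] + x[V.CYA_DM] + x[V.OTH_DM])
                      + p.k_pom * x[V.POM_DM] + p.k_im * x[V.IM]
                      + p.k_veg * x[V.MAC_DM] * self._ben / self._vol)
                tau = kd * grid.heights
                tau_above = np.concatenate([[0.0], np.cumsum(tau[::-1])])[:-1][::-1]
                i_top = par0 * np.exp(-tau_above)
                par_bot = i_top * np.exp(-tau)
                par_mean = np.where(tau > 1e-12, (i_top - par_bot) / np.maximum(tau, 1e-12),
                                    i_top)
                f_light = par_mean / (par_mean + self._phy.h_light)  # (3, L)

                F, src, bnd = self._assemble(x, temps, par_mean, par_bot, f_light, wind)
                m = np.ascontiguousarray((x * conv).T)
                m = emp_step_batched(m, F, dt, sources=src, boundary_sinks=bnd,
                                     validate=False)
                state.x = x = np.ascontiguousarray(m.T) / conv

                self._settle(x)
                self._mix(x, wind)
                self._in_outflow(state, q, cin, float(temps[-1]))

            if d % check_every == 0:
                try:
                    state.validate()
                except Exception as exc:  # pragma: no cover - defensive
                    raise FloatingPointError(
                        f"integrator failure at day {d} (doy {doy}): {exc}") from exc

            if d >= record_start:
                i = d - record_start
                x = state.x
                layers["temp"][i] = temps
                chl_tot, chl_groups = processes.chla(
                    [x[V.DIA_DM], x[V.CYA_DM], x[V.OTH_DM]], f_light, self.specs)
                layers["chl"][i] = chl_tot
                layers["chl_dia"][i] = chl_groups[0]
                layers["chl_cya"][i] = chl_groups[1]
                layers["chl_oth"][i] = chl_groups[2]
                layers["tn"][i] = x[_WATER_N].sum(axis=0)
                layers["tp"][i] = x[_WATER_P].sum(axis=0)
                layers["po4"][i] = x[V.PO4]
                layers["no3"][i] = x[V.NO3]
                layers["nh4"][i] = x[V.NH4]
                layers["o2"][i] = x[V.O2]
                layers["pom_dm"][i] = x[V.POM_DM]
                layers["im"][i] = x[V.IM]
                layers["zoo_dm"][i] = x[V.ZOO_DM]
                layers["dia_dm"][i] = x[V.DIA_DM]
                layers["cya_dm"][i] = x[V.CYA_DM]
                layers["oth_dm"][i] = x[V.OTH_DM]
                layers["juv_dm"][i] = x[V.JUV_DM]
                layers["adu_dm"][i] = x[V.ADU_DM]
                layers["pis_dm"][i] = x[V.PIS_DM]
                layers["zb_dm"][i] = x[V.ZB_DM]
                layers["mac_dm"][i] = x[V.MAC_DM]
                cov, lake_cov, dlim = processes.coverage_and_depth_limit(
                    x[V.MAC_DM], grid, b_cov=p.mac_b_cov, threshold=0.1)
                layers["coverage"][i] = cov
                layers["kd"][i] = kd
                scalars["lake_coverage"][i] = lake_cov
                scalars["depth_limit"][i] = dlim
                p_in = cin["po4"] + cin["dom_p"] + cin["pom_p"] + cin["phy_p"]
                scalars["p_load"][i] = q * p_in / area * 1000.0
                scalars["total_n"][i] = state.total_n(conv)
                scalars["total_p"][i] = state.total_p(conv)
                scalars["inflow_n"][i] = state.boundary["inflow_N"]
                scalars["inflow_p"][i] = state.boundary["inflow_P"]
                scalars["outflow_n"][i] = state.boundary["outflow_N"]
                scalars["outflow_p"][i] = state.boundary["outflow_P"]

        state.validate()
        return RunResult(grid=grid, day_index=rec_days, doy=doys, layers=layers,
                         scalars=scalars, final_state=state, n_days=n_days)
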