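"""Biogeochemical and food-web process rates.

Pure, array-friendly rate functions used by the model kernel: temperature
multipliers, Droop (internal-stores) phytoplankton growth, quota-regulated
Michaelis-Menten nutrient uptake, variable chlorophyll:dry-mass ratio,
hyperbolic zooplankton filtration with ranked preferences, the
macrophyte production/respiration balance, and macrophyte coverage
geometry.  Everything here is per-unit-volume (or per-unit-area for
benthic pools) and per day; assembling them into mass fluxes is the
model's job.
"""

from __future__ import annotations

import numpy as np

from lakeshift.grid import VerticalGrid
from lakeshift.parameters import PhytoGroupSpec

__all__ = [
    "temp_factor_abiotic",
    "temp_factor_biotic",
    "droop_growth",
    "nutrient_uptake",
    "chla",
    "zoo_grazing",
    "macrophyte_net_growth",
    "piscivory_coverage_factor",
    "coverage_fraction",
    "coverage_and_depth_limit",
]


def temp_factor_abiotic(t, theta):
    """Exponential temperature multiplier theta^(T - 20) for abiotic rates."""
    if np.any(np.asarray(theta) <= 0):
        raise ValueError("theta must be positive")
    return np.asarray(theta, dtype=float) ** (np.asarray(t, dtype=float) - 20.0)


def temp_factor_biotic(t, t_opt, t_sigma):
    """Gaussian temperature multiplier exp(-((T - T_opt)/T_sigma)^2 / 2)."""
    if np.any(np.asarray(t_sigma) <= 0):
        raise ValueError("t_sigma must be positive")
    z = (np.asarray(t, dtype=float) - t_opt) / t_sigma
    return np.exp(-0.5 * z * z)


def _quota(stock, dm, q_min, q_max):
    """Internal nutrient quota, clipped to the physiological range."""
    dm = np.asarray(dm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(dm > 0, np.asarray(stock, dtype=float) / np.where(dm > 0, dm, 1.0), q_min)
    return np.clip(q, q_min, q_max)


def droop_growth(dm, n_stock, p_stock, light_factor, temp_factor, spec: PhytoGroupSpec):
    """Gross production (gDM m^-3 d^-1) under Droop co-limitation.

    mu = mu_max * f_T * f_I * min_nutrients(1 - q_min/q); growth stops when
    the internal store of either nutrient reaches its subsistence quota.
    """
    q_n = _quota(n_stock, dm, spec.q_min_n, spec.q_max_n)
    q_p = _quota(p_stock, dm, spec.q_min_p, spec.q_max_p)
    lim = np.minimum(1.0 - spec.q_min_n / q_n, 1.0 - spec.q_min_p / q_p)
    mu = spec.mu_max * np.asarray(temp_factor) * np.asarray(light_factor) * np.maximum(lim, 0.0)
    return mu * np.asarray(dm, dtype=float)


def nutrient_uptake(dm, n_stock, p_stock, nh4, no3, po4, spec: PhytoGroupSpec,
                    nh4_pref: float = 3.0):
    """Quota-regulated Michaelis-Menten uptake rates (g m^-3 d^-1).

    V = V_max * (q_max - q)/(q_max - q_min) * S/(S + K) * DM.  Ammonium is
    preferred over nitrate by weighting the dissolved pools ``nh4_pref : 1``
    when partitioning N uptake.

    Returns (uptake_nh4, uptake_no3, uptake_po4).
    """
    for s in (nh4, no3, po4):
        if np.any(np.asarray(s) < 0):
            raise ValueError("dissolved nutrient concentrations must be non-negative")
    dm = np.asarray(dm, dtype=float)
    q_n = _quota(n_stock, dm, spec.q_min_n, spec.q_max_n)
    q_p = _quota(p_stock, dm, spec.q_min_p, spec.q_max_p)
    reg_n = (spec.q_max_n - q_n) / (spec.q_max_n - spec.q_min_n)
    reg_p = (spec.q_max_p - q_p) / (spec.q_max_p - spec.q_min_p)
    din = np.asarray(nh4) + np.asarray(no3)
    v_n = spec.v_max_n * reg_n * din / (din + spec.k_n) * dm
    w = nh4_pref * np.asarray(nh4)
    tot = w + np.asarray(no3)
    with np.errstate(invalid="ignore"):
        frac_nh4 = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 0.0)
    v_p = spec.v_max_p * reg_p * np.asarray(po4) / (np.asarray(po4) + spec.k_p) * dm
    return v_n * frac_nh4, v_n * (1.0 - frac_nh4), v_p


def chla(dms, light_factors, specs) -> tuple[np.ndarray, list[np.ndarray]]:
    """Total and per-group chlorophyll a (ug/L == mg/m^3).

    The chl:DM ratio slides from its minimum (light-saturated) to its
    maximum (fully light-limited): ratio = max - (max - min) * f_I.
    """
    per_group = []
    for dm, f_i, spec in zip(dms, light_factors, specs, strict=True):
        f_i = np.clip(np.asarray(f_i, dtype=float), 0.0, 1.0)
        ratio = spec.chl_dm_max - (spec.chl_dm_max - spec.chl_dm_min) * f_i
        per_group.append(ratio * np.asarray(dm, dtype=float))
    return sum(per_group), per_group


def zoo_grazing(foods, prefs, zoo_dm, f_temp, f_max, h_food):
    """Per-food grazing fluxes (g m^-3 d^-1), hyperbolic filtration.

    Effective food F = sum_i p_i C_i; filtration rate (volume swept per
    unit grazer per day) = F_max * f_T / (1 + F/h_food); the grazing flux
    on food i is filtration * p_i * C_i * ZOO_DM, so total intake
    saturates at F_max * f_T * h_food * ZOO_DM for abundant food.
    """
    foods = [np.asarray(c, dtype=float) for c in foods]
    eff = sum(p * c for p, c in zip(prefs, foods, strict=True))
    filt = f_max * np.asarray(f_temp) / (1.0 + eff / h_food)
    return [filt * p * c * np.asarray(zoo_dm) for p, c in zip(prefs, foods)]


def macrophyte_net_growth(t, bottom_par, biomass, *, p_max, c_prod, resp, c_resp,
                          h_light, b_max, f_nutrient=1.0):
    """Net macrophyte growth (gDM m^-2 d^-1).

    growth = B * [p_max e^{c_p (T-20)} * PAR/(PAR+H_L) * (1 - B/B_max) * f_nut
                  - r_m e^{c_r (T-20)}]

    With c_resp > c_prod the net rate has an interior temperature optimum;
    the net value may be negative (die-back under dark or hot conditions).
    """
    if np.any(np.asarray(biomass) < 0):
        raise ValueError("biomass must be non-negative")
    b = np.asarray(biomass, dtype=float)
    t = np.asarray(t, dtype=float)
    par = np.asarray(bottom_par, dtype=float)
    prod = (p_max * np.exp(c_prod * (t - 20.0)) * par / (par + h_light)
            * np.maximum(1.0 - b / b_max, 0.0) * f_nutrient)
    loss = resp * np.exp(c_resp * (t - 20.0))
    return b * (prod - loss)


def piscivory_coverage_factor(coverage, c_cov_veg_min, h_d_veg_pisc):
    """Sigmoidal dependence of piscivore intake on macrophyte coverage (%).

    Rises monotonically from ``c_cov_veg_min`` at zero coverage toward 1.
    """
    cov = np.asarray(coverage, dtype=float)
    if np.any(cov < 0) or np.any(cov > 100):
        raise ValueError("coverage must be within [0, 100] %")
    return c_cov_veg_min + (1.0 - c_cov_veg_min) * cov / (cov + h_d_veg_pisc)


def coverage_fraction(biomass_areal, b_cov):
    """Per-layer macrophyte coverage (%) from areal biomass (gDM/m^2)."""
    return 100.0 * (1.0 - np.exp(-np.asarray(biomass_areal, dtype=float) / b_cov))


def coverage_and_depth_limit(biomass_areal, grid: VerticalGrid, *, b_cov: float,
                             threshold: float = 0.1):
    """Coverage per layer, benthic-area-weighted lake coverage, depth limit.

    The depth limit is the mid-depth (m below the surface) of the deepest
    layer whose coverage reaches ``threshold`` percent; 0 when no layer
    does.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must be in (0, 100)")
    cov = coverage_fraction(biomass_areal, b_cov)
    w = grid.benthic_areas
    lake_cov = float((cov * w).sum() / w.sum())
    above = np.nonzero(cov >= threshold)[0]
    depth_limit = float(grid.center_depths[above.min()]) if above.size else 0.0
    return cov, lake_cov, depth_limit
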