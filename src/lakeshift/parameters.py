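"""Named, bounded, unit-carrying model parameters.

The default set parameterizes a small, shallow, eutrophic temperate lake
with three phytoplankton groups (diatoms, cyanobacteria, other edible
algae), one zooplankton group, three layer-bound fish groups, detritivorous
zoobenthos, rooted submerged macrophytes, and an active 10-cm sediment
layer with phosphate sorption to iron-rich inorganic matter.  Bounds
define the calibration search space.  Values are this package's own
parameterization chosen for plausible magnitudes and clear qualitative
behaviour (spring diatom bloom, clear-water phase, late-summer peaks,
turbid-clear bistability in the fully-mixed configuration); they are not
a published reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from types import SimpleNamespace

import numpy as np

__all__ = ["Parameter", "ParameterSet", "PhytoGroupSpec", "default_parameters"]


@dataclass(frozen=True)
class Parameter:
    value: float
    lower: float
    upper: float
    unit: str = "-"
    description: str = ""

    def __post_init__(self):
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter value {self.value} outside bounds [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class PhytoGroupSpec:
    """Traits of one phytoplankton group (Droop internal-stores physiology)."""

    name: str
    mu_max: float        # 1/d
    t_opt: float         # deg C
    t_sigma: float       # deg C
    q_min_n: float       # gN/gDM
    q_max_n: float
    q_min_p: float       # gP/gDM
    q_max_p: float
    v_max_n: float       # gN/gDM/d
    v_max_p: float       # gP/gDM/d
    k_n: float           # g/m^3
    k_p: float           # g/m^3
    chl_dm_min: float    # mg chl / g DM
    chl_dm_max: float
    settling: float      # m/d
    k_ext: float         # m^2/gDM
    h_light: float       # W/m^2, light half-saturation
    resp: float          # 1/d at 20 C
    mort: float          # 1/d

    def __post_init__(self):
        if not (0 < self.q_min_n < self.q_max_n and 0 < self.q_min_p < self.q_max_p):
            raise ValueError("quota bounds must satisfy 0 < q_min < q_max")
        if self.chl_dm_min > self.chl_dm_max:
            raise ValueError("chl_dm_min must not exceed chl_dm_max")


class ParameterSet:
    """Ordered mapping of named :class:`Parameter` entries.

    Supports vector views over a subset of names (the calibration
    interface) and fast flattening to a plain attribute namespace for the
    simulation inner loop.
    """

    def __init__(self, entries: dict[str, Parameter]):
        self._entries = dict(entries)

    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def __eq__(self, other):
        return isinstance(other, ParameterSet) and self._entries == other._entries

    def entry(self, name: str) -> Parameter:
        return self._entries[name]

    def names(self) -> list[str]:
        return list(self._entries)

    def bounds(self, names=None) -> np.ndarray:
        names = names if names is not None else self.names()
        return np.array([[self._entries[n].lower, self._entries[n].upper] for n in names])

    def values(self, names=None) -> np.ndarray:
        names = names if names is not None else self.names()
        return np.array([self._entries[n].value for n in names])

    def with_values(self, names, values) -> "ParameterSet":
        """New set with ``names`` replaced by ``values`` (bounds-checked)."""
        out = dict(self._entries)
        for n, v in zip(names, values, strict=True):
            out[n] = replace(out[n], value=float(v))
        return ParameterSet(out)

    def with_bounds(self, names, bounds) -> "ParameterSet":
        out = dict(self._entries)
        for n, (lo, hi) in zip(names, bounds, strict=True):
            e = out[n]
            out[n] = Parameter(float(np.clip(e.value, lo, hi)), float(lo), float(hi),
                               e.unit, e.description)
        return ParameterSet(out)

    def flat(self) -> SimpleNamespace:
        """Plain float namespace for the inner simulation loop."""
        return SimpleNamespace(**{n: e.value for n, e in self._entries.items()})

    def phyto_specs(self) -> list[PhytoGroupSpec]:
        """The three phytoplankton group specs assembled from entries."""
        specs = []
        for g in ("dia", "cya", "oth"):
            specs.append(PhytoGroupSpec(
                name=g,
                mu_max=self[f"{g}_mu_max"], t_opt=self[f"{g}_t_opt"],
                t_sigma=self[f"{g}_t_sigma"],
                q_min_n=self["phy_q_min_n"], q_max_n=self["phy_q_max_n"],
                q_min_p=self["phy_q_min_p"], q_max_p=self["phy_q_max_p"],
                v_max_n=self["phy_v_max_n"], v_max_p=self[f"{g}_v_max_p"],
                k_n=self["phy_k_n"], k_p=self[f"{g}_k_p"],
                chl_dm_min=self["phy_chl_dm_min"], chl_dm_max=self["phy_chl_dm_max"],
                settling=self[f"{g}_settling"], k_ext=self["phy_k_ext"],
                h_light=self[f"{g}_h_light"], resp=self["phy_resp"],
                mort=self["phy_mort"],
            ))
        return specs

    def to_frame(self):
        import pandas as pd

        rows = [{"name": n, "value": e.value, "lower": e.lower, "upper": e.upper,
                 "unit": e.unit, "description": e.description}
                for n, e in self._entries.items()]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df) -> "ParameterSet":
        return cls({r["name"]: Parameter(r["value"], r["lower"], r["upper"],
                                         r.get("unit", "-"), r.get("description", ""))
                    for r in df.to_dict("records")})


def _p(value, lower, upper, unit="-", desc=""):
    return Parameter(float(value), float(lower), float(upper), unit, desc)


def default_parameters() -> ParameterSet:
    e: dict[str, Parameter] = {}

    # ----- abiotic temperature coefficients -----
    e["theta_min"] = _p(1.07, 1.02, 1.15, "-", "theta for mineralization")
    e["theta_nit"] = _p(1.08, 1.02, 1.15, "-", "theta for nitrification")
    e["theta_dif"] = _p(1.02, 1.0, 1.1, "-", "theta for sediment diffusion")
    e["theta_rea"] = _p(1.024, 1.0, 1.1, "-", "theta for reaeration")

    # ----- phytoplankton groups -----
    e["dia_mu_max"] = _p(2.2, 1.0, 3.5, "1/d", "diatom max growth")
    e["cya_mu_max"] = _p(1.0, 0.4, 2.0, "1/d", "cyanobacteria max growth")
    e["oth_mu_max"] = _p(1.8, 0.8, 3.0, "1/d", "other algae max growth")
    e["dia_t_opt"] = _p(12.0, 5.0, 20.0, "degC", "diatom optimum temperature")
    e["cya_t_opt"] = _p(24.0, 18.0, 30.0, "degC", "cyanobacteria optimum temperature")
    e["oth_t_opt"] = _p(18.0, 10.0, 25.0, "degC", "other algae optimum temperature")
    e["dia_t_sigma"] = _p(10.0, 4.0, 16.0, "degC", "diatom temperature breadth")
    e["cya_t_sigma"] = _p(6.0, 3.0, 12.0, "degC", "cyanobacteria temperature breadth")
    e["oth_t_sigma"] = _p(9.0, 4.0, 16.0, "degC", "other algae temperature breadth")
    e["dia_settling"] = _p(0.15, 0.05, 1.0, "m/d", "diatom settling velocity")
    e["cya_settling"] = _p(0.01, 0.0, 0.2, "m/d", "cyanobacteria settling velocity")
    e["oth_settling"] = _p(0.06, 0.02, 0.5, "m/d", "other algae settling velocity")
    e["dia_h_light"] = _p(12.0, 5.0, 60.0, "W/m2", "diatom light half-saturation")
    e["cya_h_light"] = _p(10.0, 5.0, 60.0, "W/m2", "cyanobacteria light half-saturation")
    e["oth_h_light"] = _p(12.0, 5.0, 60.0, "W/m2", "other algae light half-saturation")
    e["dia_v_max_p"] = _p(0.025, 0.002, 0.05, "gP/gDM/d", "diatom max P uptake")
    e["cya_v_max_p"] = _p(0.012, 0.002, 0.05, "gP/gDM/d", "cyanobacteria max P uptake")
    e["oth_v_max_p"] = _p(0.02, 0.002, 0.05, "gP/gDM/d", "other algae max P uptake")
    e["dia_k_p"] = _p(0.02, 0.002, 0.1, "gP/m3", "diatom P affinity half-sat")
    e["cya_k_p"] = _p(0.008, 0.002, 0.1, "gP/m3", "cyanobacteria P affinity half-sat")
    e["oth_k_p"] = _p(0.015, 0.002, 0.1, "gP/m3", "other algae P affinity half-sat")
    e["phy_q_min_n"] = _p(0.015, 0.005, 0.03, "gN/gDM", "min N quota")
    e["phy_q_max_n"] = _p(0.08, 0.03, 0.12, "gN/gDM", "max N quota")
    e["phy_q_min_p"] = _p(0.003, 0.001, 0.006, "gP/gDM", "min P quota")
    e["phy_q_max_p"] = _p(0.012, 0.006, 0.03, "gP/gDM", "max P quota")
    e["phy_v_max_n"] = _p(0.07, 0.01, 0.3, "gN/gDM/d", "max N uptake")
    e["phy_k_n"] = _p(0.15, 0.02, 0.8, "gN/m3", "N affinity half-sat")
    e["phy_chl_dm_min"] = _p(5.0, 2.0, 10.0, "mg chl/gDM", "chl:DM at light saturation")
    e["phy_chl_dm_max"] = _p(10.0, 6.0, 30.0, "mg chl/gDM", "chl:DM under light limitation")
    e["phy_k_ext"] = _p(0.15, 0.05, 0.4, "m2/gDM", "phytoplankton specific extinction")
    e["phy_resp"] = _p(0.05, 0.01, 0.15, "1/d", "phytoplankton respiration at 20C")
    e["phy_mort"] = _p(0.04, 0.01, 0.15, "1/d", "phytoplankton mortality/lysis")
    e["nh4_pref"] = _p(3.0, 1.0, 10.0, "-", "NH4-over-NO3 uptake preference weight")

    # ----- light / water column -----
    e["k_bg"] = _p(0.4, 0.1, 2.0, "1/m", "background extinction")
    e["k_pom"] = _p(0.04, 0.01, 0.2, "m2/g", "POM specific extinction")
    e["k_im"] = _p(0.05, 0.01, 0.2, "m2/g", "inorganic matter specific extinction")
    e["k_veg"] = _p(0.01, 0.0, 0.05, "m2/g", "macrophyte self-shading coefficient")

    # ----- zooplankton -----
    e["zoo_f_max"] = _p(0.4, 0.1, 1.5, "m3/gDM/d", "max filtering rate")
    e["zoo_h_food"] = _p(0.8, 0.2, 5.0, "g/m3", "filtering half-saturation food level")
    e["zoo_pref_dia"] = _p(1.0, 0.5, 1.0, "-", "preference for diatoms")
    e["zoo_pref_oth"] = _p(0.75, 0.3, 1.0, "-", "preference for other algae")
    e["zoo_pref_cya"] = _p(0.4, 0.05, 0.8, "-", "preference for cyanobacteria")
    e["zoo_pref_pom"] = _p(0.15, 0.05, 0.6, "-", "preference for POM")
    e["zoo_assim"] = _p(0.6, 0.3, 0.8, "-", "assimilation efficiency")
    e["zoo_resp"] = _p(0.05, 0.02, 0.2, "1/d", "zooplankton respiration at 20C")
    e["zoo_mort"] = _p(0.03, 0.01, 0.15, "1/d", "zooplankton background mortality")
    e["zoo_mort2"] = _p(0.05, 0.0, 0.3, "m3/gDM/d",
                        "quadratic zooplankton closure (unresolved predation)")
    e["zoo_t_opt"] = _p(20.0, 12.0, 28.0, "degC", "zooplankton optimum temperature")
    e["zoo_t_sigma"] = _p(10.0, 4.0, 16.0, "degC", "zooplankton temperature breadth")

    # ----- fish -----
    e["juv_uptake"] = _p(0.06, 0.02, 0.4, "g/gDM/d", "juvenile fish max intake")
    e["juv_h_food"] = _p(0.5, 0.1, 3.0, "g/m3", "juvenile intake half-sat (zooplankton)")
    e["adu_uptake"] = _p(0.04, 0.01, 0.3, "g/gDM/d", "adult fish max intake")
    e["adu_h_food"] = _p(10.0, 2.0, 50.0, "g/m2", "adult intake half-sat (zoobenthos)")
    e["pis_uptake"] = _p(0.08, 0.01, 0.2, "g/gDM/d", "piscivore max intake")
    e["pis_h_food"] = _p(2.0, 0.5, 10.0, "g/m3", "piscivore intake half-sat (prey fish)")
    e["fish_assim"] = _p(0.35, 0.2, 0.7, "-", "fish assimilation efficiency")
    e["fish_resp"] = _p(0.004, 0.001, 0.05, "1/d", "fish respiration at 20C")
    e["fish_mort"] = _p(0.0015, 0.0005, 0.02, "1/d", "fish background mortality")
    e["fish_t_opt"] = _p(22.0, 12.0, 28.0, "degC", "fish optimum temperature")
    e["fish_t_sigma"] = _p(10.0, 4.0, 16.0, "degC", "fish temperature breadth")
    e["cCovVegMin"] = _p(0.1, 0.01, 1.0, "-", "piscivory multiplier at zero coverage")
    e["hDVegPisc"] = _p(15.0, 2.0, 60.0, "% coverage", "piscivory-coverage half-saturation")
    e["fish_age_frac"] = _p(0.5, 0.1, 0.9, "-", "juvenile-to-adult transfer on Jan 1")
    e["fish_spawn_frac"] = _p(0.15, 0.02, 0.5, "-", "adult-to-juvenile transfer on spawn day")
    e["fish_spawn_day"] = _p(135, 90, 180, "doy", "spawning day of year")
    e["winter_kill_frac"] = _p(0.0, 0.0, 1.0, "-", "fraction of fish killed on kill day")
    e["winter_kill_day"] = _p(20, 1, 90, "doy", "winter fish-kill day of year")

    # ----- zoobenthos -----
    e["zb_uptake"] = _p(0.06, 0.01, 0.3, "g/gDM/d", "zoobenthos max intake")
    e["zb_h_food"] = _p(300.0, 50.0, 2000.0, "g/m2", "zoobenthos intake half-sat (sed POM)")
    e["zb_assim"] = _p(0.4, 0.2, 0.7, "-", "zoobenthos assimilation efficiency")
    e["zb_resp"] = _p(0.01, 0.002, 0.05, "1/d", "zoobenthos respiration at 20C")
    e["zb_mort"] = _p(0.005, 0.001, 0.03, "1/d", "zoobenthos mortality")
    e["zb_mort2"] = _p(0.0005, 0.0, 0.01, "m2/gDM/d",
                       "quadratic zoobenthos closure (unresolved predation)")
    e["zb_t_opt"] = _p(15.0, 8.0, 25.0, "degC", "zoobenthos optimum temperature")
    e["zb_t_sigma"] = _p(10.0, 4.0, 16.0, "degC", "zoobenthos temperature breadth")

    # ----- macrophytes -----
    e["mac_p_max"] = _p(0.35, 0.05, 0.8, "1/d", "macrophyte max gross production at 20C")
    e["mac_c_prod"] = _p(0.014, 0.005, 0.05, "1/degC", "production temperature exponent")
    e["mac_resp"] = _p(0.03, 0.005, 0.1, "1/d", "maintenance respiration at 20C")
    e["mac_c_resp"] = _p(0.074, 0.02, 0.15, "1/degC", "respiration temperature exponent")
    e["mac_h_light"] = _p(10.0, 4.0, 60.0, "W/m2", "light half-saturation at the bottom")
    e["mac_b_max"] = _p(400.0, 100.0, 1000.0, "gDM/m2", "carrying-capacity biomass")
    e["mac_mort"] = _p(0.004, 0.001, 0.03, "1/d", "macrophyte loss rate")
    e["mac_q_n"] = _p(0.02, 0.01, 0.05, "gN/gDM", "macrophyte N content")
    e["mac_q_p"] = _p(0.002, 0.0008, 0.006, "gP/gDM", "macrophyte P content")
    e["mac_h_n"] = _p(0.1, 0.02, 2.0, "gN/m3", "porewater N half-sat for growth")
    e["mac_h_p"] = _p(0.01, 0.002, 0.3, "gP/m3", "porewater P half-sat for growth")
    e["mac_b_cov"] = _p(120.0, 30.0, 400.0, "gDM/m2", "coverage saturation biomass scale")
    e["mac_f_shoot"] = _p(0.3, 0.0, 1.0, "-",
                          "fraction of macrophyte nutrient uptake from the water column")
    e["mac_protect"] = _p(0.8, 0.0, 1.0, "-", "max resuspension damping by full coverage")

    # ----- water-column chemistry -----
    e["k_hyd_pom"] = _p(0.03, 0.005, 0.15, "1/d", "POM hydrolysis to DOM at 20C")
    e["k_min_dom"] = _p(0.08, 0.01, 0.2, "1/d", "DOM mineralization at 20C")
    e["k_nit"] = _p(0.1, 0.01, 0.5, "1/d", "water nitrification at 20C")
    e["h_o2_nit"] = _p(2.0, 0.5, 6.0, "gO2/m3", "O2 half-sat of nitrification")
    e["k_den_wat"] = _p(0.08, 0.005, 0.3, "1/d", "water denitrification at 20C")
    e["h_o2_den"] = _p(0.5, 0.1, 3.0, "gO2/m3", "O2 inhibition half-sat of denitrification")
    e["y_o2_dm"] = _p(1.4, 1.0, 2.0, "gO2/gDM", "O2 per unit DM produced/mineralized")
    e["y_o2_nit"] = _p(4.57, 4.57, 4.57, "gO2/gN", "O2 consumed per N nitrified")
    e["pom_settling"] = _p(0.2, 0.05, 1.0, "m/d", "POM settling velocity")
    e["im_settling"] = _p(0.5, 0.1, 3.0, "m/d", "inorganic matter settling velocity")

    # ----- sediment -----
    e["sed_depth"] = _p(0.1, 0.1, 0.1, "m", "active sediment layer height")
    e["sed_porosity"] = _p(0.8, 0.6, 0.95, "-", "sediment porosity")
    e["k_min_sed"] = _p(0.008, 0.0005, 0.03, "1/d", "sediment POM mineralization at 20C")
    e["k_humif"] = _p(0.001, 0.0001, 0.01, "1/d", "POM humification rate")
    e["k_min_hum"] = _p(0.0002, 1e-05, 0.002, "1/d", "humus mineralization at 20C")
    e["k_bur"] = _p(2e-04, 1e-06, 0.002, "1/d", "burial rate of humus and sediment IM")
    e["k_nit_sed"] = _p(0.3, 0.01, 0.8, "1/d", "sediment nitrification at 20C")
    e["k_den_sed"] = _p(0.6, 0.02, 1.5, "1/d", "sediment denitrification at 20C")
    e["k_diff"] = _p(0.04, 0.002, 0.2, "m/d", "porewater-water diffusion piston velocity")
    e["q_sorb_max"] = _p(0.004, 0.0005, 0.02, "gP/gIM", "max P sorption capacity of IM")
    e["h_sorb"] = _p(0.5, 0.05, 3.0, "gP/m3", "porewater PO4 sorption half-sat")
    e["h_o2_sorb"] = _p(1.0, 0.2, 5.0, "gO2/m3", "O2 half-sat of oxic sorption")
    e["k_sorp"] = _p(0.05, 0.005, 0.5, "1/d", "sorption relaxation rate")
    e["k_resus"] = _p(0.01, 0.001, 0.1, "1/d per tau", "resuspension rate coefficient")
    e["tau_crit"] = _p(0.3, 0.05, 1.5, "-", "critical shear (dimensionless proxy)")

    # ----- physics -----
    e["fetch"] = _p(1000.0, 100.0, 5000.0, "m", "effective wind fetch")
    e["c_tau"] = _p(0.05, 0.005, 0.3, "-", "shear proxy wind coefficient")
    e["shear_depth_scale"] = _p(1.5, 0.5, 5.0, "m", "shear decay depth scale")
    e["mix_d0"] = _p(1e-4, 1e-6, 1e-3, "m2/s", "background vertical diffusivity")
    e["mix_cw"] = _p(2e-4, 1e-5, 2e-3, "m2/s per (m/s)^3", "wind-cubed diffusivity coefficient")
    e["tau_temp_surface"] = _p(3.0, 0.5, 10.0, "d", "surface temperature relaxation time")
    e["tau_temp_depth"] = _p(8.0, 2.0, 30.0, "m", "temperature relaxation depth scale")
    e["solar_gain"] = _p(5.0, 0.0, 8.0, "degC", "clear-sky equilibrium temperature surplus")
    e["rea_k0"] = _p(0.5, 0.1, 2.0, "m/d", "reaeration piston velocity, calm")
    e["rea_kw"] = _p(0.05, 0.005, 0.3, "m/d per (m/s)^2", "reaeration wind coefficient")
    e["latitude"] = _p(56.0, 30.0, 70.0, "degN", "lake latitude (solar geometry)")

    return ParameterSet(e)
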