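"""Daily forcing bundle driving the lake model.

The simulation core runs on a canonical 365-day year (leap days are
dropped when ingesting dated series) so that multi-year scenario blocks
tile exactly.  A :class:`ForcingBundle` carries daily meteorology
(air temperature, cloud, wind speed), total inflow discharge, and
flow-weighted inflow concentrations for the transported constituents.

Inlet nutrient loads follow the monitoring convention for lowland
agricultural streams: the particulate organic fraction of the inflow is
taken as a fixed share of the total load (75% of total P and 90% of
total N organic by default), the remainder entering as dissolved
inorganic species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ForcingBundle",
    "drop_leap_days",
    "build_forcing",
    "partition_inflow_nutrients",
]

DAYS_PER_YEAR = 365

#: constituents carried by the inflow, in state units (g/m^3)
INFLOW_SPECIES = ("nh4", "no3", "po4", "dom_n", "dom_p", "pom_n", "pom_p",
                  "pom_dm", "phy_dm", "phy_n", "phy_p", "zoo_dm", "zoo_n",
                  "zoo_p", "im")


def drop_leap_days(df: pd.DataFrame, time_col: str = "time") -> pd.DataFrame:
    """Remove Feb 29 rows so every year has exactly 365 days."""
    t = pd.DatetimeIndex(df[time_col])
    keep = ~((t.month == 2) & (t.day == 29))
    return df.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class ForcingBundle:
    """Daily model forcing on the canonical 365-day calendar.

    ``start_doy`` is the 0-based day-of-year of the first record (0 =
    Jan 1); ``concentrations[s]`` is the flow-weighted inflow
    concentration of species ``s`` in g/m^3.
    """

    air_temp: np.ndarray      # deg C
    cloud: np.ndarray         # fraction 0-1
    wind: np.ndarray          # m/s
    discharge: np.ndarray     # m^3/d, all inlets combined
    concentrations: dict      # species -> (n,) g/m^3
    start_doy: int = 0

    def __post_init__(self):
        n = self.n_days
        for name in ("air_temp", "cloud", "wind", "discharge"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"forcing component {name!r} has inconsistent length")
        for s in INFLOW_SPECIES:
            if s not in self.concentrations or len(self.concentrations[s]) != n:
                raise ValueError(f"missing or inconsistent inflow species {s!r}")

    @property
    def n_days(self) -> int:
        return len(self.air_temp)

    def doy(self, day_index) -> np.ndarray:
        """0-based day-of-year for simulation day index."""
        return (np.asarray(day_index) + self.start_doy) % DAYS_PER_YEAR

    def slice(self, start: int, stop: int) -> "ForcingBundle":
        if not 0 <= start < stop <= self.n_days:
            raise ValueError("window not covered by forcing")
        return ForcingBundle(
            air_temp=self.air_temp[start:stop], cloud=self.cloud[start:stop],
            wind=self.wind[start:stop], discharge=self.discharge[start:stop],
            concentrations={s: c[start:stop] for s, c in self.concentrations.items()},
            start_doy=int((self.start_doy + start) % DAYS_PER_YEAR),
        )

    def tile(self, reps: int) -> "ForcingBundle":
        """Repeat this bundle ``reps`` times (exact within-window repetition)."""
        if reps < 1:
            raise ValueError("reps must be >= 1")
        return replace(self, air_temp=np.tile(self.air_temp, reps),
                       cloud=np.tile(self.cloud, reps), wind=np.tile(self.wind, reps),
                       discharge=np.tile(self.discharge, reps),
                       concentrations={s: np.tile(c, reps)
                                       for s, c in self.concentrations.items()})

    def concat(self, other: "ForcingBundle") -> "ForcingBundle":
        if other.start_doy != (self.start_doy + self.n_days) % DAYS_PER_YEAR:
            raise ValueError("concatenated forcing is not calendar-continuous")
        return replace(self, air_temp=np.concatenate([self.air_temp, other.air_temp]),
                       cloud=np.concatenate([self.cloud, other.cloud]),
                       wind=np.concatenate([self.wind, other.wind]),
                       discharge=np.concatenate([self.discharge, other.discharge]),
                       concentrations={s: np.concatenate([self.concentrations[s],
                                                          other.concentrations[s]])
                                       for s in self.concentrations})

    def scale_p(self, multiplier: float) -> "ForcingBundle":
        """Scale inflow phosphorus (PO4 and organic P) concentrations."""
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        conc = dict(self.concentrations)
        for s in ("po4", "dom_p", "pom_p", "phy_p"):
            conc[s] = conc[s] * multiplier
        return replace(self, concentrations=conc)

    def total_p_conc(self) -> np.ndarray:
        c = self.concentrations
        return c["po4"] + c["dom_p"] + c["pom_p"] + c["phy_p"]

    def total_n_conc(self) -> np.ndarray:
        c = self.concentrations
        return c["nh4"] + c["no3"] + c["dom_n"] + c["pom_n"] + c["phy_n"]

    def areal_p_load(self, lake_area: float) -> float:
        """Mean external P load (mg P m^-2 d^-1) over the bundle."""
        return float(np.mean(self.discharge * self.total_p_conc()) / lake_area * 1000.0)

    def areal_n_load(self, lake_area: float) -> float:
        """Mean external N load (mg N m^-2 d^-1)."""
        return float(np.mean(self.discharge * self.total_n_conc()) / lake_area * 1000.0)


def partition_inflow_nutrients(tn, tp, *, org_frac_p: float = 0.75,
                               org_frac_n: float = 0.90, frac_nh4: float = 0.3,
                               dom_share: float = 0.75, phyto_share: float = 0.05,
                               zoo_share: float = 0.01,
                               pom_q_n: float = 0.06, phy_q_n: float = 0.03,
                               zoo_q_n: float = 0.07) -> dict:
    """Split total inflow nutrients into model species.

    The organic fraction is ``org_frac_p`` of total P and ``org_frac_n``
    of total N.  Within the organic pool, ``dom_share`` enters as
    dissolved organic matter, ``phyto_share`` as live stream-borne algae
    (split evenly among the groups downstream), and the remainder as
    particulate organic matter.  The inorganic remainder of N is split
    between ammonium (``frac_nh4``) and nitrate.  Dry masses are inferred
    from organic N at fixed N contents.
    """
    tn = np.asarray(tn, dtype=float)
    tp = np.asarray(tp, dtype=float)
    org_n = org_frac_n * tn
    org_p = org_frac_p * tp
    inorg_n = tn - org_n
    pom_share = 1.0 - dom_share - phyto_share - zoo_share
    if pom_share < 0:
        raise ValueError("organic shares must not exceed 1")
    phy_n = phyto_share * org_n
    return {
        "nh4": frac_nh4 * inorg_n,
        "no3": (1.0 - frac_nh4) * inorg_n,
        "po4": tp - org_p,
        "dom_n": dom_share * org_n,
        "dom_p": dom_share * org_p,
        "pom_n": pom_share * org_n,
        "pom_p": pom_share * org_p,
        "pom_dm": pom_share * org_n / pom_q_n,
        "phy_dm": phy_n / phy_q_n,
        "phy_n": phy_n,
        "phy_p": phyto_share * org_p,
        "zoo_dm": zoo_share * org_n / zoo_q_n,
        "zoo_n": zoo_share * org_n,
        "zoo_p": zoo_share * org_p,
    }


def build_forcing(meteo_daily: pd.DataFrame, inflow: pd.DataFrame, *,
                  inflow_im: float = 2.0, start_doy: int = 0) -> ForcingBundle:
    """Assemble a ForcingBundle from daily meteorology and inlet tables.

    ``meteo_daily`` needs columns time, air_temp, cloud, wind_speed (one
    row per canonical day).  ``inflow`` is the long-format inlet table
    (columns: time, inlet, discharge_m3s, nh4, no3, po4, org_n, org_p in
    g/m^3, monthly rows); values are held stepwise-constant within each
    month and inlets are combined flow-weighted.
    """
    met = drop_leap_days(meteo_daily)
    t = pd.DatetimeIndex(met["time"])
    n = len(met)

    inf = inflow.copy()
    inf["time"] = pd.DatetimeIndex(inf["time"])
    inf["month"] = inf["time"].dt.to_period("M")
    q_m3d = inf["discharge_m3s"] * 86400.0
    agg = {}
    for sp, col in [("nh4", "nh4"), ("no3", "no3"), ("po4", "po4")]:
        agg[sp] = (inf[col] * q_m3d).groupby(inf["month"]).sum()
    org_n = (inf["org_n"] * q_m3d).groupby(inf["month"]).sum()
    org_p = (inf["org_p"] * q_m3d).groupby(inf["month"]).sum()
    q_tot = q_m3d.groupby(inf["month"]).sum()

    months = t.to_period("M")
    if not set(months.unique()).issubset(set(q_tot.index)):
        raise ValueError("inflow table does not cover the meteorology window")
    q_daily = q_tot.reindex(months).to_numpy()
    conc = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for sp, series in [("nh4", agg["nh4"]), ("no3", agg["no3"]), ("po4", agg["po4"]),
                           ("org_n", org_n), ("org_p", org_p)]:
            load = series.reindex(months).to_numpy()
            conc[sp] = np.where(q_daily > 0, load / np.where(q_daily > 0, q_daily, 1.0), 0.0)
    # split the organic load among dissolved, particulate, and live algae
    o_n, o_p = conc.pop("org_n"), conc.pop("org_p")
    dom_share, phyto_share, zoo_share = 0.75, 0.05, 0.01
    pom_q_n, phy_q_n, zoo_q_n = 0.06, 0.03, 0.07
    pom_share = 1.0 - dom_share - phyto_share - zoo_share
    conc["dom_n"] = dom_share * o_n
    conc["dom_p"] = dom_share * o_p
    conc["pom_n"] = pom_share * o_n
    conc["pom_p"] = pom_share * o_p
    conc["pom_dm"] = pom_share * o_n / pom_q_n
    conc["phy_n"] = phyto_share * o_n
    conc["phy_p"] = phyto_share * o_p
    conc["phy_dm"] = phyto_share * o_n / phy_q_n
    conc["zoo_n"] = zoo_share * o_n
    conc["zoo_p"] = zoo_share * o_p
    conc["zoo_dm"] = zoo_share * o_n / zoo_q_n
    conc["im"] = np.full(n, float(inflow_im))

    return ForcingBundle(
        air_temp=met["air_temp"].to_numpy(float),
        cloud=met["cloud"].to_numpy(float),
        wind=met["wind_speed"].to_numpy(float),
        discharge=q_daily,
        concentrations=conc,
        start_doy=start_doy,
    )
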