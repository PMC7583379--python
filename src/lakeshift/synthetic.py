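"""Synthetic study-lake generator.

Generates every input the pipeline needs — basin hypsograph, 3-hourly
meteorology, monthly inlet forcing, and sparse depth-pooled observations
from a truth run — for a small, shallow temperate lake (defaults: 0.91
km^2 surface, 1.2 m mean and 2.6 m maximum depth; winter/summer air
temperature means 3.7/14.5 degC; external loads about 120 Mg N/yr and
3 Mg P/yr; hydraulic residence about 16 d in winter and 32 d in summer).
Inlet nutrients are partitioned with 75% of total P and 90% of total N
organic.  Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from lakeshift.forcing import DAYS_PER_YEAR, ForcingBundle, build_forcing
from lakeshift.grid import Hypsograph, VerticalGrid, build_grid
from lakeshift.model import LakeModel, RunResult
from lakeshift.parameters import ParameterSet, default_parameters

__all__ = [
    "SyntheticLakeSpec",
    "gen_hypsograph",
    "gen_meteorology",
    "gen_inflow",
    "gen_observations",
    "make_twin_fixture",
    "canonical_dates",
]

#: default analytical error fractions by observed variable
ERROR_FRACTIONS = {
    "temp": 0.05, "o2": 0.10, "chl": 0.20, "tn": 0.15, "tp": 0.15,
    "po4": 0.15, "no3": 0.15, "nh4": 0.15, "zoo_dm": 0.20, "pom_dm": 0.15,
}

WINTER_MONTHS = (10, 11, 12, 1, 2, 3, 4)  # Oct-Apr
SUMMER_MONTHS = (5, 6, 7, 8, 9)           # May-Sep


@dataclass(frozen=True)
class SyntheticLakeSpec:
    """Morphometry, climate, and loading of the synthetic study lake."""

    surface_area: float = 0.91e6     # m^2
    max_depth: float = 2.6           # m
    mean_depth: float = 1.2          # m
    winter_air_temp: float = 3.7     # degC, Oct-Apr mean
    summer_air_temp: float = 14.5    # degC, May-Sep mean
    annual_precip_mm: float = 803.0
    tn_load: float = 120.0e6         # g N/yr
    tp_load: float = 3.0e6           # g P/yr
    residence_winter_d: float = 16.0
    residence_summer_d: float = 32.0
    mean_wind: float = 4.0           # m/s
    mean_cloud: float = 0.6
    n_inlets: int = 3
    inlet_shares: tuple = (0.5, 0.3, 0.2)
    org_frac_p: float = 0.75
    org_frac_n: float = 0.90
    start_year: int = 1990
    seed: int = 42

    def __post_init__(self):
        if not 0 < self.mean_depth < self.max_depth:
            raise ValueError("need 0 < mean_depth < max_depth")

    @property
    def volume(self) -> float:
        return self.surface_area * self.mean_depth


def canonical_dates(start_year: int, years: int) -> pd.DatetimeIndex:
    """Daily timestamps covering ``years`` canonical 365-day years."""
    raw = pd.date_range(f"{start_year}-01-01", periods=years * 366 + 2, freq="D")
    keep = ~((raw.month == 2) & (raw.day == 29))
    return raw[keep][: years * DAYS_PER_YEAR]


# ---------------------------------------------------------------------------
# hypsograph
# ---------------------------------------------------------------------------

def gen_hypsograph(spec: SyntheticLakeSpec, n_points: int = 27) -> Hypsograph:
    """Power-law basin A(z) = A_s (z/z_max)^p with p solved numerically so
    the tabulated (trapezoid-integrated) hypsograph reproduces the target
    mean depth (volume / surface area)."""
    levels = np.linspace(0.0, spec.max_depth, n_points)

    def mean_depth_of(p):
        areas = spec.surface_area * (levels / spec.max_depth) ** p
        vol = np.trapezoid(areas, levels)
        return vol / spec.surface_area - spec.mean_depth

    # mean depth ranges over (0, z_max) as p spans (0, inf)
    try:
        p = brentq(mean_depth_of, 1e-3, 50.0)
    except ValueError as exc:
        raise ValueError("infeasible mean/max depth combination") from exc
    areas = spec.surface_area * (levels / spec.max_depth) ** p
    return Hypsograph(levels=levels, areas=areas)


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def _seasonal_coefficients(peak_doy: float = 205.0):
    """Mean of the annual cosine over the summer and winter windows."""
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    months = pd.DatetimeIndex(canonical_dates(2001, 1)).month
    cosine = np.cos(2 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)
    summer = np.isin(months, SUMMER_MONTHS)
    return cosine[summer].mean(), cosine[~summer].mean(), cosine


def gen_meteorology(spec: SyntheticLakeSpec, years: int, seed: int | None = None,
                    *, noise: bool = True) -> pd.DataFrame:
    """3-hourly meteorology: seasonal + diurnal cycles with AR(1) anomalies.

    The seasonal sinusoid amplitude and offset are solved exactly so the
    noise-free Oct-Apr and May-Sep means equal the spec's winter and
    summer air temperatures.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    c_s, c_w, cosine = _seasonal_coefficients()
    amp = (spec.summer_air_temp - spec.winter_air_temp) / (c_s - c_w)
    base = spec.summer_air_temp - amp * c_s

    n_days = years * DAYS_PER_YEAR
    dates = canonical_dates(spec.start_year, years)
    doy_cos = np.tile(cosine, years)
    seasonal = base + amp * doy_cos

    rho = 0.8
    sd_daily = 2.5 * np.sqrt(1 - rho ** 2)
    anom = np.zeros(n_days)
    if noise:
        eps = rng.normal(0.0, sd_daily, n_days)
        for i in range(1, n_days):
            anom[i] = rho * anom[i - 1] + eps[i]
    t_daily = seasonal + anom

    # expand to 3-hourly with a diurnal cycle peaking mid-afternoon
    hours = np.arange(0, 24, 3)
    diurnal = 3.0 * np.cos(2 * np.pi * (hours - 15.0) / 24.0)
    air = (t_daily[:, None] + diurnal[None, :]).ravel()
    times = (np.repeat(dates.values, 8)
             + np.tile((hours * 3600 * 1e9).astype("timedelta64[ns]"), n_days))

    n = n_days * 8
    if noise:
        wind = np.maximum(rng.gamma(4.0, spec.mean_wind / 4.0, n_days), 0.3)
        cloud_anom = np.clip(rng.beta(2.0, 2.0, n_days), 0.0, 1.0)
        cloud = np.clip(0.3 + 0.6 * cloud_anom + 0.15 * doy_cos * -1.0, 0.0, 1.0)
        press = 1013.0 + rng.normal(0.0, 8.0, n_days)
    else:
        wind = np.full(n_days, spec.mean_wind)
        cloud = np.full(n_days, spec.mean_cloud)
        press = np.full(n_days, 1013.0)
    direction = rng.uniform(0, 2 * np.pi, n_days) if noise else np.zeros(n_days)
    wind8 = np.repeat(wind, 8)
    return pd.DataFrame({
        "time": times,
        "air_temp": air,
        "pressure": np.repeat(press, 8),
        "dewpoint": air - 2.0,
        "cloud": np.repeat(cloud, 8),
        "wind_u": wind8 * np.repeat(np.cos(direction), 8),
        "wind_v": wind8 * np.repeat(np.sin(direction), 8),
    })


# ---------------------------------------------------------------------------
# inflow
# ---------------------------------------------------------------------------

def gen_inflow(spec: SyntheticLakeSpec, years: int, seed: int | None = None,
               *, noise: bool = True, conc_sigma: float = 0.12) -> pd.DataFrame:
    """Monthly per-inlet discharge and nutrient concentrations.

    Discharge is winter-high so the hydraulic residence time is about
    ``residence_winter_d`` in Oct-Apr and ``residence_summer_d`` in
    May-Sep; flow-weighted total N and P concentrations are set so the
    annual loads hit the spec's targets, with multiplicative lognormal
    month-to-month variation.  Total nutrients are partitioned into
    inorganic and particulate organic species (75% organic P, 90%
    organic N by default).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
    months = pd.period_range(f"{spec.start_year}-01", periods=years * 12, freq="M")
    mon_no = months.month.to_numpy()
    winter = np.isin(mon_no, WINTER_MONTHS)
    q_total_m3d = np.where(winter, spec.volume / spec.residence_winter_d,
                           spec.volume / spec.residence_summer_d)
    days_in_month = np.where(mon_no == 2, 28, np.where(np.isin(mon_no, (4, 6, 9, 11)), 30, 31))
    annual_volume = float((q_total_m3d * days_in_month)[:12].sum())

    tn_conc = spec.tn_load / annual_volume  # flow-weighted g/m^3
    tp_conc = spec.tp_load / annual_volume

    rows = []
    sigma = conc_sigma if noise else 0.0
    for i, share in enumerate(spec.inlet_shares[: spec.n_inlets]):
        q_inlet = q_total_m3d * share
        jitter_n = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, len(months)))
        jitter_p = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, len(months)))
        tn = tn_conc * jitter_n
        tp = tp_conc * jitter_p
        org_n = spec.org_frac_n * tn
        org_p = spec.org_frac_p * tp
        inorg_n = tn - org_n
        rows.append(pd.DataFrame({
            "time": months.to_timestamp(),
            "inlet": f"inlet{i + 1}",
            "discharge_m3s": q_inlet / 86400.0,
            "nh4": 0.3 * inorg_n,
            "no3": 0.7 * inorg_n,
            "po4": tp - org_p,
            "org_n": org_n,
            "org_p": org_p,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Sparse depth-pooled observations (long format).

    Columns: variable, day (simulation day index), time (ISO timestamp),
    sample_depth_m, value, error_fraction.
    """

    records: pd.DataFrame

    def __post_init__(self):
        req = {"variable", "day", "sample_depth_m", "value", "error_fraction"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        r = self.records
        if (r["value"] < 0).any():
            raise ValueError("observed values must be non-negative")
        ef = r["error_fraction"]
        if ((ef <= 0) | (ef >= 1)).any():
            raise ValueError("error fractions must be in (0, 1)")

    def for_variables(self, variables) -> pd.DataFrame:
        return self.records[self.records["variable"].isin(list(variables))]

    def __len__(self):
        return len(self.records)


def sampling_days(years: int, start_year: int = 1990, *, start_offset_days: int = 0):
    """Monitoring schedule: one sample per winter month (the 15th), two per
    summer month (the 8th and 22nd).  Returns (day_index, timestamp)."""
    dates = canonical_dates(start_year, years)
    sel = []
    for j, ts in enumerate(dates):
        ts = pd.Timestamp(ts)
        if ts.month in WINTER_MONTHS and ts.day == 15:
            sel.append(j)
        elif ts.month in SUMMER_MONTHS and ts.day in (8, 22):
            sel.append(j)
    idx = np.asarray(sel) + start_offset_days
    return idx, dates[sel]


def gen_observations(truth: RunResult, spec: SyntheticLakeSpec, seed: int,
                     *, variables=None, start_offset_days: int = 0,
                     start_year: int | None = None,
                     ice_temp: float = 0.1) -> ObservationSet:
    """Sample a truth run on the monitoring schedule with analytical noise.

    The pooled sampling depth is twice the Secchi-depth proxy (1.7 / K_d
    of the truth run), clipped to the 0.2-1.0 m band and to the lake
    depth.  Winter dates with an ice proxy (surface water <= ``ice_temp``
    degC) are skipped.  Noise is multiplicative lognormal with coefficient
    of variation equal to each variable's error fraction; temperature gets
    additive noise instead (its values cross zero).
    """
    rng = np.random.default_rng(seed)
    variables = list(ERROR_FRACTIONS) if variables is None else list(variables)
    years = int(np.ceil(truth.n_days / DAYS_PER_YEAR))
    sy = spec.start_year if start_year is None else start_year
    days, stamps = sampling_days(years, sy, start_offset_days=start_offset_days)
    keep = (days >= truth.day_index[0]) & (days <= truth.day_index[-1])
    days, stamps = days[keep], stamps[keep]
    pos = days - truth.day_index[0]

    kd_col = truth.column_mean("kd")[pos]
    secchi = 1.7 / np.maximum(kd_col, 1e-6)
    depth = np.clip(2.0 * secchi, 0.2, 1.0)
    depth = np.minimum(depth, truth.grid.max_depth)
    surf_temp = truth.layers["temp"][pos, -1]
    months = pd.DatetimeIndex(stamps).month
    open_water = ~(np.isin(months, WINTER_MONTHS) & (surf_temp <= ice_temp))

    rows = []
    for var in variables:
        ef = ERROR_FRACTIONS[var]
        pooled = np.array([
            truth.depth_pooled(var, d)[pi] for pi, d in zip(pos, depth)
        ])
        if var == "temp":
            noisy = pooled + rng.normal(0.0, ef * 5.0, len(days))
            noisy = np.maximum(noisy, 0.0)
        else:
            sig = np.sqrt(np.log1p(ef ** 2))
            noisy = pooled * np.exp(rng.normal(-0.5 * sig ** 2, sig, len(days)))
        rows.append(pd.DataFrame({
            "variable": var, "day": days, "time": stamps,
            "sample_depth_m": depth, "value": noisy,
            "error_fraction": ef, "open_water": open_water,
        }))
    df = pd.concat(rows, ignore_index=True)
    df = df[df["open_water"]].drop(columns="open_water").reset_index(drop=True)
    return ObservationSet(df)


# ---------------------------------------------------------------------------
# twin fixture
# ---------------------------------------------------------------------------

#: parameters perturbed (and recovered) in the twin experiment — one or
#: two sensitive parameters per process, each with a direct observational
#: signal in that process's target variables
TWIN_PARAMETERS = ["solar_gain", "rea_k0", "k_nit", "k_den_sed",
                   "k_diff", "dia_mu_max", "zoo_f_max", "pom_settling"]

TWIN_VARIABLES = {
    "physics": ["temp"],
    "oxygen": ["o2"],
    "nitrogen": ["no3", "nh4", "tn"],
    "phosphorus": ["po4", "tp"],
    "plankton": ["chl", "zoo_dm"],
    "particulates": ["pom_dm"],
}


@dataclass
class TwinFixture:
    """Everything needed for a parameter-recovery (twin) experiment."""

    spec: SyntheticLakeSpec
    grid: VerticalGrid
    forcing: ForcingBundle
    truth_params: ParameterSet
    start_params: ParameterSet
    observations: ObservationSet
    truth_run: RunResult
    years: int
    warmup_days: int
    dt: float


def make_twin_fixture(spec: SyntheticLakeSpec | None = None, *, seed: int = 42,
                      years: int = 2, n_layers: int = 1, dt: float = 1.0,
                      warmup_days: int = DAYS_PER_YEAR,
                      perturb_frac: float = 0.35) -> TwinFixture:
    """Deterministic twin-experiment bundle on a reduced synthetic lake.

    A truth run with the default parameters generates observations; the
    starting parameter set perturbs :data:`TWIN_PARAMETERS` to random
    points within ``+/- perturb_frac`` of truth (clipped to bounds).  The
    fully mixed (1-layer) configuration and a coarse step keep each
    objective evaluation cheap enough for population-based calibration.
    """
    spec = spec or SyntheticLakeSpec(seed=seed)
    from lakeshift.grid import DEFAULT_ZOOM

    hyps = gen_hypsograph(spec)
    grid = build_grid(hyps, n_layers=n_layers,
                      zoom=0.0 if n_layers == 1 else DEFAULT_ZOOM)
    meteo = gen_meteorology(spec, years, seed=seed)
    inflow = gen_inflow(spec, years, seed=seed + 1)
    from lakeshift.physics import meteo_to_daily

    forcing = build_forcing(meteo_to_daily(meteo), inflow)
    truth = default_parameters()
    model = LakeModel(grid, truth, dt=dt)
    truth_run = model.run(forcing, initial="turbid")
    obs = gen_observations(truth_run, spec, seed=seed + 2,
                           variables=[v for vs in TWIN_VARIABLES.values() for v in vs])
    obs = ObservationSet(obs.records[obs.records["day"] >= warmup_days].reset_index(drop=True))

    rng = np.random.default_rng(seed + 3)
    start_vals = []
    for name in TWIN_PARAMETERS:
        entry = truth.entry(name)
        lo = max(entry.lower, entry.value * (1 - perturb_frac))
        hi = min(entry.upper, entry.value * (1 + perturb_frac))
        v = entry.value
        while abs(v - entry.value) < 0.05 * entry.value:  # force a real perturbation
            v = rng.uniform(lo, hi)
        start_vals.append(v)
    start = truth.with_values(TWIN_PARAMETERS, start_vals)
    return TwinFixture(spec=spec, grid=grid, forcing=forcing, truth_params=truth,
                       start_params=start, observations=obs, truth_run=truth_run,
                       years=years, warmup_days=warmup_days, dt=dt)
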