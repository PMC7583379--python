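"""Model-observation comparison and stepwise autocalibration.

Fit statistics (R^2, MARE, RE, RMSE, percentage bias), depth-matched
extraction of simulated counterparts to pooled samples, a profiled
Gaussian log-likelihood objective, a seeded differential-evolution
optimizer (DE/rand/1/bin with reflection at bounds), between-step range
narrowing, and the stepwise procedure that calibrates parameter subsets
bottom-up (physics, then chemistry, then biology), carrying best values
and narrowed ranges forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lakeshift.model import RunResult
from lakeshift.parameters import ParameterSet
from lakeshift.synthetic import ObservationSet

__all__ = [
    "FitMetrics",
    "fit_metrics",
    "depth_matched_extract",
    "extract_pairs",
    "log_likelihood",
    "differential_evolution",
    "DEResult",
    "narrow_ranges",
    "CalibrationStep",
    "StepReport",
    "stepwise_calibrate",
]

log = logging.getLogger(__name__)

LL_CAP = 1e6  # objective cap for an exact fit (zero residual)


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit statistics between simulated and observed pairs.

    r2 — squared Pearson correlation; mare — mean absolute relative error
    over pairs with nonzero observation; re — total absolute error over
    total observation; rmse — root mean square error (variable units);
    bias — 100 * sum(S - O) / sum(O) (percent).
    """

    r2: float
    mare: float
    re: float
    rmse: float
    bias: float
    n: int


def fit_metrics(sim, obs) -> FitMetrics:
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValueError("sim and obs must be 1D arrays of equal length")
    n = sim.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    resid = sim - obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if np.std(sim) > 0 and np.std(obs) > 0:
        r2 = float(np.corrcoef(sim, obs)[0, 1] ** 2)
    else:
        r2 = 1.0 if np.allclose(sim, obs) else 0.0
    nz = obs != 0
    mare = float(np.mean(np.abs(resid[nz]) / np.abs(obs[nz]))) if nz.any() else np.nan
    denom = np.abs(obs).sum()
    re = float(np.abs(resid).sum() / denom) if denom > 0 else np.nan
    osum = obs.sum()
    bias = float(100.0 * resid.sum() / osum) if osum != 0 else np.nan
    return FitMetrics(r2=r2, mare=mare, re=re, rmse=rmse, bias=bias, n=n)


# ---------------------------------------------------------------------------
# depth matching
# ---------------------------------------------------------------------------

def depth_matched_extract(result: RunResult, variable: str, day: int,
                          sample_depth: float) -> float:
    """Simulated counterpart of one pooled sample: the volume-weighted mean
    over layers intersecting [surface, sample_depth] at the nearest daily
    output.  Raises KeyError for days outside the recorded window."""
    pos = int(day) - int(result.day_index[0])
    if pos < 0 or pos >= len(result.day_index):
        raise KeyError(f"day {day} outside recorded window")
    return float(result.depth_pooled(variable, sample_depth)[pos])


def extract_pairs(result: RunResult, obs: ObservationSet,
                  variables=None) -> pd.DataFrame:
    """(variable, day, sim, obs) pairs; observations outside the recorded
    window are skipped (count logged)."""
    rec = obs.records if variables is None else obs.for_variables(variables)
    lo, hi = int(result.day_index[0]), int(result.day_index[-1])
    inside = (rec["day"] >= lo) & (rec["day"] <= hi)
    skipped = int((~inside).sum())
    if skipped:
        log.debug("skipping %d observations outside the run window", skipped)
    rec = rec[inside]
    sims = np.array([
        result.depth_pooled(v, d)[int(t) - lo]
        for v, d, t in zip(rec["variable"], rec["sample_depth_m"], rec["day"])
    ]) if len(rec) else np.empty(0)
    return pd.DataFrame({"variable": rec["variable"].to_numpy(),
                         "day": rec["day"].to_numpy(),
                         "sim": sims, "obs": rec["value"].to_numpy()})


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def log_likelihood(pairs: pd.DataFrame, variables=None, *, cap: float = LL_CAP) -> float:
    """Profiled Gaussian log-likelihood, summed over variables.

    Per variable: -(n/2) ln(SSR/n) (the iid-Gaussian ln-likelihood with
    its variance maximized out, up to constants).  Higher is better; an
    exact fit is capped at ``cap``.
    """
    if variables is not None:
        pairs = pairs[pairs["variable"].isin(list(variables))]
    total = 0.0
    for _, grp in pairs.groupby("variable", sort=False):
        n = len(grp)
        if n < 2:
            continue
        ssr = float(np.sum((grp["sim"].to_numpy() - grp["obs"].to_numpy()) ** 2))
        total += cap if ssr <= 0 else -(n / 2.0) * np.log(ssr / n)
    return min(total, cap)


# ---------------------------------------------------------------------------
# differential evolution
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    best: np.ndarray
    best_objective: float
    population: np.ndarray
    objectives: np.ndarray
    history: np.ndarray  # best objective per generation
    n_evaluations: int


def differential_evolution(objective, bounds, *, pop_size: int | None = None,
                           f: float = 0.5, cr: float = 0.9,
                           generations: int = 50, seed: int = 0,
                           init: np.ndarray | None = None) -> DEResult:
    """Maximize ``objective`` with DE/rand/1/bin and reflection at bounds.

    Deterministic for a given seed.  Candidates with non-finite objective
    are rejected (treated as -inf and logged at debug level).
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (d, 2) array")
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(bounds)
    pop_size = max(4, 10 * d) if pop_size is None else int(pop_size)
    if pop_size < 4:
        raise ValueError("pop_size must be >= 4")
    rng = np.random.default_rng(seed)

    pop = lo + rng.random((pop_size, d)) * (hi - lo)
    if init is not None:
        pop[0] = np.clip(init, lo, hi)

    def safe_eval(x):
        val = objective(x)
        if not np.isfinite(val):
            log.debug("rejecting candidate with non-finite objective")
            return -np.inf
        return float(val)

    objs = np.array([safe_eval(x) for x in pop])
    n_eval = pop_size
    history = [objs.max()]

    span = hi - lo
    for _ in range(generations):
        for i in range(pop_size):
            r = rng.choice(pop_size, size=3, replace=False)
            while i in r:
                r = rng.choice(pop_size, size=3, replace=False)
            mutant = pop[r[0]] + f * (pop[r[1]] - pop[r[2]])
            # reflect into bounds
            over = mutant > hi
            under = mutant < lo
            mutant[over] = hi[over] - np.mod(mutant[over] - hi[over], span[over] + 1e-300)
            mutant[under] = lo[under] + np.mod(lo[under] - mutant[under], span[under] + 1e-300)
            mutant = np.clip(mutant, lo, hi)
            cross = rng.random(d) < cr
            cross[rng.integers(d)] = True
            trial = np.where(cross, mutant, pop[i])
            val = safe_eval(trial)
            n_eval += 1
            if val >= objs[i]:
                pop[i] = trial
                objs[i] = val
        history.append(objs.max())

    best_i = int(np.argmax(objs))
    return DEResult(best=pop[best_i].copy(), best_objective=float(objs[best_i]),
                    population=pop, objectives=objs,
                    history=np.asarray(history), n_evaluations=n_eval)


def narrow_ranges(population: np.ndarray, objectives: np.ndarray,
                  old_bounds: np.ndarray, *, keep_frac: float = 0.1,
                  expand_frac: float = 0.1) -> np.ndarray:
    """Bounds spanned by the top ``keep_frac`` of the population, expanded
    symmetrically by ``expand_frac`` of their span and clipped to the old
    bounds (so the new range is always a subset)."""
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    old_bounds = np.asarray(old_bounds, dtype=float)
    n_keep = max(1, int(np.ceil(keep_frac * len(population))))
    top = population[np.argsort(objectives)[::-1][:n_keep]]
    lo = top.min(axis=0)
    hi = top.max(axis=0)
    span = hi - lo
    degenerate = span <= 0
    span = np.where(degenerate, expand_frac * (old_bounds[:, 1] - old_bounds[:, 0]), span)
    lo = lo - expand_frac * span
    hi = hi + expand_frac * span
    return np.column_stack([np.maximum(lo, old_bounds[:, 0]),
                            np.minimum(hi, old_bounds[:, 1])])


# ---------------------------------------------------------------------------
# stepwise procedure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationStep:
    """One step of the stepwise procedure."""

    index: int
    name: str
    variables: tuple
    parameters: tuple
    budget: int = 250           # objective evaluations
    pop_size: int | None = None
    keep_frac: float = 0.1
    expand_frac: float = 0.1


@dataclass
class StepReport:
    step: CalibrationStep
    best_objective: float
    best_values: dict
    bounds_after: dict
    metrics: dict  # variable -> FitMetrics
    n_evaluations: int


def stepwise_calibrate(runner, params: ParameterSet, steps, obs: ObservationSet,
                       *, seed: int = 0):
    """Run the stepwise calibration.

    ``runner(params) -> RunResult`` executes the model.  Each step
    optimizes its parameter subset against its target variables with
    differential evolution, then narrows the subset's ranges from the
    final population and carries the best values forward.

    Returns (final ParameterSet, list of StepReport).
    """
    for st in steps:
        for name in st.parameters:
            if name not in params:
                raise KeyError(f"step {st.index} references unknown parameter {name!r}")
    current = params
    reports = []
    for k, st in enumerate(steps):
        names = list(st.parameters)
        bounds = current.bounds(names)

        def objective(vec, _names=names, _vars=st.variables):
            try:
                res = runner(current.with_values(_names, vec))
            except (FloatingPointError, ValueError):
                return -np.inf
            return log_likelihood(extract_pairs(res, obs, _vars))

        dim = len(names)
        pop = st.pop_size or max(5 * dim, 8)
        gens = max(1, st.budget // pop - 1)
        de = differential_evolution(objective, bounds, pop_size=pop,
                                    generations=gens, seed=seed + 1000 * k,
                                    init=current.values(names))
        new_bounds = narrow_ranges(de.population, de.objectives, bounds,
                                   keep_frac=st.keep_frac, expand_frac=st.expand_frac)
        current = current.with_bounds(names, new_bounds).with_values(names, de.best)
        res = runner(current)
        pairs = extract_pairs(res, obs)
        metrics = {}
        for v in st.variables:
            sub = pairs[pairs["variable"] == v]
            if len(sub) >= 2:
                metrics[v] = fit_metrics(sub["sim"].to_numpy(), sub["obs"].to_numpy())
        reports.append(StepReport(
            step=st, best_objective=de.best_objective,
            best_values=dict(zip(names, de.best)),
            bounds_after=dict(zip(names, map(tuple, new_bounds))),
            metrics=metrics, n_evaluations=de.n_evaluations))
        log.info("calibration step %d (%s): best objective %.3f",
                 st.index, st.name, de.best_objective)
    return current, reports


def twin_calibration_steps(budget: int = 1000) -> list[CalibrationStep]:
    """Reduced stepwise procedure for the parameter-recovery experiment:
    per-process subsets first, then a joint polish over all parameters and
    variables within narrowed ranges.  ``budget`` is the total number of
    objective evaluations across all steps."""
    shares = (0.10, 0.10, 0.20, 0.15, 0.30, 0.15)
    bs = [max(8, int(budget * w)) for w in shares]
    return [
        CalibrationStep(1, "physical processes", ("temp",),
                        ("solar_gain",), bs[0]),
        CalibrationStep(2, "oxygen dynamics", ("o2",),
                        ("rea_k0",), bs[1]),
        CalibrationStep(3, "nitrogen cycling", ("no3", "nh4", "tn"),
                        ("k_nit", "k_den_sed"), bs[2]),
        CalibrationStep(4, "phosphorus cycling", ("po4", "tp"),
                        ("k_diff",), bs[3]),
        CalibrationStep(5, "plankton dynamics", ("chl", "zoo_dm"),
                        ("dia_mu_max", "zoo_f_max"), bs[4]),
        CalibrationStep(6, "particulate matter", ("pom_dm",),
                        ("pom_settling",), bs[5]),
    ]


def run_twin_experiment(fixture, *, budget: int = 1000, seed: int = 0):
    """Parameter-recovery (twin) experiment on a synthetic fixture.

    Observations generated from a known truth parameterization are fitted
    starting from a perturbed parameter set; recovery quality is measured
    against the truth values and the truth objective.

    Returns a dict with the recovered ParameterSet, per-step reports, the
    truth and recovered objectives, and per-parameter relative errors.
    """
    from lakeshift.model import LakeModel
    from lakeshift.synthetic import TWIN_PARAMETERS

    grid, forcing, dt = fixture.grid, fixture.forcing, fixture.dt
    warm = fixture.warmup_days

    def runner(p):
        return LakeModel(grid, p, dt=dt).run(forcing, initial="turbid",
                                             record_start=warm)

    obs = fixture.observations
    all_vars = sorted(obs.records["variable"].unique())
    truth_obj = log_likelihood(extract_pairs(runner(fixture.truth_params), obs),
                               all_vars)
    steps = twin_calibration_steps(budget)
    recovered, reports = stepwise_calibrate(runner, fixture.start_params, steps,
                                            obs, seed=seed)
    final_obj = log_likelihood(extract_pairs(runner(recovered), obs), all_vars)
    rel_err = {
        name: abs(recovered[name] - fixture.truth_params[name])
        / abs(fixture.truth_params[name])
        for name in TWIN_PARAMETERS
    }
    return {
        "recovered": recovered,
        "reports": reports,
        "truth_objective": truth_obj,
        "final_objective": final_obj,
        "relative_errors": rel_err,
    }


def default_calibration_steps(budget: int = 250) -> list[CalibrationStep]:
    """The seven-step bottom-up procedure: physics, mineralization,
    N cycling, P interactions, plankton, macrophytes, then a combined
    nutrient-and-plankton polish."""
    return [
        CalibrationStep(1, "physical processes", ("temp",),
                        ("tau_temp_surface", "solar_gain"), budget),
        CalibrationStep(2, "mineralization", ("o2",),
                        ("k_min_dom", "k_min_sed"), budget),
        CalibrationStep(3, "denitrification and nitrification", ("no3", "nh4", "tn"),
                        ("k_nit", "k_den_sed", "k_nit_sed"), budget),
        CalibrationStep(4, "P in water column and sediment", ("po4", "tp"),
                        ("k_diff", "q_sorb_max", "k_sorp"), budget),
        CalibrationStep(5, "plankton seasonal trends", ("chl", "zoo_dm"),
                        ("dia_mu_max", "oth_mu_max", "zoo_f_max"), budget),
        CalibrationStep(6, "macrophyte dynamics", ("coverage",),
                        ("mac_p_max", "mac_h_light"), budget),
        CalibrationStep(7, "all nutrient and plankton dynamics",
                        ("no3", "nh4", "tn", "po4", "tp", "chl", "zoo_dm"),
                        ("k_nit", "k_den_sed", "k_diff", "dia_mu_max", "zoo_f_max"),
                        budget),
    ]
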