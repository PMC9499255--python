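"""Parameter estimation: SEM-weighted least squares, qualitative penalty
constraints, particle-swarm global optimisation, chi-square acceptance and
ensemble uncertainty bands.

The cost is V(q) = sum_i ((y_i - yhat_i)/SEM_i)^2 over all records of the
study datasets; a candidate parameter vector is accepted when its
*unpenalised* cost stays below the (1-alpha) quantile of chi^2 with one
degree of freedom per data point.  Eight qualitative constraints add a
large constant penalty each during optimisation but are excluded from the
chi-square verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .body import Anthropometry
from .fluxes import FluxBreakdown, observable_map, organ_uptake_fractions
from .meals_diets import DietSchedule
from .model_core import SimulationResult, simulate
from .parameters import BOUNDS, PARAM_NAMES, ParameterSet

__all__ = [
    "sem",
    "StudyDataset",
    "cost",
    "chi2_threshold",
    "chi2_test",
    "evaluate_penalties",
    "PENALTY_CONSTANT",
    "fit_global",
    "FitResult",
    "ensemble_bands",
]

#: constant added to the objective per violated qualitative constraint; it
#: must dominate any plausible chi-square cost
PENALTY_CONSTANT = 1.0e5

#: plausibility bands of post-absorptive organ glucose-uptake shares
#: (slack of 0.03 around the literature bands)
UPTAKE_BANDS = {
    "brain": (0.40, 0.50),
    "muscle": (0.15, 0.20),
    "liver": (0.10, 0.15),
    "kidney": (0.05, 0.10),
}
UPTAKE_SLACK = 0.03


def sem(sigma: float, n: float) -> float:
    """Standard error of the mean, sigma/sqrt(n)."""
    if n < 1:
        raise ValueError(f"replicate count n={n} must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return sigma / np.sqrt(n)


@dataclass
class StudyDataset:
    """Observable time series with SEM weights and protocol metadata.

    ``records`` columns: time_h, observable, value, sd, n, sem,
    is_calibration.  ``protocol`` is the meal schedule driving the
    simulation; ``t_span`` the simulated span in hours.
    """

    study_id: str
    population: str                 # "healthy" | "t2d"
    records: pd.DataFrame
    protocol: DietSchedule
    t_span: tuple[float, float]
    init: str = "basal"

    REQUIRED = ("time_h", "observable", "value", "sd", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset records missing columns: {sorted(missing)}")
        df = self.records.copy()
        if "sem" not in df.columns:
            df["sem"] = df["sd"] / np.sqrt(df["n"])
        if "is_calibration" not in df.columns:
            df["is_calibration"] = False
        t0, t1 = self.t_span
        if (df["time_h"] < t0 - 1e-9).any() or (df["time_h"] > t1 + 1e-9).any():
            raise ValueError("record times fall outside the protocol span")
        self.records = df

    @property
    def n_points(self) -> int:
        return len(self.records)

    def calibration_records(self) -> pd.DataFrame:
        return self.records[self.records["is_calibration"]]

    def validation_records(self) -> pd.DataFrame:
        return self.records[~self.records["is_calibration"]]

    def floor_sems(self, fraction: float = 0.05) -> "StudyDataset":
        """Floor each observable's SEMs at ``fraction`` of its dynamic range.

        Guards against single points with unrealistically small errors
        dominating the fit (the classical fix is replacing them with a mean
        SEM; a range-based floor achieves the same robustly).
        """
        df = self.records.copy()
        for obs, grp in df.groupby("observable"):
            rng = grp["value"].max() - grp["value"].min()
            floor = fraction * rng if rng > 0 else fraction * abs(grp["value"].mean())
            if floor > 0:
                df.loc[df["observable"] == obs, "sem"] = df.loc[
                    df["observable"] == obs, "sem"].clip(lower=floor)
        return StudyDataset(self.study_id, self.population, df, self.protocol,
                            self.t_span, self.init)

    # --- CSV round trip (tidy exchange format) -------------------------
    def to_csv(self, path, protocol_ref: str = "") -> None:
        df = self.records.copy()
        df.insert(0, "study", self.study_id)
        df.insert(1, "population", self.population)
        df.insert(2, "protocol_ref", protocol_ref)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol: DietSchedule,
                 t_span: tuple[float, float], init: str = "basal") -> "StudyDataset":
        df = pd.read_csv(path)
        study = str(df["study"].iloc[0]) if "study" in df else Path(str(path)).stem
        pop = str(df["population"].iloc[0]) if "population" in df else "healthy"
        keep = [c for c in df.columns
                if c in ("time_h", "observable", "value", "sd", "n", "sem",
                         "is_calibration")]
        return cls(study, pop, df[keep], protocol, t_span, init)


def _interp_observable(dataset: StudyDataset, sim: SimulationResult,
                       records: pd.DataFrame) -> np.ndarray:
    yhat = np.empty(len(records))
    for i, (_, row) in enumerate(records.iterrows()):
        series = observable_map(sim, row["observable"])
        yhat[i] = np.interp(row["time_h"], sim.t, series)
    return yhat


def cost(dataset: StudyDataset, sim: SimulationResult,
         records: pd.DataFrame | None = None) -> float:
    """SEM-weighted least-squares cost of a simulation against a dataset."""
    rec = dataset.records if records is None else records
    if (rec["sem"] <= 0).any():
        raise ValueError("all records used in the cost must have SEM > 0")
    yhat = _interp_observable(dataset, sim, rec)
    resid = (rec["value"].to_numpy() - yhat) / rec["sem"].to_numpy()
    return float(np.sum(resid**2))


def chi2_threshold(alpha: float, dof: int) -> float:
    """(1-alpha) quantile of the chi-square distribution with ``dof`` degrees
    of freedom (one per data point)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if dof < 1:
        raise ValueError(f"dof={dof} must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, dof))


def chi2_test(cost_value: float, dof: int, alpha: float = 0.05) -> bool:
    """True (pass) when the cost does not exceed the chi-square threshold."""
    return cost_value <= chi2_threshold(alpha, dof)


def evaluate_penalties(
    sim: SimulationResult,
    fluxes: FluxBreakdown | None = None,
    fed_window: tuple[float, float] | None = None,
    fast_window: tuple[float, float] | None = None,
    post_absorptive_window: tuple[float, float] | None = None,
) -> tuple[float, dict[str, bool]]:
    """Check the eight qualitative plausibility constraints on a simulation.

    Returns (penalty, report); the penalty is PENALTY_CONSTANT per violated
    constraint.  It is added to the optimisation objective but never enters
    a chi-square verdict.  Constraints 5, 7 and 8 need windows (a
    post-absorptive span, a fed-state span, the end of an extended fast);
    they are skipped (reported True) when the window is not supplied.
    """
    fx = fluxes or FluxBreakdown.from_simulation(sim)
    report: dict[str, bool] = {}

    flux_min = min(float(np.min(v)) for v in sim.fluxes.values())
    report["non_negative"] = (float(sim.states.min()) >= -1e-9
                              and flux_min >= -1e-9)
    report["insulin_below_3000"] = float(sim.state("plasma_insulin").max()) <= 3000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rgp_share = np.where(fx.egp > 1e-9, fx.rgp / fx.egp, 0.0)
    report["rgp_below_40pct"] = float(np.nanmax(rgp_share)) <= 0.40
    tot_cl = fx.insulin_clearance_liver + fx.insulin_clearance_periphery
    with np.errstate(divide="ignore", invalid="ignore"):
        liver_share = np.where(tot_cl > 1e-12, fx.insulin_clearance_liver / tot_cl, 1.0)
    report["liver_insulin_clearance_above_40pct"] = float(np.min(liver_share)) >= 0.40
    if post_absorptive_window is not None:
        shares = organ_uptake_fractions(fx, post_absorptive_window)
        report["uptake_proportions"] = all(
            lo - UPTAKE_SLACK <= shares[o] <= hi + UPTAKE_SLACK
            for o, (lo, hi) in UPTAKE_BANDS.items())
    else:
        report["uptake_proportions"] = True
    gng_share = np.where(fx.egp > 1e-9, fx.gng / fx.egp, 0.0)
    report["gng_below_100pct"] = float(np.nanmax(gng_share)) <= 1.0 + 1e-9
    if fed_window is not None:
        gly = sim.state("hepatic_glycogen")[sim.window_mask(fed_window)]
        report["fed_glycogen_window"] = bool((gly.min() >= 200.0) & (gly.max() <= 350.0))
    else:
        report["fed_glycogen_window"] = True
    if fast_window is not None:
        gly = sim.state("hepatic_glycogen")[sim.window_mask(fast_window)]
        report["unfed_glycogen_below_100"] = bool(gly.max() < 100.0)
    else:
        report["unfed_glycogen_below_100"] = True

    penalty = PENALTY_CONSTANT * sum(not ok for ok in report.values())
    return penalty, report


@dataclass
class FitResult:
    """Outcome of a global fit: accepted ensemble and diagnostics."""

    param_names: tuple[str, ...]
    best_x: np.ndarray
    best_cost: float                # unpenalised
    best_penalty: float
    ensemble: np.ndarray            # (n_members, n_params), chi2-accepted
    ensemble_costs: np.ndarray
    per_study_costs: dict[str, float]
    dof: int
    threshold: float
    chi2_pass: bool
    penalty_report: dict[str, bool]
    n_evaluations: int
    seed: int
    base: ParameterSet

    @property
    def param_minmax(self) -> dict[str, tuple[float, float]]:
        """Per-parameter min/max across the accepted ensemble."""
        if len(self.ensemble) == 0:
            return {}
        return {name: (float(self.ensemble[:, i].min()),
                       float(self.ensemble[:, i].max()))
                for i, name in enumerate(self.param_names)}

    def parameter_set(self, x: np.ndarray | None = None) -> ParameterSet:
        x = self.best_x if x is None else x
        over = {n: float(v) for n, v in zip(self.param_names, x)
                if n in PARAM_NAMES}
        ps = self.base.with_general(**over)
        pers = {n: float(v) for n, v in zip(self.param_names, x)
                if n not in PARAM_NAMES}
        return ps.with_personal(**pers) if pers else ps

    def to_json(self, path) -> None:
        payload = {
            "param_names": list(self.param_names),
            "best_x": self.best_x.tolist(),
            "best_cost": self.best_cost,
            "dof": self.dof,
            "threshold": self.threshold,
            "chi2_pass": self.chi2_pass,
            "penalty_report": self.penalty_report,
            "n_ensemble": int(len(self.ensemble)),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


PRESETS = {
    # full-scale settings of the published estimation procedure
    "full": {"swarm_size": 2000, "max_iters": 400},
    # small smoke preset so the whole stack runs in CI minutes
    "smoke": {"swarm_size": 24, "max_iters": 30},
}

_PERSONAL_BOUNDS = {
    "basal_glucose": (3.0, 15.0),
    "basal_insulin": (5.0, 500.0),
    "insulin_production": (0.25, 4.0),
    "insulin_clearance": (0.25, 4.0),
    "insulin_resistance": (0.25, 4.0),
}


def _particle_swarm(objective, lo, hi, swarm_size, max_iters, seed,
                    tol=1e-6, stall_iters=20, archive_cb=None):
    """Global-best particle swarm with reflecting bounds; deterministic
    under a fixed seed.  Stops on max_iters or ``stall_iters`` iterations
    without an improvement larger than ``tol``."""
    rng = np.random.default_rng(seed)
    dim = len(lo)
    span = hi - lo
    x = lo + rng.random((swarm_size, dim)) * span
    v = np.zeros_like(x)
    pbest_x = x.copy()
    pbest_f = np.array([objective(xi) for xi in x])
    if archive_cb is not None:
        for xi, fi in zip(x, pbest_f):
            archive_cb(xi, fi)
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), pbest_f[g]
    n_eval = swarm_size
    w, c1, c2 = 0.729, 1.49445, 1.49445
    vmax = 0.25 * span
    stall = 0
    for _ in range(max_iters):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        v = w * v + c1 * r1 * (pbest_x - x) + c2 * r2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = x + v
        # reflect at the bounds
        below, above = x < lo, x > hi
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
        x = np.clip(x, lo, hi)
        f = np.array([objective(xi) for xi in x])
        n_eval += swarm_size
        if archive_cb is not None:
            for xi, fi in zip(x, f):
                archive_cb(xi, fi)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f - tol:
            gbest_x, gbest_f = pbest_x[g].copy(), pbest_f[g]
            stall = 0
        else:
            stall += 1
            if stall >= stall_iters:
                break
    return gbest_x, gbest_f, n_eval


def fit_global(
    datasets: list[StudyDataset],
    population: str = "healthy",
    free_params: tuple[str, ...] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    preset: str = "smoke",
    swarm_size: int | None = None,
    max_iters: int | None = None,
    tol: float = 1e-6,
    stall_iters: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    anthropometry: Anthropometry | None = None,
    base: ParameterSet | None = None,
    grid_minutes: float = 2.0,
    penalty_windows: dict[str, tuple[float, float]] | None = None,
    polish: bool = True,
    max_ensemble: int = 500,
) -> FitResult:
    """Fit free parameters to the datasets by particle-swarm optimisation.

    By default all 57 general parameters plus the 5 personal parameters are
    free (the full training problem); passing ``free_params`` restricts the
    search, with the remaining parameters held at the base values.  Every
    evaluated vector whose unpenalised cost passes the chi-square test is
    archived as the accepted ensemble.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if any(d.population != population for d in datasets):
        raise ValueError("all datasets must share the requested population tag")
    base = base or ParameterSet.for_variant(population)
    anthropometry = anthropometry or Anthropometry(diabetic=(population == "t2d"))
    free = tuple(free_params) if free_params else (
        PARAM_NAMES + tuple(_PERSONAL_BOUNDS))
    all_bounds = dict(BOUNDS) | _PERSONAL_BOUNDS | (bounds or {})
    for name, (lo, hi) in all_bounds.items():
        if lo > hi:
            raise ValueError(f"bounds for {name} have lower > upper")
    lo = np.array([all_bounds[n][0] for n in free])
    hi = np.array([all_bounds[n][1] for n in free])

    cfg = PRESETS[preset].copy()
    if swarm_size is not None:
        cfg["swarm_size"] = swarm_size
    if max_iters is not None:
        cfg["max_iters"] = max_iters

    dof = sum(d.n_points for d in datasets)
    threshold = chi2_threshold(alpha, dof)
    pw = penalty_windows or {}

    def build_params(x: np.ndarray) -> ParameterSet:
        gen = {n: float(v) for n, v in zip(free, x) if n in PARAM_NAMES}
        pers = {n: float(v) for n, v in zip(free, x) if n in _PERSONAL_BOUNDS}
        ps = base.with_general(**gen) if gen else base
        return ps.with_personal(**pers) if pers else ps

    def run(x: np.ndarray):
        ps = build_params(x)
        total, per_study, penalty = 0.0, {}, 0.0
        for d in datasets:
            sim = simulate(ps, anthropometry, d.protocol, d.t_span,
                           init=d.init, grid_minutes=grid_minutes)
            c = cost(d, sim)
            per_study[d.study_id] = c
            total += c
            pen, _ = evaluate_penalties(
                sim,
                fed_window=pw.get("fed"), fast_window=pw.get("fast"),
                post_absorptive_window=pw.get("post_absorptive"))
            penalty += pen
        return total, per_study, penalty

    ensemble: list[np.ndarray] = []
    ensemble_costs: list[float] = []
    cache: dict[bytes, float] = {}

    def objective(x: np.ndarray) -> float:
        key = x.tobytes()
        if key in cache:
            return cache[key]
        try:
            total, _, penalty = run(x)
        except Exception:
            total, penalty = 1e12, 0.0
        if total <= threshold and len(ensemble) < max_ensemble:
            ensemble.append(x.copy())
            ensemble_costs.append(total)
        val = total + penalty
        cache[key] = val
        return val

    gx, gf, n_eval = _particle_swarm(
        objective, lo, hi, cfg["swarm_size"], cfg["max_iters"], seed,
        tol=tol, stall_iters=stall_iters, archive_cb=None)

    if polish:
        res = optimize.minimize(
            objective, gx, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 80 * len(free), "xatol": 1e-6, "fatol": tol})
        n_eval += res.nfev
        if res.fun < gf:
            gx, gf = np.clip(res.x, lo, hi), res.fun

    total, per_study, penalty = run(gx)
    ps = build_params(gx)
    sim0 = simulate(ps, anthropometry, datasets[0].protocol, datasets[0].t_span,
                    init=datasets[0].init, grid_minutes=grid_minutes)
    _, report = evaluate_penalties(
        sim0, fed_window=pw.get("fed"), fast_window=pw.get("fast"),
        post_absorptive_window=pw.get("post_absorptive"))

    return FitResult(
        param_names=free,
        best_x=gx,
        best_cost=total,
        best_penalty=penalty,
        ensemble=np.array(ensemble) if ensemble else np.empty((0, len(free))),
        ensemble_costs=np.array(ensemble_costs),
        per_study_costs=per_study,
        dof=dof,
        threshold=threshold,
        chi2_pass=chi2_test(total, dof, alpha),
        penalty_report=report,
        n_evaluations=n_eval,
        seed=seed,
        base=base,
    )


def ensemble_bands(
    fit: FitResult,
    protocol: DietSchedule,
    t_span: tuple[float, float],
    observables: tuple[str, ...] = ("plasma_glucose", "plasma_insulin"),
    anthropometry: Anthropometry | None = None,
    grid_minutes: float = 2.0,
    init: str = "basal",
) -> dict[str, dict[str, np.ndarray]]:
    """Pointwise min/max envelope over the accepted ensemble.

    Returns {observable: {"t", "lo", "hi", "best"}}; the model uncertainty
    of a prediction is the spread between ensemble members.
    """
    if len(fit.ensemble) == 0:
        raise ValueError("ensemble is empty; no uncertainty band available")
    anthropometry = anthropometry or Anthropometry()
    sims = [
        simulate(fit.parameter_set(x), anthropometry, protocol, t_span,
                 init=init, grid_minutes=grid_minutes)
        for x in fit.ensemble
    ]
    best = simulate(fit.parameter_set(), anthropometry, protocol, t_span,
                    init=init, grid_minutes=grid_minutes)
    out: dict[str, dict[str, np.ndarray]] = {}
    for kind in observables:
        stack = np.vstack([observable_map(s, kind) for s in sims])
        out[kind] = {
            "t": sims[0].t,
            "lo": stack.min(axis=0),
            "hi": stack.max(axis=0),
            "best": observable_map(best, kind),
        }
    return out
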