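"""Three-category personalisation of the population model into a twin.

Category i  -- anthropometry: sex/weight/height scale the blood and organ
volumes (see :mod:`glucotwin.body`); the diabetes flag selects the healthy
or T2D general-parameter set.
Category ii -- basal calibration: the subject's basal glucose/insulin set
the two basal personal parameters, and a plausible five-day lead-in diet is
searched so the simulated state at study start matches the supplied
baseline observations.
Category iii -- data calibration: the three modifiers (insulin production,
clearance, resistance) are fitted to designated calibration points, with
all 57 general parameters held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .body import Anthropometry, BloodVolumes, blood_volumes
from .estimation import StudyDataset, cost
from .meals_diets import DietSchedule, build_diet
from .model_core import simulate
from .parameters import ParameterSet, PersonalParameters

__all__ = [
    "Anthropometry",
    "BloodVolumes",
    "blood_volumes",
    "calibrate_basal",
    "fit_person_params",
]

# lead-in diet search space: 3 meals/day for 5 days, meal size 200-1000 kcal
_LEAD_IN_DAYS = 5
_MEAL_KCAL_BOUNDS = (200.0, 1000.0)


def _lead_in(daily_kcal: float) -> DietSchedule:
    return build_diet("SFM", daily_kcal=daily_kcal, days=_LEAD_IN_DAYS)


def calibrate_basal(
    params: ParameterSet,
    anthropometry: Anthropometry,
    initial_observations: dict[str, tuple[float, float | None]],
    grid_minutes: float = 5.0,
) -> tuple[ParameterSet, DietSchedule]:
    """Category-ii calibration: basal parameters plus a lead-in diet.

    ``initial_observations`` maps observable kind to (value, sem); sem may
    be None, in which case 5% of the value is used.  Basal glucose/insulin
    observations set the corresponding personal parameters directly; when a
    baseline hepatic glycogen is supplied, the daily energy of a five-day
    standard lead-in diet is tuned so the simulated store at study start
    matches it within its SEM.
    """
    if not initial_observations:
        raise ValueError("at least one baseline observation is required")
    over = {}
    if "plasma_glucose" in initial_observations:
        over["basal_glucose"] = initial_observations["plasma_glucose"][0]
    if "plasma_insulin" in initial_observations:
        over["basal_insulin"] = initial_observations["plasma_insulin"][0]
    params = params.with_personal(**over) if over else params

    target = initial_observations.get("hepatic_glycogen")
    if target is None:
        return params, _lead_in(2000.0)

    value, semv = target
    tol = semv if semv else 0.05 * value
    lo = 3 * _MEAL_KCAL_BOUNDS[0]
    hi = 3 * _MEAL_KCAL_BOUNDS[1]

    def end_glycogen(daily_kcal: float) -> float:
        sched = _lead_in(daily_kcal)
        sim = simulate(params, anthropometry, sched,
                       (0.0, 24.0 * _LEAD_IN_DAYS), init="basal",
                       grid_minutes=grid_minutes)
        return float(sim.state("hepatic_glycogen")[-1])

    res = optimize.minimize_scalar(
        lambda k: (end_glycogen(k) - value) ** 2,
        bounds=(lo, hi), method="bounded",
        options={"xatol": 10.0})
    best_kcal = float(res.x)
    resid = abs(end_glycogen(best_kcal) - value)
    if resid > tol:
        raise ValueError(
            f"no admissible lead-in diet: best daily energy {best_kcal:.0f} kcal "
            f"leaves hepatic glycogen {resid:.0f} mmol/L from the baseline "
            f"(tolerance {tol:.0f})")
    return params, _lead_in(best_kcal)


def fit_person_params(
    params: ParameterSet,
    calibration_data: StudyDataset,
    anthropometry: Anthropometry | None = None,
    grid_minutes: float = 2.0,
) -> PersonalParameters:
    """Category-iii calibration: fit the three modifiers to calibration data.

    Minimises the SEM-weighted least-squares cost on the designated
    calibration records only, searching insulin production, clearance and
    resistance in log space; the 57 general parameters and the basal
    personal parameters are untouched.
    """
    recs = calibration_data.calibration_records()
    if len(recs) == 0:
        raise ValueError("calibration dataset designates no calibration points")
    anthropometry = anthropometry or Anthropometry(
        diabetic=(calibration_data.population == "t2d"))

    values = recs["value"].to_numpy()
    sems = recs["sem"].to_numpy()
    times = recs["time_h"].to_numpy()
    kinds = recs["observable"].to_numpy()

    def residuals(logmods: np.ndarray) -> np.ndarray:
        prod, clear, resist = np.exp(logmods)
        ps = params.with_personal(
            insulin_production=prod, insulin_clearance=clear,
            insulin_resistance=resist)
        try:
            sim = simulate(ps, anthropometry, calibration_data.protocol,
                           calibration_data.t_span, init=calibration_data.init,
                           grid_minutes=grid_minutes)
        except Exception:
            return np.full(len(values), 1e6)
        from .fluxes import observable_map
        yhat = np.array([
            np.interp(t, sim.t, observable_map(sim, k))
            for t, k in zip(times, kinds)])
        return (values - yhat) / sems

    res = optimize.least_squares(
        residuals, np.zeros(3), method="trf",
        bounds=(np.log(0.2) * np.ones(3), np.log(5.0) * np.ones(3)),
        diff_step=1e-3, xtol=1e-8, ftol=1e-8)
    if not res.success and not np.all(np.isfinite(res.x)):
        raise RuntimeError("personal-parameter optimisation failed")
    prod, clear, resist = np.exp(res.x)
    return PersonalParameters(
        basal_glucose=params.personal.basal_glucose,
        basal_insulin=params.personal.basal_insulin,
        insulin_production=float(prod),
        insulin_clearance=float(clear),
        insulin_resistance=float(resist),
    )
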