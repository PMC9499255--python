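"""Pre-built experimental protocols: mixed meals, OGTT, multi-day fasts,
the protein-tolerance-test/fast design, and the three-week diet comparison.

Every summary number is recomputed from the returned trajectory; no value
is detached from the simulation that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .body import Anthropometry
from .fluxes import FluxBreakdown, gng_fraction
from .meals_diets import DietSchedule, MealEvent, build_diet, meal_from_energy
from .model_core import DigitalTwin, SimulationResult

__all__ = [
    "ProtocolResult",
    "default_optt",
    "run_optt_fast_optt",
    "run_fast",
    "run_diet_comparison",
    "standard_week",
    "diet_switch_schedule",
    "PROTOCOL_PRESETS",
]

#: peak plasma-glucose rise (mmol/L) below which a fed-state bolus response
#: is called negligible
NOTICEABLE_RISE = 0.5


@dataclass
class ProtocolResult:
    """Simulation plus protocol-specific summary numbers."""

    sim: SimulationResult
    summaries: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.summaries[key]


def default_optt(start_h: float = 0.0) -> MealEvent:
    """The oral protein tolerance test bolus: 132.5 kcal, 25.55 g protein,
    2.6 g carbohydrate (fat completed from the energy closure)."""
    return meal_from_energy(132.5, carb_g=2.6, protein_g=25.55, start_h=start_h)


def standard_week(days: int = 7, daily_kcal: float = 2000.0) -> DietSchedule:
    """Standardised lead-in diet: three ~667 kcal meals/day at the default
    45/27/27 energy split."""
    return build_diet("SFM", daily_kcal=daily_kcal, days=days)


def _rise_and_sustain(sim: SimulationResult, bolus_h: float,
                      peak_window_h: float = 2.0,
                      sustain_window_h: float = 6.0) -> tuple[float, float]:
    """Peak rise above the pre-bolus level within ``peak_window_h`` and the
    longest contiguous time (h) the glucose stays above that level."""
    G = sim.state("plasma_glucose")
    t = sim.t
    pre = float(np.interp(bolus_h - 0.05, t, G))
    mask_peak = (t >= bolus_h) & (t <= bolus_h + peak_window_h)
    rise = float(G[mask_peak].max() - pre)
    mask_sus = (t >= bolus_h) & (t <= bolus_h + sustain_window_h)
    above = G[mask_sus] > pre
    longest = run = 0
    dt = float(t[1] - t[0])
    for flag in above:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return rise, longest * dt


def run_optt_fast_optt(
    twin: DigitalTwin,
    optt: MealEvent | None = None,
    fast_h: float = 48.0,
    lead_in_days: int = 3,
    grid_minutes: float = 1.0,
) -> ProtocolResult:
    """Protein bolus before and after a long fast.

    The twin eats the standardised diet for ``lead_in_days`` days (dinner at
    19:00); the first bolus is taken at 23:00 on the last fed day, a
    ``fast_h``-hour fast follows, and the second, identical bolus is taken
    at its end.  Summaries: the fed and post-fast glucose rises, how long
    the post-fast excursion stays above the pre-bolus level, and the
    glucose decline over the fast.
    """
    optt = optt if optt is not None else default_optt()
    fed_bolus_h = 24.0 * (lead_in_days - 1) + 23.0
    fast_bolus_h = fed_bolus_h + fast_h
    lead = standard_week(days=lead_in_days)
    meals = lead.meals + (
        MealEvent(fed_bolus_h, optt.carb_g, optt.protein_g, optt.fat_g,
                  optt.duration_min),
        MealEvent(fast_bolus_h, optt.carb_g, optt.protein_g, optt.fat_g,
                  optt.duration_min),
    )
    horizon = fast_bolus_h / 24.0 + 8.0 / 24.0
    sched = DietSchedule(meals=meals, horizon_days=horizon)
    sim = twin.simulate(sched, (0.0, fast_bolus_h + 8.0),
                        grid_minutes=grid_minutes)

    G = sim.state("plasma_glucose")
    t = sim.t
    fed_rise, fed_sustained = _rise_and_sustain(sim, fed_bolus_h)
    fast_rise, fast_sustained = _rise_and_sustain(sim, fast_bolus_h)
    g_fast_start = float(np.interp(fed_bolus_h + 1.0, t, G))
    g_fast_end = float(np.interp(fast_bolus_h - 0.05, t, G))
    gly_end = float(np.interp(fast_bolus_h - 0.05, t, sim.state("hepatic_glycogen")))

    return ProtocolResult(sim=sim, summaries={
        "fed_optt_rise_mM": fed_rise,
        "fed_optt_sustained_h": fed_sustained,
        "fed_response_noticeable": float(fed_rise >= NOTICEABLE_RISE),
        "postfast_optt_rise_mM": fast_rise,
        "postfast_optt_sustained_h": fast_sustained,
        "fast_glucose_start_mM": g_fast_start,
        "fast_glucose_end_mM": g_fast_end,
        "fast_glucose_drop_mM": g_fast_start - g_fast_end,
        "fast_end_glycogen_mM": gly_end,
        "fed_bolus_h": fed_bolus_h,
        "fast_bolus_h": fast_bolus_h,
    })


def run_fast(twin: DigitalTwin, hours: float,
             grid_minutes: float = 1.0) -> ProtocolResult:
    """A pure fast from the fed basal state.

    Fasts beyond 72 h are outside the range the model was developed for and
    trigger a warning.
    """
    if hours > 72.0:
        warnings.warn(
            f"a {hours:.0f} h fast exceeds the supported 72 h range; "
            "interpret results with care", stacklevel=2)
    sim = twin.simulate(None, (0.0, hours), grid_minutes=grid_minutes)
    fx = FluxBreakdown.from_simulation(sim)
    G = sim.state("plasma_glucose")
    gly = sim.state("hepatic_glycogen")
    summaries = {
        "glucose_start_mM": float(G[0]),
        "glucose_end_mM": float(G[-1]),
        "glycogen_start_mM": float(gly[0]),
        "glycogen_end_mM": float(gly[-1]),
        "gng_fraction_first_6h": gng_fraction(fx, (0.0, 6.0)),
        "gng_fraction_last_6h": gng_fraction(fx, (hours - 6.0, hours)),
    }
    return ProtocolResult(sim=sim, summaries=summaries)


def diet_switch_schedule(scheme: str, daily_kcal: float = 2000.0,
                         weeks: int = 3, duration_min: float = 15.0) -> DietSchedule:
    """Three-week switch protocol: week 1 standardised diet, then the named
    scheme from week 2 on."""
    std = standard_week(days=7, daily_kcal=daily_kcal)
    target = build_diet(scheme, daily_kcal=daily_kcal, days=7 * (weeks - 1),
                        duration_min=duration_min).shifted(7 * 24.0)
    return DietSchedule(meals=std.meals + target.meals, scheme=scheme,
                        horizon_days=7.0 * weeks)


_DIET_SUMMARY_VARS = ("plasma_glucose", "plasma_insulin", "hepatic_glycogen")


def run_diet_comparison(
    twin: DigitalTwin,
    schedules: dict[str, DietSchedule],
    grid_minutes: float = 2.0,
) -> dict[str, ProtocolResult]:
    """Simulate three-week diet-switch schedules and summarise the analysis
    week (the second week after the switch, i.e. protocol days 14-21).

    Each schedule must already contain the standard first week and the diet
    switch (see :func:`diet_switch_schedule`) and span at least three
    weeks.  Summaries are the analysis-week means of plasma glucose,
    insulin, hepatic glycogen, gluconeogenesis and EGP.
    """
    results: dict[str, ProtocolResult] = {}
    for name, sched in schedules.items():
        if sched.horizon_days < 21.0 - 1e-9:
            raise ValueError(
                f"schedule {name!r} spans {sched.horizon_days:.0f} days; the "
                "diet-comparison protocol needs at least three weeks")
        sim = twin.simulate(sched, (0.0, sched.horizon_days * 24.0),
                            grid_minutes=grid_minutes)
        mask = (sim.t >= 14 * 24.0) & (sim.t < 21 * 24.0)
        summaries = {
            "mean_glucose_mM": float(sim.state("plasma_glucose")[mask].mean()),
            "mean_insulin_pM": float(sim.state("plasma_insulin")[mask].mean()),
            "mean_glycogen_mM": float(sim.state("hepatic_glycogen")[mask].mean()),
            "mean_gng_umol_kg_min": float(sim.fluxes["gng_total"][mask].mean()),
            "mean_egp_umol_kg_min": float(sim.fluxes["egp"][mask].mean()),
            "weekly_kcal": sum(
                m.kcal for m in sched.meals if 14 * 24.0 <= m.start_h < 21 * 24.0),
        }
        results[name] = ProtocolResult(sim=sim, summaries=summaries)
    return results


#: protocol presets mirroring the designs of the studies the model targets
PROTOCOL_PRESETS: dict[str, dict] = {
    # mixed meal (87 g carbohydrate / 23 g protein) at t = 1 h
    "mixed_meal": {
        "schedule": DietSchedule(
            meals=(MealEvent(1.0, carb_g=87.0, protein_g=23.0, fat_g=20.0),),
            horizon_days=0.5),
        "t_span": (0.0, 10.0),
    },
    # fast after a standard meal taken 4 h before the observation window
    "meal_then_fast": {
        "schedule": DietSchedule(
            meals=(MealEvent(0.0, carb_g=98.2, protein_g=26.0, fat_g=20.0),),
            horizon_days=1.2),
        "t_span": (0.0, 27.0),
        "window": (4.0, 27.0),
    },
    # 48 h fast then an OGTT of 1 g carbohydrate per kg body weight
    "fast_then_ogtt": {
        "t_span": (0.0, 60.0),
        "ogtt_h": 51.5,
        "carb_g_per_kg": 1.0,
    },
    # protein bolus before/after a 48 h fast
    "optt_fast_optt": {
        "fast_h": 48.0,
        "optt_kcal": 132.5, "optt_protein_g": 25.55, "optt_carb_g": 2.6,
    },
}


def fast_then_ogtt_schedule(anthropometry: Anthropometry,
                            ogtt_h: float = 51.5,
                            carb_g_per_kg: float = 1.0) -> DietSchedule:
    """48 h fast (preceded by overnight fast) followed by a weight-scaled
    glucose bolus."""
    grams = carb_g_per_kg * anthropometry.weight_kg
    return DietSchedule(
        meals=(MealEvent(ogtt_h, carb_g=grams),), horizon_days=60.0 / 24.0)
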