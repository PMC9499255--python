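"""Meal events, named diet schedules and the model input signal u(t).

Meals are square ingestion pulses: a meal of C grams of carbohydrate eaten
over D minutes contributes a constant C/D g/min to the carbohydrate input
for D minutes, so the integral of the input always equals the grams eaten.
Energy bookkeeping uses Atwater factors (4/4/9 kcal per g of
carbohydrate/protein/fat).  Ingested fat is tracked in the energy ledger
only; it has no metabolic dynamics in the model.

Named schemes
-------------
IF     two meals/day (12:00, 20:00)
SFM    three smaller meals/day (08:00, 13:00, 19:00)
5:2    five normal days (3 meals) + two restricted days (2 meals); the
       default 2560/600 kcal split gives a 2000 kcal/day weekly mean
HCLF   three meals/day at a 60/25/15 carb/protein/fat energy split
LCHF   three meals/day with half the HCLF carbohydrate share (30%),
       protein kept at 25%, the remainder (45%) moved to fat
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATWATER",
    "MealEvent",
    "DietSchedule",
    "ModelInput",
    "meal_from_energy",
    "build_diet",
    "to_input_signal",
    "SCHEMES",
]

ATWATER = {"carb": 4.0, "protein": 4.0, "fat": 9.0}

#: default energy split of the isocaloric schemes (normalised before use;
#: the printed 45/27/27 split sums to 99%)
STANDARD_SPLIT = (45.0, 27.0, 27.0)

SCHEMES = ("IF", "5:2", "SFM", "HCLF", "LCHF", "custom")


@dataclass(frozen=True)
class MealEvent:
    """A single timed meal: start (h), duration (min) and macronutrients (g)."""

    start_h: float
    carb_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    duration_min: float = 15.0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("meal duration must be positive")
        for name in ("carb_g", "protein_g", "fat_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def kcal(self) -> float:
        return (
            ATWATER["carb"] * self.carb_g
            + ATWATER["protein"] * self.protein_g
            + ATWATER["fat"] * self.fat_g
        )

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_min / 60.0


def meal_from_energy(
    kcal: float,
    carb_g: float,
    protein_g: float,
    start_h: float = 0.0,
    duration_min: float = 15.0,
) -> MealEvent:
    """Complete a meal's fat content from its total energy (Atwater closure)."""
    fat_kcal = kcal - ATWATER["carb"] * carb_g - ATWATER["protein"] * protein_g
    if fat_kcal < -1.0:  # 1 kcal tolerance on the closure
        raise ValueError(
            f"{kcal} kcal is below the energy of {carb_g} g carbohydrate + "
            f"{protein_g} g protein alone"
        )
    fat_g = max(fat_kcal, 0.0) / ATWATER["fat"]
    return MealEvent(
        start_h=start_h, carb_g=carb_g, protein_g=protein_g, fat_g=fat_g,
        duration_min=duration_min,
    )


@dataclass(frozen=True)
class DietSchedule:
    """Ordered, non-overlapping meal events over a horizon of days."""

    meals: tuple[MealEvent, ...]
    scheme: str = "custom"
    horizon_days: float = 1.0

    def __post_init__(self) -> None:
        meals = tuple(sorted(self.meals, key=lambda m: m.start_h))
        object.__setattr__(self, "meals", meals)
        for a, b in zip(meals, meals[1:]):
            if b.start_h < a.end_h - 1e-9:
                raise ValueError(
                    f"overlapping meals at {a.start_h} h and {b.start_h} h"
                )

    @property
    def total_kcal(self) -> float:
        return sum(m.kcal for m in self.meals)

    @property
    def mean_daily_kcal(self) -> float:
        return self.total_kcal / self.horizon_days

    def shifted(self, offset_h: float) -> "DietSchedule":
        return DietSchedule(
            meals=tuple(
                MealEvent(m.start_h + offset_h, m.carb_g, m.protein_g, m.fat_g, m.duration_min)
                for m in self.meals
            ),
            scheme=self.scheme,
            horizon_days=self.horizon_days,
        )

    def concat(self, other: "DietSchedule") -> "DietSchedule":
        """Append ``other`` (whose times are absolute) after this schedule."""
        return DietSchedule(
            meals=self.meals + other.meals,
            scheme="custom",
            horizon_days=self.horizon_days + other.horizon_days,
        )


def _normalise_split(split: tuple[float, float, float]) -> tuple[float, float, float]:
    s = float(sum(split))
    if s <= 0:
        raise ValueError("macronutrient split must have a positive sum")
    if not 90.0 <= s <= 110.0 and not 0.9 <= s <= 1.1:
        raise ValueError(f"macronutrient split {split} does not sum to ~100%")
    return (split[0] / s, split[1] / s, split[2] / s)


def _meal(start_h: float, kcal: float, split: tuple[float, float, float],
          duration_min: float) -> MealEvent:
    fc, fp, ff = split
    return MealEvent(
        start_h=start_h,
        carb_g=fc * kcal / ATWATER["carb"],
        protein_g=fp * kcal / ATWATER["protein"],
        fat_g=ff * kcal / ATWATER["fat"],
        duration_min=duration_min,
    )

# default clock times (hours within a day)
_TIMES = {
    "IF": (12.0, 20.0),
    "SFM": (8.0, 13.0, 19.0),
    "3meals": (8.0, 13.0, 19.0),
    "5:2_restricted": (12.0, 19.0),
}


def build_diet(
    scheme: str,
    daily_kcal: float = 2000.0,
    macro_split: tuple[float, float, float] | None = None,
    meal_times: tuple[float, ...] | None = None,
    days: int = 7,
    duration_min: float = 15.0,
) -> DietSchedule:
    """Build one of the named diet schedules (times are absolute hours).

    For 5:2 the ``daily_kcal`` target is the weekly mean: normal days get
    ``daily_kcal*2560/2000`` and the two restricted days ``daily_kcal*600/2000``,
    preserving the isocaloric weekly average.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "custom" and meal_times is None:
        raise ValueError("custom scheme requires explicit meal_times")

    split = _normalise_split(macro_split) if macro_split is not None else None
    meals: list[MealEvent] = []

    for day in range(days):
        off = 24.0 * day
        if scheme == "5:2":
            restricted = day % 7 in (5, 6)
            day_kcal = daily_kcal * (600.0 if restricted else 2560.0) / 2000.0
            times = _TIMES["5:2_restricted"] if restricted else _TIMES["3meals"]
            day_split = split or _normalise_split(STANDARD_SPLIT)
        else:
            day_kcal = daily_kcal
            if scheme == "IF":
                times = meal_times or _TIMES["IF"]
                day_split = split or _normalise_split(STANDARD_SPLIT)
            elif scheme == "SFM":
                times = meal_times or _TIMES["SFM"]
                day_split = split or _normalise_split(STANDARD_SPLIT)
            elif scheme == "HCLF":
                times = meal_times or _TIMES["3meals"]
                day_split = split or _normalise_split((60.0, 25.0, 15.0))
            elif scheme == "LCHF":
                times = meal_times or _TIMES["3meals"]
                day_split = split or _normalise_split((30.0, 25.0, 45.0))
            else:  # custom
                times = meal_times
                day_split = split or _normalise_split(STANDARD_SPLIT)
        per_meal = day_kcal / len(times)
        for t in times:
            meals.append(_meal(off + t, per_meal, day_split, duration_min))

    return DietSchedule(meals=tuple(meals), scheme=scheme, horizon_days=float(days))


class ModelInput:
    """Piecewise-constant ingestion-rate signal u(t) derived from a schedule.

    Rates are in g/min; times internally in minutes.  The integral of each
    macronutrient rate over a meal equals that meal's grams by construction.
    """

    def __init__(self, schedule: DietSchedule):
        self.schedule = schedule
        edges: set[float] = {0.0}
        for m in schedule.meals:
            edges.add(m.start_h * 60.0)
            edges.add(m.end_h * 60.0)
        self.edges = np.array(sorted(edges))
        n = len(self.edges)
        self._carb = np.zeros(n)
        self._prot = np.zeros(n)
        self._fat = np.zeros(n)
        for m in schedule.meals:
            s, e = m.start_h * 60.0, m.end_h * 60.0
            sel = (self.edges >= s - 1e-9) & (self.edges < e - 1e-9)
            self._carb[sel] += m.carb_g / m.duration_min
            self._prot[sel] += m.protein_g / m.duration_min
            self._fat[sel] += m.fat_g / m.duration_min

    def rates(self, t_min: float) -> tuple[float, float, float]:
        """(carb, protein, fat) ingestion rates in g/min at time t (minutes)."""
        i = int(np.searchsorted(self.edges, t_min, side="right")) - 1
        if i < 0 or t_min < 0:
            return (0.0, 0.0, 0.0)
        return (self._carb[i], self._prot[i], self._fat[i])

    def breakpoints_min(self, t0_min: float, t1_min: float) -> np.ndarray:
        """Segment boundaries (meal starts/ends) inside [t0, t1], inclusive."""
        inner = self.edges[(self.edges > t0_min + 1e-9) & (self.edges < t1_min - 1e-9)]
        return np.concatenate([[t0_min], inner, [t1_min]])

    def total_grams(self) -> tuple[float, float, float]:
        carb = sum(m.carb_g for m in self.schedule.meals)
        prot = sum(m.protein_g for m in self.schedule.meals)
        fat = sum(m.fat_g for m in self.schedule.meals)
        return carb, prot, fat


def to_input_signal(schedule: DietSchedule) -> ModelInput:
    """Square-pulse input signal for a diet schedule."""
    return ModelInput(schedule)


def empty_schedule(days: float = 1.0) -> DietSchedule:
    """A fasting (no-meal) schedule."""
    return DietSchedule(meals=(), scheme="custom", horizon_days=days)
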