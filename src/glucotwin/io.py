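"""YAML/JSON configuration I/O: subjects, protocols, parameter sets."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .body import Anthropometry
from .meals_diets import DietSchedule, MealEvent, build_diet
from .parameters import ParameterSet

__all__ = [
    "load_subject",
    "save_subject",
    "load_protocol",
    "save_protocol",
    "load_params",
    "save_params",
]


def load_subject(path) -> tuple[Anthropometry, dict]:
    """Read a subject profile YAML.

    Expected keys: sex, weight_kg, height_m, optional age_y, diabetic, and
    an optional ``personal`` mapping of personal-parameter overrides, which
    is returned as the second element.
    """
    d = yaml.safe_load(Path(path).read_text())
    anthro = Anthropometry(
        sex=d.get("sex", "male"),
        weight_kg=float(d.get("weight_kg", 80.0)),
        height_m=float(d.get("height_m", 1.80)),
        age_y=d.get("age_y"),
        diabetic=bool(d.get("diabetic", False)),
    )
    return anthro, dict(d.get("personal", {}))


def save_subject(anthro: Anthropometry, path, personal: dict | None = None) -> None:
    d = {
        "sex": anthro.sex, "weight_kg": anthro.weight_kg,
        "height_m": anthro.height_m, "diabetic": anthro.diabetic,
    }
    if anthro.age_y is not None:
        d["age_y"] = anthro.age_y
    if personal:
        d["personal"] = dict(personal)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_protocol(path) -> DietSchedule:
    """Read a protocol YAML: either a named scheme

        scheme: "5:2"
        daily_kcal: 2000
        days: 7

    or an explicit meal list

        meals:
          - {start_h: 1.0, carb_g: 87, protein_g: 23, fat_g: 20, duration_min: 15}
    """
    d = yaml.safe_load(Path(path).read_text())
    if "meals" in d:
        meals = tuple(
            MealEvent(
                start_h=float(m["start_h"]),
                carb_g=float(m.get("carb_g", 0.0)),
                protein_g=float(m.get("protein_g", 0.0)),
                fat_g=float(m.get("fat_g", 0.0)),
                duration_min=float(m.get("duration_min", 15.0)),
            ) for m in d["meals"])
        horizon = float(d.get("horizon_days")
                        or max(m.end_h for m in meals) / 24.0 + 0.5)
        return DietSchedule(meals=meals, scheme=d.get("scheme", "custom"),
                            horizon_days=horizon)
    return build_diet(
        d["scheme"],
        daily_kcal=float(d.get("daily_kcal", 2000.0)),
        macro_split=tuple(d["macro_split"]) if "macro_split" in d else None,
        days=int(d.get("days", 7)),
        duration_min=float(d.get("duration_min", 15.0)),
    )


def save_protocol(schedule: DietSchedule, path) -> None:
    d = {
        "scheme": schedule.scheme,
        "horizon_days": schedule.horizon_days,
        "meals": [
            {"start_h": m.start_h, "carb_g": round(m.carb_g, 4),
             "protein_g": round(m.protein_g, 4), "fat_g": round(m.fat_g, 4),
             "duration_min": m.duration_min}
            for m in schedule.meals
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_params(path) -> ParameterSet:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        return ParameterSet.from_dict(yaml.safe_load(p.read_text()))
    return ParameterSet.from_dict(json.loads(p.read_text()))


def save_params(params: ParameterSet, path) -> None:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    else:
        p.write_text(json.dumps(params.to_dict(), indent=2))
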