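"""Personalise the population model into an individual twin.

Category i: anthropometry scales blood volumes (liver blood = 13% of the
Nadler total).  Category iii: the three personal modifiers (insulin
production, clearance, resistance) are fitted to a synthetic subject's
calibration data; the recovered modifiers should match the values the
subject was generated with, and the 57 general parameters stay untouched.
"""

from glucotwin import (Anthropometry, ParameterSet, blood_volumes,
                       fit_person_params)
from glucotwin.study_fixtures import generate_study, standard_meal_fixture

anthro = Anthropometry(sex="male", weight_kg=80.0, height_m=1.80)
bv = blood_volumes(anthro)
print(f"total blood volume {bv.total_l:.2f} L, liver {bv.liver_l:.2f} L "
      f"({bv.liver_l / bv.total_l:.0%} of total)\n")

population = ParameterSet.healthy()
subject_truth = dict(insulin_production=1.3, insulin_clearance=0.8,
                     insulin_resistance=1.1)
spec = standard_meal_fixture(
    seed=21, params=population.with_personal(**subject_truth), n_points=24)
dataset, _ = generate_study(spec)
dataset.records["is_calibration"] = True

mods = fit_person_params(population, dataset, anthro)
print("modifier              recovered   truth")
for name, tv in subject_truth.items():
    print(f"{name:20s} {getattr(mods, name):9.3f} {tv:7.3f}")
print("\n(general parameters are held fixed during personalisation)")
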