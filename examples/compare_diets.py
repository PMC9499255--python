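"""Compare five named diet schemes on the three-week switch protocol.

Week 1 is a standardised 2000 kcal/day diet; the named scheme starts in
week 2; the table shows analysis-week (week 3) means.  IF, 5:2 and SFM are
isocaloric (2000 kcal/day weekly average); HCLF and LCHF differ in
macronutrient composition.  Expect: more frequent meals (SFM) lower mean
insulin with little glucose change, and the high-carbohydrate diet (HCLF)
raises glycogen, insulin and glucose relative to LCHF.
"""

from glucotwin import DigitalTwin, run_diet_comparison
from glucotwin.protocols import diet_switch_schedule

twin = DigitalTwin.default()
schedules = {s: diet_switch_schedule(s) for s in ("SFM", "IF", "5:2", "HCLF", "LCHF")}
results = run_diet_comparison(twin, schedules, grid_minutes=3.0)

print("diet   glucose  insulin  glycogen   GNG    EGP")
print("        mmol/L   pmol/L    mmol/L   umol/kg/min")
for name, r in results.items():
    s = r.summaries
    print(f"{name:5s} {s['mean_glucose_mM']:8.2f} {s['mean_insulin_pM']:8.1f} "
          f"{s['mean_glycogen_mM']:9.0f} {s['mean_gng_umol_kg_min']:6.2f} "
          f"{s['mean_egp_umol_kg_min']:6.2f}")
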