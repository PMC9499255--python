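# Methods

## Model structure

The twin is a 15-state ODE system spanning three timescales: minutes
(gut absorption, insulin), hours (plasma glucose, hepatic metabolite
pools), and days (hepatic/renal glycogen, muscle protein reserve).

States by compartment — gut: stomach carbohydrate, intestinal glucose,
stomach protein, intestinal amino acids (grams); circulation: plasma and
interstitial glucose (mmol/L), plasma and liver-compartment insulin
(pmol/L); liver: glycogen, a glucose-6-phosphate pool, amino acids,
pyruvate and TCA intermediates (mmol per L of liver volume); kidney:
glycogen; muscle: a mobilisable protein reserve (mmol amino acids).

Rate laws are saturating (Michaelis–Menten-type) for uptake and
production, with Hill-type insulin inhibition of gluconeogenesis and
glycogenolysis, and linear-in-signal insulin stimulation of peripheral
uptake. Hepatic insulin actions (liver uptake, glycogen synthesis)
saturate at twice their basal activity, reflecting the near-saturated
portal insulin receptor at high secretion rates and preventing unbounded
postprandial deposition. Insulin secretion responds to plasma glucose as
a power law plus an oral (incretin-like) term proportional to the meal
glucose appearance rate. Ingested fat enters the energy ledger only; the
model has no lipid dynamics (see Limitations).

Glucose production is structural: four non-negative source fluxes
(hepatic/renal glycogenolysis, hepatic/renal gluconeogenesis) each feed
plasma directly, so EGP = HGP + RGP = GNG + glycogenolysis holds exactly
by construction rather than to solver tolerance.

### The fed/fasted protein switch

The hepatic glycogen level acts as the energy-status signal: a decreasing
Hill switch (half point 120 mmol/L, exponent 3) simultaneously (i) raises
the catabolic routing of hepatic amino acids towards pyruvate, (ii)
suppresses anabolic amino-acid consumption, and (iii) disinhibits muscle
proteolysis. Fed (glycogen ≳ 250 mmol/L) the switch is nearly off and a
protein bolus is metabolically silent for plasma glucose; after a 48 h
fast (glycogen < 100 mmol/L) absorbed amino acids flow through pyruvate
into gluconeogenesis and glucose rises by over 1 mmol/L for several
hours.

### Basal anchoring

All rate laws are normalised at the subject's declared basal operating
point (basal glucose G_b, basal insulin I_b — two of the five personal
parameters — plus reference pool levels). At that point basal endogenous
glucose production equals `egp_basal` (default 10 µmol/kg/min), split
across the four sources by the `w_*` weights, and equals total uptake,
split across organs by the `f_uptake_*` shares; derived constants
(basal secretion, liver→plasma insulin transfer, glycolysis, pyruvate
oxidation, TCA drain, basal amino-acid pool) are solved so that every
*fast* state has exactly zero derivative there. The slow stores are
deliberately not anchored: hepatic glycogen drains at its physiological
basal rate (~10 mmol/L/h post-absorptively), which is precisely the
finite-store behaviour that makes glucose fall over a long fast. A true
all-state fixed point does not exist in the fed regime, by design; the
steady-state contract is therefore "fast states exact, glucose drift
< 0.05 mmol/L over the first hour". Infeasible anchors (e.g. synthesis
demand exceeding basal hepatic uptake) raise an error naming the violated
balance.

Personal modifiers (production, clearance, resistance) are applied on top
of the anchor, so a modifier ≠ 1 moves the subject away from the declared
population basal — which is exactly what calibration fits them to do.

## Parameters

57 general parameters per population variant (healthy / T2D), each with
declared optimisation bounds, plus 5 personal parameters. The defaults
are this package's own model development: they were calibrated so that
the eight qualitative constraints and the published physiological bands
hold simultaneously (organ uptake shares 40–50% brain / 15–20% muscle /
10–15% liver / 5–10% kidney post-absorptively; renal EGP share 5–15%;
hepatic insulin clearance 50–80%; fed glycogen 200–350 mmol/L and unfed
< 100 mmol/L; an overnight gluconeogenic fraction near 50% rising towards
90% at 48–68 h, higher in the T2D variant). They are not a transcription
of any published fitted vector. The T2D variant differs in blunted
glucose-stimulated secretion, higher insulin-inhibition constants
(hepatic insulin resistance), lower peripheral insulin-dependent uptake,
a larger gluconeogenesis weight, and a smaller glycogen store with weaker
synthesis.

Units: glucose mmol/L, insulin pmol/L, glycogen mmol per L of organ
volume, fluxes µmol/kg/min externally (mmol/min internally), time hours
externally, minutes internally. Blood volume follows the sex-specific
Nadler height³/weight regressions with liver blood fixed at 13% of total
and a ±30% calibration band; glucose distributes in 0.18 L/kg, the liver
pool volume is 0.021 L/kg.

## Simulation

Stiff-capable integration (LSODA, rtol 1e-6, atol 1e-8) restarted at
every meal start/end so input discontinuities never straddle a solver
step; dense output on a regular grid (default 1 min). A fixed-step
classical RK4 integrator over the same right-hand side serves as the
solver-independence oracle; the two agree to well within 0.5% on all
observables for the fixture protocols. Tiny negative solver undershoots
of empty pools (within 1e-6) are clamped to zero at segment boundaries;
anything larger is flagged on the result. Meals above ~1000 kcal are
outside the supported input range and trigger a warning rather than an
error.

## Estimation

Cost: `V(q) = Σ ((y − ŷ)/SEM)²`, ŷ linearly interpolated from the dense
grid at the record times. Records with SEM below 5% of the observable's
dynamic range can be floored to that value (`StudyDataset.floor_sems`),
the generic version of the manual fix needed when single digitised points
carry unrealistically small errors. Eight qualitative constraints add
1e5 each to the optimisation objective — large enough to dominate any
plausible χ² cost — and are excluded from the χ² verdict, which always
audits the unpenalised cost. Degrees of freedom = number of data points,
with no subtraction of parameter count; this convention reproduces all
six reference threshold/cost pairings used in the tests.

The global optimiser is an in-package global-best particle swarm
(inertia 0.729, both acceleration constants 1.49445, velocity clamp 25%
of the box, reflecting bounds), deterministic under a fixed seed, with
stall-based termination (default 20 stall iterations at tolerance 1e-6)
and an optional Nelder–Mead polish. The `full` preset uses a swarm of
2000; the `smoke` preset (swarm 24, 30 iterations) runs the whole stack
in minutes and is what the test suite uses. Every evaluated vector whose
unpenalised cost passes the χ² test is archived (capped at 500); the
pointwise min/max of ensemble simulations is the model-uncertainty band.

Personal-parameter calibration (category iii) fits the three modifiers in
log space by trust-region least squares on the weighted residuals of the
designated calibration points only; the general parameters are never
touched. Basal calibration (category ii) sets the basal personal
parameters from the supplied baselines and tunes the daily energy of a
five-day, three-meal standard lead-in diet (meal size 200–1000 kcal) by
bounded scalar search until the simulated hepatic glycogen at study start
matches the baseline within its SEM (5% when no SEM is given).

## Synthetic studies

The fixture generator draws additive, independent, normally distributed
noise around a truth simulation; stored values are replicate means with
SEM = σ/√n, and the truth parameters travel in a JSON sidecar. Default
design: a mixed-meal study (87 g carbohydrate / 23 g protein), 12 time
points over 10 h, glucose and insulin observed, σ = 5% of a typical
dynamic range, n = 5 replicates. The generator reproduces the statistical
assumptions of the cost function and nothing else: it does not emulate
figure-digitisation error, inter-subject variability beyond the personal
parameters, or non-Gaussian sensor noise, so passing recovery tests
demonstrate internal consistency of the estimation stack, not performance
on real clinical data.

## Window conventions and protocol sizes

"Post-absorptive" = hours 10–14 of a fast after a standard dinner;
"postprandial" = 0–3 h after a ~700 kcal standard meal; the fed-glycogen
constraint is checked on the evening of the last day of a standard-diet
week, the unfed constraint at hours 46–48 of a 48 h fast. The diet
comparison uses a three-week protocol (standard week, switch, analysis of
week 3) at a 2–3 min output grid; summaries are invariant to grid
resolution within 1%. The Monte-Carlo checks use 150 fixture seeds for
the truth-cost calibration and 20 seeds × 3 free parameters for recovery
(smoke-preset swarm); these sizes keep the full suite in CPU minutes
while leaving the binomial checks well-powered.

## Numerical and design choices

- Meal input: square pulse over the ingestion duration (default 15 min);
  the integral always equals the grams eaten.
- Macronutrient splits are normalised to sum to 1 before use (printed
  splits like 45/27/27 sum to 99%); kcal closure enforced to 1 kcal via
  Atwater factors 4/4/9.
- The LCHF template halves HCLF's carbohydrate energy share (60% → 30%),
  keeps protein at 25% and moves the remainder (45%) to fat, since only
  the carbohydrate halving is specified for that scheme.
- Default meal times: IF 12:00/20:00; SFM and normal 5:2 days
  08:00/13:00/19:00; restricted 5:2 days 12:00/19:00.
- A fed-state bolus response is called "negligible" below a configurable
  0.5 mmol/L peak rise.
- "Other tissues" glucose uptake is an explicit flux (share ~18% at
  basal), not a residual.
- Kidney gluconeogenesis shares the hepatic pyruvate-availability signal
  but does not drain the hepatic pool (renal precursors are taken up from
  the circulation and are outside the model boundary, like brain uptake).

## Limitations

- No lipid metabolism or glucose–fat crosstalk: fat is energetically
  booked but dynamically inert, so LCHF-type predictions reflect only the
  carbohydrate/protein changes.
- Single-meal hepatic glycogen deposition is smaller than mixed-meal
  studies report; the calibrated quantity is the store's weekly
  equilibrium and its fed/unfed windows, not the per-meal increment.
- Insulin secretion has no explicit first-phase/second-phase separation;
  the incretin term is a lumped proxy.
- No body-weight-dependent insulin resistance and no long-term weight
  change; anthropometry only scales volumes.
- Behaviour outside the calibrated input range (meals ≫ 1000 kcal, fasts
  > 72 h) is unvalidated and guarded by warnings.
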