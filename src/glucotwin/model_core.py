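"""Whole-body glucose-insulin-glycogen ODE model.

The model tracks meal carbohydrate and protein through the gut into plasma
glucose and a hepatic amino-acid pool, couples plasma/liver insulin to
glucose-dependent secretion and two-site clearance, and maintains finite
hepatic and renal glycogen stores.  Endogenous glucose production (EGP) is
the sum of four non-negative source fluxes -- hepatic/renal glycogenolysis
and hepatic/renal gluconeogenesis -- each inhibited by insulin (Hill
terms), so the bookkeeping EGP = HGP + RGP = GNG + glycogenolysis closes
exactly at every instant.  An energy-status switch (a falling hepatic
glycogen store) re-routes amino acids from anabolic fates towards pyruvate
and gluconeogenesis, and disinhibits muscle proteolysis: this is what makes
a protein bolus glucogenic after a long fast but not in the fed state.

Units: glucose mmol/L, insulin pmol/L, hepatic/renal glycogen mmol per L of
organ volume, gut pools g, fluxes internally mmol/min (reported as
umol/kg/min); time is hours externally, minutes internally.

All rate laws are anchored at the subject's declared basal operating point
(basal glucose/insulin, reference glycogen): at that point every fast state
has zero derivative by construction, while the slow stores (glycogen,
muscle protein) drain at their physiological basal rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .body import Anthropometry, blood_volumes
from .meals_diets import DietSchedule, ModelInput, empty_schedule, to_input_signal
from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "SimulationError",
    "SimulationResult",
    "BasalAnchor",
    "build_anchor",
    "compute_fluxes",
    "rhs",
    "steady_state",
    "simulate",
    "simulate_fixed_step",
    "DigitalTwin",
]

STATE_NAMES = (
    "stomach_carb",       # g
    "gut_glucose",        # g
    "stomach_protein",    # g
    "gut_aa",             # g
    "plasma_glucose",     # mmol/L
    "tissue_glucose",     # mmol/L
    "plasma_insulin",     # pmol/L
    "liver_insulin",      # pmol/L
    "hepatic_glycogen",   # mmol/L liver
    "hepatic_g6p",        # mmol/L liver
    "hepatic_aa",         # mmol/L liver
    "hepatic_pyruvate",   # mmol/L liver
    "tca_pool",           # mmol/L liver
    "renal_glycogen",     # mmol/L kidney
    "muscle_protein",     # mmol amino acids
)
_IX = {name: i for i, name in enumerate(STATE_NAMES)}

# molar bookkeeping
MMOL_GLUCOSE_PER_G = 1000.0 / 180.156
MMOL_AA_PER_G = 1000.0 / 110.0   # mean amino-acid residue mass 110 g/mol
PYR_PER_GLUCOSE = 2.0            # 2 pyruvate -> 1 glucose in gluconeogenesis

# structural constants (model shape, not fitted)
KM_BRAIN = 1.0        # mmol/L, brain uptake half-saturation
HILL_LIVER_UPTAKE = 2.0
HILL_CAP = 4.0        # steepness of glycogen-synthesis shut-off
HILL_SWITCH = 3.0     # steepness of the glycogen energy-status switch
HILL_MDEG = 2.0       # steepness of insulin inhibition of proteolysis
KM_PYR_OX = 0.10      # mmol/L, pyruvate-oxidation half-saturation
TCA_BASAL = 0.5       # mmol/L, basal TCA-intermediate pool
PLASMA_FRACTION = 0.6  # plasma fraction of blood volume (insulin spaces)
SEC_CAP = 40.0        # secretion ceiling, multiples of basal


class SimulationError(RuntimeError):
    """Integration failure; carries the last successfully reached time (h)."""

    def __init__(self, message: str, last_time_h: float | None = None):
        super().__init__(message)
        self.last_time_h = last_time_h


def _hill_inh(x: float, k: float, n: float) -> float:
    """Decreasing Hill inhibition term 1/(1+(x/k)^n)."""
    if x <= 0.0:
        return 1.0
    return 1.0 / (1.0 + (x / k) ** n)


@dataclass(frozen=True)
class BasalAnchor:
    """Derived constants fixing the subject's basal operating point."""

    bw: float
    v_g: float
    v_gt: float
    v_l: float
    v_k: float
    v_i: float
    v_il: float
    g_b: float
    i_b: float
    il_b: float
    gt_b: float
    s_b: float            # basal insulin secretion, pmol/min
    k_out: float          # liver->plasma insulin transfer, 1/min
    r_b: float            # basal glucose turnover, mmol/min
    shares: dict[str, float]       # normalised basal uptake shares
    weights: dict[str, float]      # normalised basal EGP source weights
    # normalisation denominators of the production terms
    sat_gly_ref: float
    inh_gly_b: float
    sat_pyr_b: float
    inh_gng_b: float
    sat_glyk_ref: float
    sat_g6p_b: float
    cap_gly_ref: float
    # derived rate constants
    k_glycolysis: float   # mmol/min per (mmol/L) of hepatic glucose pool
    aa_b: float           # basal hepatic amino-acid pool, mmol/L
    cat_act_b: float
    v_pyr_ox: float       # maximal pyruvate oxidation, mmol/min
    k_tca: float          # TCA drain rate constant
    inh_mdeg_b: float
    gate_mdeg_b: float
    sw_ref: float


def build_anchor(params: ParameterSet, anthropometry: Anthropometry) -> BasalAnchor:
    """Compute the derived basal constants; raise if no admissible basal
    steady state exists (the violated balance is named in the message)."""
    g = params.general
    p = params.personal
    bw = anthropometry.weight_kg
    bv = blood_volumes(anthropometry)

    v_g = g["v_glucose_per_kg"] * bw
    v_gt = g["v_tissue_per_kg"] * bw
    v_l = g["v_liver_per_kg"] * bw
    v_k = g["v_kidney_per_kg"] * bw
    v_il = PLASMA_FRACTION * bv.liver_l
    v_i = PLASMA_FRACTION * (bv.total_l - bv.liver_l)

    g_b, i_b = p.basal_glucose, p.basal_insulin
    il_b = g["liver_plasma_insulin_ratio"] * i_b
    r_b = g["egp_basal"] * bw / 1000.0  # mmol/min

    share_raw = {k: g[f"f_uptake_{k}"] for k in ("brain", "muscle", "liver", "kidney", "other")}
    tot = sum(share_raw.values())
    shares = {k: v / tot for k, v in share_raw.items()}

    w_raw = {
        "glycogenolysis_liver": g["w_glycogenolysis_liver"],
        "gng_liver": g["w_gng_liver"],
        "gng_kidney": g["w_gng_kidney"],
        "glycogenolysis_kidney": g["w_glycogenolysis_kidney"],
    }
    wtot = sum(w_raw.values())
    weights = {k: v / wtot for k, v in w_raw.items()}

    # interstitial glucose consistent with basal muscle+other disposal
    gt_b = g_b - r_b * (shares["muscle"] + shares["other"]) / (g["k_glucose_exchange"] * v_g)
    if gt_b <= 0.5:
        raise ValueError(
            "no admissible basal steady state: interstitial glucose would be "
            f"{gt_b:.2f} mmol/L; increase k_glucose_exchange or basal glucose"
        )

    # insulin loop: transfer and secretion anchored to (i_b, il_b)
    k_out = g["cl_insulin_periphery"] * i_b * v_i / (il_b * v_il)
    s_b = (g["cl_insulin_liver"] + k_out) * il_b * v_il

    # production-term normalisations at the reference internal state
    gly_ref = g["glycogen_ref"]
    sat_gly_ref = gly_ref / (gly_ref + g["km_glycogenolysis"])
    inh_gly_b = _hill_inh(il_b, g["ki_insulin_glycogenolysis"], g["hill_insulin_glycogenolysis"])
    pyr_b = g["pyruvate_basal"]
    sat_pyr_b = pyr_b / (pyr_b + g["km_gng_pyruvate"])
    inh_gng_b = _hill_inh(il_b, g["ki_insulin_gng"], g["hill_insulin_gng"])
    glyk_ref = g["glycogen_kidney_ref"]
    sat_glyk_ref = glyk_ref / (glyk_ref + g["km_glycogenolysis_kidney"])

    # hepatic glucose pool: basal glycolysis closes the G6P balance
    g6p_b = g["g6p_basal"]
    sat_g6p_b = g6p_b / (g6p_b + g["km_synthesis_g6p"])
    cap_gly_ref = 1.0 / (1.0 + (gly_ref / g["glycogen_max"]) ** HILL_CAP)
    u_liver_b = r_b * shares["liver"]
    syn_b = g["v_glycogen_synthesis"] * sat_g6p_b * cap_gly_ref
    glycolysis_b = u_liver_b - syn_b
    if glycolysis_b <= 0.0:
        raise ValueError(
            "no admissible basal steady state: basal glycogen synthesis "
            f"({syn_b:.3f} mmol/min) exceeds basal hepatic glucose uptake "
            f"({u_liver_b:.3f} mmol/min); lower v_glycogen_synthesis"
        )
    k_glycolysis = glycolysis_b / g6p_b

    # amino-acid pool: turnover balances catabolic + anabolic removal
    sw_ref = _hill_inh(gly_ref, g["glycogen_switch_km"], HILL_SWITCH)
    cat_act_b = g["cat_floor"] + (1.0 - g["cat_floor"]) * sw_ref
    aa_removal = (g["k_aa_catabolic"] * cat_act_b + g["k_aa_anabolic"]) * v_l
    aa_b = g["aa_turnover"] / aa_removal
    cat_b = g["k_aa_catabolic"] * cat_act_b * aa_b * v_l

    # pyruvate balance: supply must cover basal gluconeogenesis
    cori_b = g["frac_cori"] * r_b * (shares["muscle"] + shares["other"]) * PYR_PER_GLUCOSE
    inflow_b = (
        PYR_PER_GLUCOSE * glycolysis_b
        + g["frac_aa_to_pyruvate"] * cat_b
        + cori_b
        + g["glycerol_supply"]
        + g["muscle_deg_basal"]
    )
    gng_consumption_b = PYR_PER_GLUCOSE * r_b * weights["gng_liver"]
    ox_b = inflow_b - gng_consumption_b
    if ox_b <= 0.0:
        raise ValueError(
            "no admissible basal steady state: basal pyruvate supply "
            f"({inflow_b:.3f} mmol/min) cannot cover basal hepatic "
            f"gluconeogenesis ({gng_consumption_b:.3f} mmol/min)"
        )
    v_pyr_ox = ox_b * (pyr_b + KM_PYR_OX) / pyr_b

    # TCA drain closes at the basal pool
    tca_in_b = (1.0 - g["frac_aa_to_pyruvate"]) * cat_b + ox_b
    k_tca = tca_in_b / (TCA_BASAL * v_l)

    inh_mdeg_b = _hill_inh(i_b, g["ki_insulin_muscle_deg"], HILL_MDEG)
    gate_mdeg_b = g["mdeg_glycogen_floor"] + (1.0 - g["mdeg_glycogen_floor"]) * sw_ref

    return BasalAnchor(
        bw=bw, v_g=v_g, v_gt=v_gt, v_l=v_l, v_k=v_k, v_i=v_i, v_il=v_il,
        g_b=g_b, i_b=i_b, il_b=il_b, gt_b=gt_b, s_b=s_b, k_out=k_out, r_b=r_b,
        shares=shares, weights=weights,
        sat_gly_ref=sat_gly_ref, inh_gly_b=inh_gly_b, sat_pyr_b=sat_pyr_b,
        inh_gng_b=inh_gng_b, sat_glyk_ref=sat_glyk_ref, sat_g6p_b=sat_g6p_b,
        cap_gly_ref=cap_gly_ref, k_glycolysis=k_glycolysis, aa_b=aa_b,
        cat_act_b=cat_act_b, v_pyr_ox=v_pyr_ox, k_tca=k_tca,
        inh_mdeg_b=inh_mdeg_b, gate_mdeg_b=gate_mdeg_b, sw_ref=sw_ref,
    )


FLUX_NAMES = (
    "ra_meal_glucose", "aa_absorption",
    "insulin_secretion", "insulin_clearance_liver", "insulin_clearance_periphery",
    "uptake_brain", "uptake_muscle", "uptake_liver", "uptake_kidney", "uptake_other",
    "glycogenolysis_liver", "gng_liver", "glycogenolysis_kidney", "gng_kidney",
    "hgp", "rgp", "egp", "gng_total", "glycogenolysis_total",
    "glycogen_synthesis", "glycolysis", "aa_catabolic", "aa_anabolic",
    "muscle_degradation", "pyruvate_oxidation",
)


def compute_fluxes(t_min: float, y, params: ParameterSet, anchor: BasalAnchor,
                   u: ModelInput | None) -> dict[str, float]:
    """All reaction fluxes at one instant, in mmol/min (insulin: pmol/min).

    The single source of truth for both the ODE right-hand side and the
    reported flux trajectories, so production bookkeeping closes exactly.
    """
    g = params.general
    p = params.personal
    a = anchor

    sc = max(y[0], 0.0); gg = max(y[1], 0.0)
    sp = max(y[2], 0.0); ga = max(y[3], 0.0)
    G = max(y[4], 1e-6); Gt = max(y[5], 1e-6)
    I = max(y[6], 0.0); Il = max(y[7], 0.0)
    GLY = max(y[8], 0.0); G6P = max(y[9], 0.0)
    AA = max(y[10], 0.0); PYR = max(y[11], 0.0)
    TCA = max(y[12], 0.0); GLYK = max(y[13], 0.0)
    MP = max(y[14], 0.0)

    # effective insulin at action sites (resistance divides the signal)
    i_eff = I / p.insulin_resistance
    il_eff = Il / p.insulin_resistance

    # --- gut ---
    ra_meal = g["k_absorb_carb"] * gg * MMOL_GLUCOSE_PER_G        # mmol glucose/min
    aa_abs = g["k_absorb_prot"] * ga * MMOL_AA_PER_G              # mmol aa/min

    # --- insulin secretion / clearance ---
    rel = (G / a.g_b) ** g["sec_hill"]
    oral = g["sec_incretin"] * ra_meal / a.r_b
    secretion = p.insulin_production * a.s_b * min(rel + oral, SEC_CAP)
    cl_liver = p.insulin_clearance * g["cl_insulin_liver"] * Il * a.v_il
    cl_periph = p.insulin_clearance * g["cl_insulin_periphery"] * I * a.v_i

    # --- organ glucose uptake (normalised to basal shares) ---
    r_b = a.r_b
    u_brain = r_b * a.shares["brain"] * (G / (G + KM_BRAIN)) / (a.g_b / (a.g_b + KM_BRAIN))
    # hepatic insulin action saturates at twice its basal activity
    il_act = 2.0 * il_eff / (il_eff + a.il_b)
    u_liver = (
        r_b * a.shares["liver"] * (G / a.g_b) ** HILL_LIVER_UPTAKE
        * (1.0 - g["ins_frac_liver_uptake"] + g["ins_frac_liver_uptake"] * il_act)
    )
    u_kidney = (
        r_b * a.shares["kidney"]
        * (G / (G + g["km_uptake_kidney"])) / (a.g_b / (a.g_b + g["km_uptake_kidney"]))
    )
    u_muscle = (
        r_b * a.shares["muscle"]
        * (Gt / (Gt + g["km_uptake_muscle"])) / (a.gt_b / (a.gt_b + g["km_uptake_muscle"]))
        * (1.0 - g["ins_frac_muscle"] + g["ins_frac_muscle"] * i_eff / a.i_b)
    )
    u_other = (
        r_b * a.shares["other"] * (Gt / a.gt_b)
        * (1.0 - g["ins_frac_other"] + g["ins_frac_other"] * i_eff / a.i_b)
    )

    # --- endogenous glucose production (four non-negative sources) ---
    glyc_l = (
        r_b * a.weights["glycogenolysis_liver"]
        * (GLY / (GLY + g["km_glycogenolysis"])) / a.sat_gly_ref
        * _hill_inh(il_eff, g["ki_insulin_glycogenolysis"], g["hill_insulin_glycogenolysis"])
        / a.inh_gly_b
    )
    sat_pyr = (PYR / (PYR + g["km_gng_pyruvate"])) / a.sat_pyr_b
    inh_gng = _hill_inh(il_eff, g["ki_insulin_gng"], g["hill_insulin_gng"]) / a.inh_gng_b
    gng_l = r_b * a.weights["gng_liver"] * sat_pyr * inh_gng
    gng_k = r_b * a.weights["gng_kidney"] * sat_pyr * inh_gng
    glyc_k = (
        r_b * a.weights["glycogenolysis_kidney"]
        * (GLYK / (GLYK + g["km_glycogenolysis_kidney"])) / a.sat_glyk_ref
        * _hill_inh(il_eff, g["ki_insulin_glycogenolysis"], g["hill_insulin_glycogenolysis"])
        / a.inh_gly_b
    )
    hgp = glyc_l + gng_l
    rgp = glyc_k + gng_k
    egp = hgp + rgp

    # --- hepatic glucose pool, glycogen synthesis, glycolysis ---
    cap = 1.0 / (1.0 + (GLY / g["glycogen_max"]) ** HILL_CAP)
    syn = (
        g["v_glycogen_synthesis"] * (G6P / (G6P + g["km_synthesis_g6p"]))
        * (1.0 - g["ins_frac_synthesis"] + g["ins_frac_synthesis"] * il_act)
        * cap
    )
    glycolysis = a.k_glycolysis * G6P

    # --- amino-acid routing (energy-status switch) ---
    sw = _hill_inh(GLY, g["glycogen_switch_km"], HILL_SWITCH)
    cat_act = g["cat_floor"] + (1.0 - g["cat_floor"]) * sw
    ana_act = (
        (1.0 - g["ins_frac_anabolic"] + g["ins_frac_anabolic"] * il_eff / a.il_b)
        * (1.0 - sw) / (1.0 - a.sw_ref)
    )
    aa_cat = g["k_aa_catabolic"] * cat_act * AA * a.v_l
    aa_ana = g["k_aa_anabolic"] * ana_act * AA * a.v_l

    # --- muscle proteolysis (insulin- and energy-gated) ---
    gate = g["mdeg_glycogen_floor"] + (1.0 - g["mdeg_glycogen_floor"]) * sw
    m_deg = (
        g["muscle_deg_basal"]
        * _hill_inh(i_eff, g["ki_insulin_muscle_deg"], HILL_MDEG) / a.inh_mdeg_b
        * gate / a.gate_mdeg_b
        * (MP / g["muscle_protein_pool"])
    )

    # --- pyruvate oxidation ---
    pyr_ox = a.v_pyr_ox * PYR / (PYR + KM_PYR_OX)

    return {
        "ra_meal_glucose": ra_meal, "aa_absorption": aa_abs,
        "insulin_secretion": secretion,
        "insulin_clearance_liver": cl_liver,
        "insulin_clearance_periphery": cl_periph,
        "uptake_brain": u_brain, "uptake_muscle": u_muscle,
        "uptake_liver": u_liver, "uptake_kidney": u_kidney, "uptake_other": u_other,
        "glycogenolysis_liver": glyc_l, "gng_liver": gng_l,
        "glycogenolysis_kidney": glyc_k, "gng_kidney": gng_k,
        "hgp": hgp, "rgp": rgp, "egp": egp,
        "gng_total": gng_l + gng_k, "glycogenolysis_total": glyc_l + glyc_k,
        "glycogen_synthesis": syn, "glycolysis": glycolysis,
        "aa_catabolic": aa_cat, "aa_anabolic": aa_ana,
        "muscle_degradation": m_deg, "pyruvate_oxidation": pyr_ox,
    }


def rhs(t_min: float, y, params: ParameterSet, anchor: BasalAnchor,
        u: ModelInput | None) -> list[float]:
    """State derivatives (per minute) at time ``t_min`` (minutes)."""
    if not all(map(math.isfinite, y)):
        raise SimulationError(
            f"non-finite state encountered at t = {t_min / 60.0:.2f} h "
            "(integration blow-up)", last_time_h=t_min / 60.0)
    g = params.general
    a = anchor
    f = compute_fluxes(t_min, y, params, anchor, u)
    uc, up, _ = u.rates(t_min) if u is not None else (0.0, 0.0, 0.0)

    exch = g["k_glucose_exchange"] * a.v_g * (y[4] - y[5])
    tca_out = a.k_tca * max(y[12], 0.0) * a.v_l

    return [
        uc - g["k_stomach_carb"] * max(y[0], 0.0),
        g["k_stomach_carb"] * max(y[0], 0.0) - g["k_absorb_carb"] * max(y[1], 0.0),
        up - g["k_stomach_prot"] * max(y[2], 0.0),
        g["k_stomach_prot"] * max(y[2], 0.0) - g["k_absorb_prot"] * max(y[3], 0.0),
        (f["egp"] + f["ra_meal_glucose"] - f["uptake_brain"] - f["uptake_liver"]
         - f["uptake_kidney"] - exch) / a.v_g,
        (exch - f["uptake_muscle"] - f["uptake_other"]) / a.v_gt,
        (a.k_out * y[7] * a.v_il - f["insulin_clearance_periphery"]) / a.v_i,
        (f["insulin_secretion"] - f["insulin_clearance_liver"]) / a.v_il
        - a.k_out * y[7],
        (f["glycogen_synthesis"] - f["glycogenolysis_liver"]) / a.v_l,
        (f["uptake_liver"] - f["glycogen_synthesis"] - f["glycolysis"]) / a.v_l,
        (f["aa_absorption"] + g["aa_turnover"] - f["aa_catabolic"] - f["aa_anabolic"]) / a.v_l,
        (PYR_PER_GLUCOSE * f["glycolysis"]
         + g["frac_aa_to_pyruvate"] * f["aa_catabolic"]
         + g["frac_cori"] * PYR_PER_GLUCOSE * (f["uptake_muscle"] + f["uptake_other"])
         + g["glycerol_supply"] + f["muscle_degradation"]
         - PYR_PER_GLUCOSE * f["gng_liver"] - f["pyruvate_oxidation"]) / a.v_l,
        ((1.0 - g["frac_aa_to_pyruvate"]) * f["aa_catabolic"]
         + f["pyruvate_oxidation"] - tca_out) / a.v_l,
        (a.r_b * a.weights["glycogenolysis_kidney"] * (y[4] / a.g_b)
         * (max(y[7], 0.0) / params.personal.insulin_resistance / a.il_b)
         - f["glycogenolysis_kidney"]) / a.v_k,
        g["muscle_deg_basal"] - f["muscle_degradation"],
    ]


def steady_state(
    params: ParameterSet,
    anthropometry: Anthropometry | None = None,
    basal_glucose: float | None = None,
    basal_insulin: float | None = None,
    fed: bool = True,
) -> np.ndarray:
    """Basal state vector at the subject's anchored operating point.

    With ``fed=True`` hepatic glycogen starts at the fed reference level
    (inside the 200-350 mmol/L fed window for the healthy variant).  All
    fast states have zero derivative at the returned point; the slow stores
    (glycogen, muscle protein) drain at their physiological basal rates.
    """
    anthropometry = anthropometry or Anthropometry()
    if basal_glucose is not None or basal_insulin is not None:
        over = {}
        if basal_glucose is not None:
            over["basal_glucose"] = basal_glucose
        if basal_insulin is not None:
            over["basal_insulin"] = basal_insulin
        params = params.with_personal(**over)
    a = build_anchor(params, anthropometry)
    g = params.general
    gly0 = g["glycogen_ref"] if fed else min(g["glycogen_ref"], 90.0)
    y = np.zeros(len(STATE_NAMES))
    y[_IX["plasma_glucose"]] = a.g_b
    y[_IX["tissue_glucose"]] = a.gt_b
    y[_IX["plasma_insulin"]] = a.i_b
    y[_IX["liver_insulin"]] = a.il_b
    y[_IX["hepatic_glycogen"]] = gly0
    y[_IX["hepatic_g6p"]] = g["g6p_basal"]
    y[_IX["hepatic_aa"]] = a.aa_b
    y[_IX["hepatic_pyruvate"]] = g["pyruvate_basal"]
    y[_IX["tca_pool"]] = TCA_BASAL
    y[_IX["renal_glycogen"]] = g["glycogen_kidney_ref"]
    y[_IX["muscle_protein"]] = g["muscle_protein_pool"]
    return y


@dataclass
class SimulationResult:
    """Time grid (h), state trajectories and derived flux trajectories.

    Glucose fluxes are reported in umol/kg/min; insulin fluxes in pmol/min.
    """

    t: np.ndarray                      # hours
    states: np.ndarray                 # (n_times, n_states)
    fluxes: dict[str, np.ndarray]
    params: ParameterSet
    anthropometry: Anthropometry
    schedule: DietSchedule
    flags: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, _IX[name]]

    def observable(self, kind: str) -> np.ndarray:
        from .fluxes import observable_map  # local import avoids a cycle
        return observable_map(self, kind)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.t >= window[0] - 1e-9) & (self.t <= window[1] + 1e-9)

    def to_frame(self):
        """Tidy (time, variable, value) DataFrame of states and fluxes."""
        import pandas as pd
        rows = []
        for name in STATE_NAMES:
            rows.append(pd.DataFrame(
                {"time_h": self.t, "variable": name, "value": self.state(name)}))
        for name, arr in self.fluxes.items():
            rows.append(pd.DataFrame(
                {"time_h": self.t, "variable": f"flux:{name}", "value": arr}))
        return pd.concat(rows, ignore_index=True)


def _flux_trajectories(t_min: np.ndarray, states: np.ndarray, params: ParameterSet,
                       anchor: BasalAnchor, u: ModelInput | None) -> dict[str, np.ndarray]:
    per_kg = 1000.0 / anchor.bw  # mmol/min -> umol/kg/min
    insulin_fluxes = {"insulin_secretion", "insulin_clearance_liver",
                      "insulin_clearance_periphery"}
    out = {name: np.empty(len(t_min)) for name in FLUX_NAMES}
    for i, (tm, row) in enumerate(zip(t_min, states)):
        f = compute_fluxes(tm, row, params, anchor, u)
        for name in FLUX_NAMES:
            out[name][i] = f[name] if name in insulin_fluxes else f[name] * per_kg
    return out


def _check_meals(schedule: DietSchedule) -> None:
    for m in schedule.meals:
        if m.kcal > 1000.0:
            warnings.warn(
                f"meal at {m.start_h:.1f} h has {m.kcal:.0f} kcal; responses to "
                "meals above ~1000 kcal are outside the supported range and may "
                "show non-physiological behaviour", stacklevel=3)


def simulate(
    params: ParameterSet,
    anthropometry: Anthropometry | None = None,
    schedule: DietSchedule | None = None,
    t_span: tuple[float, float] = (0.0, 24.0),
    init: np.ndarray | str = "basal",
    grid_minutes: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model over a protocol.

    Integration is restarted at every meal start/end so input
    discontinuities never straddle a solver step; output is returned on a
    regular grid (default 1-minute resolution).
    """
    anthropometry = anthropometry or Anthropometry()
    schedule = schedule if schedule is not None else empty_schedule(
        days=(t_span[1] - t_span[0]) / 24.0)
    _check_meals(schedule)
    anchor = build_anchor(params, anthropometry)
    u = to_input_signal(schedule)

    if isinstance(init, str):
        if init not in ("basal", "fed", "unfed"):
            raise ValueError(f"unknown init {init!r}")
        y0 = steady_state(params, anthropometry, fed=(init != "unfed"))
    else:
        y0 = np.asarray(init, dtype=float).copy()
        if y0.shape != (len(STATE_NAMES),):
            raise ValueError(f"init must have {len(STATE_NAMES)} entries")

    t0, t1 = t_span[0] * 60.0, t_span[1] * 60.0
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    for m in schedule.meals:
        if m.start_h * 60.0 < t0 - 1e-9 or m.end_h * 60.0 > t1 + 1e-9:
            raise ValueError(
                f"meal at {m.start_h} h lies outside the simulated span {t_span}")

    grid = np.arange(t0, t1 + 1e-9, grid_minutes)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    segments = u.breakpoints_min(t0, t1)

    states = np.empty((len(grid), len(STATE_NAMES)))
    y = y0.copy()
    gi = 0
    fun = lambda t, yy: rhs(t, yy, params, anchor, u)  # noqa: E731
    for s0, s1 in zip(segments, segments[1:]):
        in_seg = grid[(grid >= s0 - 1e-9) & (grid < s1 - 1e-9)]
        t_eval = np.unique(np.concatenate([in_seg, [s0, s1]]))
        sol = solve_ivp(fun, (s0, s1), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, max_step=(s1 - s0))
        if not sol.success:
            last = sol.t[-1] / 60.0 if len(sol.t) else s0 / 60.0
            raise SimulationError(
                f"solver failed in segment [{s0/60:.2f}, {s1/60:.2f}] h: "
                f"{sol.message} (last good time {last:.2f} h)", last_time_h=last)
        for tt, yy in zip(sol.t, sol.y.T):
            if gi < len(grid) and abs(tt - grid[gi]) < 1e-6 and tt < s1 - 1e-9:
                states[gi] = yy
                gi += 1
        y = sol.y[:, -1]
        y[(y < 0) & (y > -1e-6)] = 0.0  # solver undershoot of an empty pool
    # final point
    states[gi:] = y
    states[(states < 0) & (states > -1e-6)] = 0.0
    flags = {}
    if states.min() < -1e-9:
        worst = states.min()
        flags["negative_states"] = float(worst)
        warnings.warn(f"state went negative beyond tolerance (min {worst:.3e})",
                      stacklevel=2)

    fluxes = _flux_trajectories(grid, states, params, anchor, u)
    return SimulationResult(
        t=grid / 60.0, states=states, fluxes=fluxes, params=params,
        anthropometry=anthropometry, schedule=schedule, flags=flags)


def simulate_fixed_step(
    params: ParameterSet,
    anthropometry: Anthropometry | None = None,
    schedule: DietSchedule | None = None,
    t_span: tuple[float, float] = (0.0, 24.0),
    init: np.ndarray | str = "basal",
    dt_min: float = 0.25,
    grid_minutes: float = 1.0,
) -> SimulationResult:
    """Reference integration with a fixed-step classical Runge-Kutta scheme.

    Deliberately simple and solver-independent; used to cross-check the
    adaptive integrator on the same right-hand side.
    """
    anthropometry = anthropometry or Anthropometry()
    schedule = schedule if schedule is not None else empty_schedule(
        days=(t_span[1] - t_span[0]) / 24.0)
    anchor = build_anchor(params, anthropometry)
    u = to_input_signal(schedule)
    if isinstance(init, str):
        y = steady_state(params, anthropometry, fed=(init != "unfed"))
    else:
        y = np.asarray(init, dtype=float).copy()

    t0, t1 = t_span[0] * 60.0, t_span[1] * 60.0
    grid = np.arange(t0, t1 + 1e-9, grid_minutes)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    states = np.empty((len(grid), len(STATE_NAMES)))
    states[0] = y
    gi = 1

    segments = u.breakpoints_min(t0, t1)
    f = lambda t, yy: np.asarray(rhs(t, yy, params, anchor, u))  # noqa: E731
    for s0, s1 in zip(segments, segments[1:]):
        n_steps = max(1, int(math.ceil((s1 - s0) / dt_min)))
        h = (s1 - s0) / n_steps
        t = s0
        for _ in range(n_steps):
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            while gi < len(grid) and grid[gi] <= t + 1e-9:
                states[gi] = y  # grid aligned with steps when dt divides grid
                gi += 1
    states[gi:] = y
    fluxes = _flux_trajectories(grid, states, params, anchor, u)
    return SimulationResult(
        t=grid / 60.0, states=states, fluxes=fluxes, params=params,
        anthropometry=anthropometry, schedule=schedule)


@dataclass(frozen=True)
class DigitalTwin:
    """A parameter set bound to a subject: the personalised simulation unit."""

    params: ParameterSet
    anthropometry: Anthropometry = field(default_factory=Anthropometry)

    @classmethod
    def default(cls, anthropometry: Anthropometry | None = None) -> "DigitalTwin":
        anthropometry = anthropometry or Anthropometry()
        params = (ParameterSet.t2d() if anthropometry.diabetic
                  else ParameterSet.healthy())
        return cls(params=params, anthropometry=anthropometry)

    def simulate(self, schedule: DietSchedule | None = None,
                 t_span: tuple[float, float] = (0.0, 24.0), **kw) -> SimulationResult:
        return simulate(self.params, self.anthropometry, schedule, t_span, **kw)

    def steady_state(self, fed: bool = True) -> np.ndarray:
        return steady_state(self.params, self.anthropometry, fed=fed)
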