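"""Model parameters: 57 general parameters per population plus 5 personal ones.

The general parameters carry the population physiology (rate constants,
organ shares, saturation and inhibition constants).  Two complete variants
are shipped -- ``healthy`` and ``t2d`` -- selected by the diabetes flag.
The five personal parameters personalise a twin: basal glucose and insulin
levels, and multiplicative modifiers for insulin production, insulin
clearance and insulin resistance (1.0 = population default).

Every general parameter has declared lower/upper optimisation bounds;
``ParameterSet.validate`` enforces them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

__all__ = [
    "GENERAL_PARAMETERS",
    "PARAM_NAMES",
    "BOUNDS",
    "PersonalParameters",
    "ParameterSet",
]

# name: (healthy default, t2d default, lower, upper, unit, description)
GENERAL_PARAMETERS: dict[str, tuple[float, float, float, float, str, str]] = {
    # --- gut ---
    "k_stomach_carb":  (0.022, 0.022, 0.008, 0.12, "1/min", "gastric emptying rate of carbohydrate"),
    "k_absorb_carb":   (0.022, 0.022, 0.008, 0.12, "1/min", "intestinal glucose absorption rate"),
    "k_stomach_prot":  (0.025, 0.025, 0.004, 0.06, "1/min", "gastric emptying rate of protein"),
    "k_absorb_prot":   (0.020, 0.020, 0.003, 0.05, "1/min", "intestinal amino-acid absorption rate"),
    # --- distribution volumes (per kg body weight) ---
    "v_glucose_per_kg": (0.18, 0.18, 0.12, 0.26, "L/kg", "plasma glucose distribution volume"),
    "v_tissue_per_kg":  (0.08, 0.08, 0.04, 0.16, "L/kg", "interstitial glucose volume"),
    "v_liver_per_kg":   (0.021, 0.021, 0.012, 0.035, "L/kg", "liver tissue volume"),
    "v_kidney_per_kg":  (0.004, 0.004, 0.002, 0.008, "L/kg", "kidney tissue volume"),
    # --- insulin secretion and clearance ---
    "sec_hill":        (3.5, 1.6, 1.0, 6.0, "-", "glucose exponent of insulin secretion"),
    "sec_incretin":    (1.2, 0.6, 0.0, 5.0, "-", "oral (incretin) amplification of secretion per basal-turnover unit of meal glucose appearance"),
    "cl_insulin_liver": (0.40, 0.40, 0.10, 1.2, "1/min", "hepatic insulin degradation rate"),
    "cl_insulin_periphery": (0.05, 0.05, 0.015, 0.15, "1/min", "peripheral insulin degradation rate"),
    "liver_plasma_insulin_ratio": (1.5, 1.5, 1.05, 3.0, "-", "basal liver/plasma insulin ratio"),
    # --- basal glucose turnover and organ shares ---
    "egp_basal":       (10.0, 11.0, 6.0, 15.0, "umol/kg/min", "basal endogenous glucose production"),
    "f_uptake_brain":  (0.45, 0.45, 0.35, 0.55, "-", "basal uptake share, brain"),
    "f_uptake_muscle": (0.18, 0.18, 0.10, 0.30, "-", "basal uptake share, muscle"),
    "f_uptake_liver":  (0.12, 0.12, 0.08, 0.18, "-", "basal uptake share, liver"),
    "f_uptake_kidney": (0.07, 0.07, 0.04, 0.10, "-", "basal uptake share, kidney"),
    "f_uptake_other":  (0.18, 0.18, 0.08, 0.30, "-", "basal uptake share, other tissues"),
    "k_glucose_exchange": (0.065, 0.065, 0.02, 0.15, "1/min", "plasma-interstitium glucose exchange"),
    # --- uptake kinetics ---
    "km_uptake_kidney": (2.0, 2.0, 0.5, 6.0, "mmol/L", "renal uptake half-saturation"),
    "km_uptake_muscle": (3.0, 3.0, 1.0, 8.0, "mmol/L", "muscle uptake half-saturation"),
    "ins_frac_muscle":  (0.75, 0.55, 0.30, 0.95, "-", "insulin-dependent fraction of muscle uptake"),
    "ins_frac_other":   (0.40, 0.40, 0.10, 0.80, "-", "insulin-dependent fraction of other uptake"),
    "ins_frac_liver_uptake": (0.50, 0.50, 0.20, 0.80, "-", "insulin-dependent fraction of liver uptake"),
    # --- glucose production weights (basal shares of EGP) ---
    "w_glycogenolysis_liver": (0.46, 0.32, 0.20, 0.70, "-", "basal EGP share, hepatic glycogenolysis"),
    "w_gng_liver":            (0.45, 0.58, 0.20, 0.70, "-", "basal EGP share, hepatic gluconeogenesis"),
    "w_gng_kidney":           (0.07, 0.08, 0.02, 0.14, "-", "basal EGP share, renal gluconeogenesis"),
    "w_glycogenolysis_kidney": (0.02, 0.02, 0.005, 0.06, "-", "basal EGP share, renal glycogenolysis"),
    # --- production kinetics and insulin inhibition ---
    "km_glycogenolysis": (150.0, 150.0, 50.0, 400.0, "mmol/L", "glycogenolysis half-saturation in glycogen"),
    "ki_insulin_glycogenolysis": (80.0, 160.0, 30.0, 400.0, "pmol/L", "insulin inhibition constant, glycogenolysis"),
    "hill_insulin_glycogenolysis": (2.0, 2.0, 1.0, 4.0, "-", "insulin inhibition steepness, glycogenolysis"),
    "km_gng_pyruvate": (0.30, 0.30, 0.05, 0.8, "mmol/L", "gluconeogenesis half-saturation in pyruvate"),
    "ki_insulin_gng":  (150.0, 300.0, 50.0, 600.0, "pmol/L", "insulin inhibition constant, gluconeogenesis"),
    "hill_insulin_gng": (1.5, 1.5, 1.0, 4.0, "-", "insulin inhibition steepness, gluconeogenesis"),
    "km_glycogenolysis_kidney": (30.0, 30.0, 10.0, 100.0, "mmol/L", "renal glycogenolysis half-saturation"),
    "glycogen_ref":    (250.0, 200.0, 120.0, 350.0, "mmol/L", "reference (anchor) hepatic glycogen"),
    "glycogen_kidney_ref": (30.0, 30.0, 10.0, 80.0, "mmol/L", "reference renal glycogen"),
    # --- glycogen synthesis ---
    "v_glycogen_synthesis": (0.45, 0.30, 0.10, 1.5, "mmol/min", "maximal hepatic glycogen synthesis"),
    "km_synthesis_g6p": (1.0, 1.0, 0.3, 3.0, "mmol/L", "synthesis half-saturation in hepatic glucose pool"),
    "ins_frac_synthesis": (0.60, 0.60, 0.20, 0.90, "-", "insulin-dependent fraction of synthesis"),
    "glycogen_max":    (340.0, 300.0, 250.0, 600.0, "mmol/L", "glycogen level where synthesis shuts off"),
    # --- hepatic pool anchors ---
    "g6p_basal":       (0.20, 0.20, 0.05, 1.0, "mmol/L", "basal hepatic glucose-6-phosphate pool"),
    "pyruvate_basal":  (0.15, 0.15, 0.05, 0.5, "mmol/L", "basal hepatic pyruvate pool"),
    # --- amino-acid handling ---
    "aa_turnover":     (0.25, 0.25, 0.05, 0.8, "mmol/min", "endogenous protein turnover into hepatic amino acids"),
    "k_aa_catabolic":  (0.065, 0.065, 0.005, 0.15, "1/min", "amino-acid catabolism rate constant"),
    "k_aa_anabolic":   (0.050, 0.050, 0.010, 0.15, "1/min", "amino-acid anabolic removal rate constant"),
    "ins_frac_anabolic": (0.80, 0.80, 0.30, 0.95, "-", "insulin-dependent fraction of anabolic routing"),
    "frac_aa_to_pyruvate": (0.70, 0.70, 0.40, 0.95, "-", "catabolised amino acids routed to pyruvate"),
    "glycogen_switch_km": (120.0, 100.0, 50.0, 250.0, "mmol/L", "glycogen level of the energy-status switch"),
    "cat_floor":       (0.15, 0.15, 0.02, 0.5, "-", "fed-state floor of catabolic routing"),
    # --- pyruvate supply ---
    "frac_cori":       (0.60, 0.60, 0.20, 0.90, "-", "peripheral uptake recycled as pyruvate (Cori)"),
    "glycerol_supply": (0.15, 0.25, 0.02, 0.5, "mmol/min", "glycerol-derived pyruvate supply"),
    "muscle_deg_basal": (0.25, 0.45, 0.05, 0.9, "mmol/min", "basal muscle proteolysis (amino-acid flux)"),
    "ki_insulin_muscle_deg": (60.0, 90.0, 20.0, 200.0, "pmol/L", "insulin inhibition constant, proteolysis"),
    "mdeg_glycogen_floor": (0.55, 0.55, 0.05, 0.8, "-", "fed-state floor of proteolysis gating"),
    "muscle_protein_pool": (30000.0, 30000.0, 10000.0, 60000.0, "mmol", "mobilisable muscle protein reserve"),
}

PARAM_NAMES: tuple[str, ...] = tuple(GENERAL_PARAMETERS)
BOUNDS: dict[str, tuple[float, float]] = {k: (v[2], v[3]) for k, v in GENERAL_PARAMETERS.items()}

assert len(PARAM_NAMES) == 57, "general parameter roster must have 57 entries"


@dataclass(frozen=True)
class PersonalParameters:
    """Person-specific parameters.

    ``basal_glucose``/``basal_insulin`` set the subject's basal operating
    point; the three modifiers scale insulin production, clearance and
    resistance relative to the population (1.0 = default).
    """

    basal_glucose: float = 5.0     # mmol/L
    basal_insulin: float = 36.0    # pmol/L
    insulin_production: float = 1.0
    insulin_clearance: float = 1.0
    insulin_resistance: float = 1.0

    def __post_init__(self) -> None:
        if not 3.0 <= self.basal_glucose <= 15.0:
            raise ValueError(f"basal glucose {self.basal_glucose} outside [3, 15] mmol/L")
        if not 5.0 <= self.basal_insulin <= 500.0:
            raise ValueError(f"basal insulin {self.basal_insulin} outside [5, 500] pmol/L")
        for name in ("insulin_production", "insulin_clearance", "insulin_resistance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


_T2D_PERSONAL = PersonalParameters(basal_glucose=9.0, basal_insulin=60.0)


@dataclass(frozen=True)
class ParameterSet:
    """General + personal parameters for one population variant."""

    general: dict[str, float] = field(default_factory=dict)
    personal: PersonalParameters = field(default_factory=PersonalParameters)
    variant: str = "healthy"

    @classmethod
    def healthy(cls, **overrides: float) -> "ParameterSet":
        gen = {k: v[0] for k, v in GENERAL_PARAMETERS.items()}
        gen.update(overrides)
        return cls(general=gen, variant="healthy")

    @classmethod
    def t2d(cls, **overrides: float) -> "ParameterSet":
        gen = {k: v[1] for k, v in GENERAL_PARAMETERS.items()}
        gen.update(overrides)
        return cls(general=gen, personal=_T2D_PERSONAL, variant="t2d")

    @classmethod
    def for_variant(cls, variant: str) -> "ParameterSet":
        if variant == "healthy":
            return cls.healthy()
        if variant == "t2d":
            return cls.t2d()
        raise ValueError(f"unknown variant {variant!r}")

    def __getitem__(self, name: str) -> float:
        return self.general[name]

    def with_general(self, **overrides: float) -> "ParameterSet":
        gen = dict(self.general)
        gen.update(overrides)
        return replace(self, general=gen)

    def with_personal(self, **overrides: float) -> "ParameterSet":
        return replace(self, personal=replace(self.personal, **overrides))

    def validate(self) -> None:
        """Raise if any general parameter lies outside its declared bounds."""
        missing = set(PARAM_NAMES) - set(self.general)
        if missing:
            raise ValueError(f"missing general parameters: {sorted(missing)}")
        for name, value in self.general.items():
            lo, hi = BOUNDS[name]
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "general": dict(self.general),
            "personal": {
                "basal_glucose": self.personal.basal_glucose,
                "basal_insulin": self.personal.basal_insulin,
                "insulin_production": self.personal.insulin_production,
                "insulin_clearance": self.personal.insulin_clearance,
                "insulin_resistance": self.personal.insulin_resistance,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            general=dict(d["general"]),
            personal=PersonalParameters(**d.get("personal", {})),
            variant=d.get("variant", "healthy"),
        )

    def digest(self) -> str:
        """Short stable hash of the parameter values (reproducibility logs)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
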