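"""Physiological flux summaries: EGP decomposition, organ uptake shares,
insulin-clearance split and the observable mapping used by the cost function.

Window conventions (the field uses the labels loosely; these are this
package's definitions): "post-absorptive" is hours 10-14 of a fast after a
standard dinner, "postprandial" is 0-3 h after a standard ~700 kcal meal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import SimulationResult

__all__ = [
    "FluxBreakdown",
    "gng_fraction",
    "organ_uptake_fractions",
    "insulin_clearance_split",
    "observable_map",
    "OBSERVABLE_KINDS",
    "ORGANS",
]

ORGANS = ("brain", "muscle", "liver", "kidney", "other")

OBSERVABLE_KINDS = (
    "plasma_glucose",
    "plasma_insulin",
    "EGP",
    "hepatic_glycogen",
    "gng_fraction_of_EGP",
    "glycogenolysis_contribution",
)


@dataclass
class FluxBreakdown:
    """Glucose-production/disposal flux trajectories (umol/kg/min) plus the
    insulin clearance split (pmol/min).

    Satisfies EGP = HGP + RGP = gluconeogenesis + glycogenolysis exactly,
    because all five series are assembled from the same four source fluxes.
    """

    t: np.ndarray
    hgp: np.ndarray
    rgp: np.ndarray
    gng_liver: np.ndarray
    gng_kidney: np.ndarray
    glycogenolysis_liver: np.ndarray
    glycogenolysis_kidney: np.ndarray
    uptake: dict[str, np.ndarray]
    insulin_clearance_liver: np.ndarray
    insulin_clearance_periphery: np.ndarray
    insulin_secretion: np.ndarray
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def egp(self) -> np.ndarray:
        return self.hgp + self.rgp

    @property
    def gng(self) -> np.ndarray:
        return self.gng_liver + self.gng_kidney

    @property
    def glycogenolysis(self) -> np.ndarray:
        return self.glycogenolysis_liver + self.glycogenolysis_kidney

    @classmethod
    def from_simulation(cls, sim: SimulationResult,
                        windows: dict[str, tuple[float, float]] | None = None
                        ) -> "FluxBreakdown":
        f = sim.fluxes
        return cls(
            t=sim.t,
            hgp=f["hgp"], rgp=f["rgp"],
            gng_liver=f["gng_liver"], gng_kidney=f["gng_kidney"],
            glycogenolysis_liver=f["glycogenolysis_liver"],
            glycogenolysis_kidney=f["glycogenolysis_kidney"],
            uptake={o: f[f"uptake_{o}"] for o in ORGANS},
            insulin_clearance_liver=f["insulin_clearance_liver"],
            insulin_clearance_periphery=f["insulin_clearance_periphery"],
            insulin_secretion=f["insulin_secretion"],
            windows=dict(windows or {}),
        )

    def to_frame(self):
        import pandas as pd
        cols = {
            "time_h": self.t, "EGP": self.egp, "HGP": self.hgp, "RGP": self.rgp,
            "gluconeogenesis": self.gng, "glycogenolysis": self.glycogenolysis,
            "insulin_secretion": self.insulin_secretion,
            "insulin_clearance_liver": self.insulin_clearance_liver,
            "insulin_clearance_periphery": self.insulin_clearance_periphery,
        }
        for o in ORGANS:
            cols[f"uptake_{o}"] = self.uptake[o]
        return pd.DataFrame(cols)

    def _resolve(self, window) -> np.ndarray:
        if isinstance(window, str):
            if window not in self.windows:
                raise KeyError(
                    f"window label {window!r} not attached to this breakdown; "
                    f"available: {sorted(self.windows)}")
            window = self.windows[window]
        mask = (self.t >= window[0] - 1e-9) & (self.t <= window[1] + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        return mask


def _mean(t: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    tt, yy = t[mask], y[mask]
    if len(tt) < 2:
        return float(yy[0])
    return float(np.trapezoid(yy, tt) / (tt[-1] - tt[0]))


def gng_fraction(fluxes: FluxBreakdown, window) -> float:
    """Time-averaged gluconeogenic fraction of EGP over a window.

    Computed as integral(GNG)/integral(EGP), i.e. the study convention of
    dividing total gluconeogenesis (liver + kidney) by total glucose
    production over the interval.
    """
    mask = fluxes._resolve(window)
    egp = _mean(fluxes.t, fluxes.egp, mask)
    if egp <= 1e-12:
        raise ValueError("EGP is zero over the window; gng fraction undefined")
    return _mean(fluxes.t, fluxes.gng, mask) / egp


def organ_uptake_fractions(fluxes: FluxBreakdown, window) -> dict[str, float]:
    """Per-organ share of total glucose disposal, averaged over a window.

    ``window`` may be a (start_h, end_h) pair or a label such as
    "post-absorptive"/"postprandial" attached to the breakdown.
    Shares sum to 1.
    """
    mask = fluxes._resolve(window)
    means = {o: _mean(fluxes.t, fluxes.uptake[o], mask) for o in ORGANS}
    total = sum(means.values())
    if total <= 0:
        raise ValueError("total glucose uptake is zero over the window")
    return {o: v / total for o, v in means.items()}


def insulin_clearance_split(fluxes: FluxBreakdown, window) -> float:
    """Hepatic share of total insulin clearance, time-averaged over a window."""
    mask = fluxes._resolve(window)
    liver = _mean(fluxes.t, fluxes.insulin_clearance_liver, mask)
    rest = _mean(fluxes.t, fluxes.insulin_clearance_periphery, mask)
    if liver + rest <= 0:
        raise ValueError("total insulin clearance is zero over the window")
    return liver / (liver + rest)


def observable_map(sim: SimulationResult, kind: str) -> np.ndarray:
    """Simulated observable time series in the units of the study data."""
    if kind == "plasma_glucose":
        return sim.state("plasma_glucose")
    if kind == "plasma_insulin":
        return sim.state("plasma_insulin")
    if kind == "EGP":
        return sim.fluxes["egp"]
    if kind == "hepatic_glycogen":
        return sim.state("hepatic_glycogen")
    if kind == "gng_fraction_of_EGP":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sim.fluxes["egp"] > 1e-12,
                            sim.fluxes["gng_total"] / sim.fluxes["egp"], np.nan)
    if kind == "glycogenolysis_contribution":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sim.fluxes["egp"] > 1e-12,
                            sim.fluxes["glycogenolysis_total"] / sim.fluxes["egp"],
                            np.nan)
    raise KeyError(f"unknown observable kind {kind!r}; known: {OBSERVABLE_KINDS}")
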