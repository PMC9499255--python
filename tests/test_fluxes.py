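import numpy as np
import pytest

from glucotwin import (Anthropometry, ParameterSet, simulate, steady_state)
from glucotwin.fluxes import (FluxBreakdown, gng_fraction,
                              insulin_clearance_split, observable_map,
                              organ_uptake_fractions)
from glucotwin.model_core import STATE_NAMES, build_anchor, compute_fluxes
from glucotwin.protocols import PROTOCOL_PRESETS

_IX = {n: i for i, n in enumerate(STATE_NAMES)}


def _synthetic_breakdown(**over):
    n = 10
    t = np.linspace(0.0, 5.0, n)
    ones = np.ones(n)
    base = dict(
        t=t, gng_liver=3.0 * ones, gng_kidney=0.5 * ones,
        glycogenolysis_liver=4.0 * ones, glycogenolysis_kidney=0.2 * ones,
        uptake={o: ones.copy() for o in
                ("brain", "muscle", "liver", "kidney", "other")},
        insulin_clearance_liver=6.0 * ones,
        insulin_clearance_periphery=4.0 * ones,
        insulin_secretion=10.0 * ones,
    )
    base.update(over)
    base["hgp"] = base["gng_liver"] + base["glycogenolysis_liver"]
    base["rgp"] = base["gng_kidney"] + base["glycogenolysis_kidney"]
    return FluxBreakdown(**base)


class TestBookkeepingClosures:
    def test_production_closures_on_simulations(self, meal_sim, fast48_sim):
        for sim in (meal_sim, fast48_sim):
            fx = FluxBreakdown.from_simulation(sim)
            scale = np.abs(fx.egp).max()
            assert np.abs(fx.egp - (fx.hgp + fx.rgp)).max() < 1e-6 * scale
            assert np.abs(fx.egp - (fx.gng + fx.glycogenolysis)).max() < 1e-6 * scale

    def test_all_reaction_fluxes_nonnegative(self, meal_sim, fast48_sim):
        for sim in (meal_sim, fast48_sim):
            for name, arr in sim.fluxes.items():
                assert arr.min() >= -1e-9, name


class TestGngFraction:
    def test_pure_gluconeogenesis_gives_one(self):
        fx = _synthetic_breakdown(
            glycogenolysis_liver=np.zeros(10), glycogenolysis_kidney=np.zeros(10))
        assert gng_fraction(fx, (0.0, 5.0)) == pytest.approx(1.0)

    def test_pure_glycogenolysis_gives_zero(self):
        fx = _synthetic_breakdown(gng_liver=np.zeros(10),
                                  gng_kidney=np.zeros(10))
        assert gng_fraction(fx, (0.0, 5.0)) == pytest.approx(0.0)

    def test_zero_egp_is_an_error(self):
        fx = _synthetic_breakdown(
            gng_liver=np.zeros(10), gng_kidney=np.zeros(10),
            glycogenolysis_liver=np.zeros(10),
            glycogenolysis_kidney=np.zeros(10))
        with pytest.raises(ValueError, match="EGP"):
            gng_fraction(fx, (0.0, 5.0))

    def test_fraction_rises_with_fasting_and_diabetes(self):
        """After a meal-then-fast protocol the gluconeogenic share of EGP is
        substantially higher in the diabetic twin than the healthy one."""
        win = (4.0, 27.0)
        preset = PROTOCOL_PRESETS["meal_then_fast"]
        h = simulate(ParameterSet.healthy(), Anthropometry(),
                     preset["schedule"], preset["t_span"], init="basal")
        d = simulate(ParameterSet.t2d(), Anthropometry(diabetic=True),
                     preset["schedule"], preset["t_span"], init="basal")
        f_h = gng_fraction(FluxBreakdown.from_simulation(h), win)
        f_d = gng_fraction(FluxBreakdown.from_simulation(d), win)
        assert 0.50 <= f_h <= 0.85
        assert 0.65 <= f_d <= 0.95
        assert f_d > f_h + 0.05


class TestOrganUptake:
    def test_shares_sum_to_one(self, meal_sim):
        fx = FluxBreakdown.from_simulation(meal_sim)
        shares = organ_uptake_fractions(fx, (0.0, 3.0))
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_equal_fluxes_give_equal_shares(self):
        fx = _synthetic_breakdown()
        fx.uptake["other"] = np.zeros(10)
        shares = organ_uptake_fractions(fx, (0.0, 5.0))
        for organ in ("brain", "muscle", "liver", "kidney"):
            assert shares[organ] == pytest.approx(0.25)

    def test_post_absorptive_brain_share_in_reported_band(self, fast48_sim):
        fx = FluxBreakdown.from_simulation(fast48_sim)
        shares = organ_uptake_fractions(fx, (10.0, 14.0))
        assert 0.40 <= shares["brain"] <= 0.50
        assert 0.15 <= shares["muscle"] <= 0.20
        assert 0.10 <= shares["liver"] <= 0.15
        assert 0.05 <= shares["kidney"] <= 0.10


class TestInsulinClearance:
    def test_all_hepatic_clearance_gives_one(self):
        fx = _synthetic_breakdown(insulin_clearance_periphery=np.zeros(10))
        assert insulin_clearance_split(fx, (0.0, 5.0)) == pytest.approx(1.0)

    def test_default_twin_liver_share_in_plausible_band(self, fast48_sim):
        fx = FluxBreakdown.from_simulation(fast48_sim)
        share = insulin_clearance_split(fx, (10.0, 14.0))
        assert 0.40 <= share          # hard physiological floor
        assert 0.50 <= share <= 0.80  # literature plausibility band


class TestObservableMap:
    def test_plasma_glucose_is_identity(self, meal_sim):
        np.testing.assert_array_equal(
            observable_map(meal_sim, "plasma_glucose"),
            meal_sim.state("plasma_glucose"))

    def test_egp_equals_hgp_plus_rgp(self, meal_sim):
        egp = observable_map(meal_sim, "EGP")
        np.testing.assert_allclose(
            egp, meal_sim.fluxes["hgp"] + meal_sim.fluxes["rgp"], rtol=1e-12)

    def test_gng_fraction_series_consistent_with_window_average(self, fast48_sim):
        """EGP-weighted average of the pointwise fraction equals the
        windowed gng_fraction computed from integrals."""
        fx = FluxBreakdown.from_simulation(fast48_sim)
        series = observable_map(fast48_sim, "gng_fraction_of_EGP")
        win = (6.0, 30.0)
        m = fast48_sim.window_mask(win)
        weighted = (np.trapezoid(series[m] * fx.egp[m], fast48_sim.t[m])
                    / np.trapezoid(fx.egp[m], fast48_sim.t[m]))
        assert weighted == pytest.approx(gng_fraction(fx, win), rel=1e-9)

    def test_unknown_kind_raises(self, meal_sim):
        with pytest.raises(KeyError):
            observable_map(meal_sim, "lactate")


class TestInsulinInhibition:
    def test_raising_insulin_never_increases_production_fluxes(
            self, healthy_params, anthro):
        anchor = build_anchor(healthy_params, anthro)
        y = steady_state(healthy_params, anthro)
        lo = compute_fluxes(0.0, y, healthy_params, anchor, None)
        y_hi = y.copy()
        y_hi[_IX["plasma_insulin"]] *= 5.0
        y_hi[_IX["liver_insulin"]] *= 5.0
        hi = compute_fluxes(0.0, y_hi, healthy_params, anchor, None)
        assert hi["gng_liver"] <= lo["gng_liver"]
        assert hi["gng_kidney"] <= lo["gng_kidney"]
        assert hi["glycogenolysis_liver"] <= lo["glycogenolysis_liver"]
        assert hi["glycogenolysis_kidney"] <= lo["glycogenolysis_kidney"]
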