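import numpy as np
import pytest

from glucotwin import (DietSchedule, MealEvent, ParameterSet,
                       SimulationError, simulate, simulate_fixed_step,
                       steady_state)
from glucotwin.model_core import (STATE_NAMES, build_anchor, compute_fluxes,
                                  rhs)

_IX = {n: i for i, n in enumerate(STATE_NAMES)}


class TestSteadyState:
    def test_fast_states_are_a_fixed_point(self, healthy_params, anthro):
        """At the anchored basal point every fast state has zero derivative;
        the slow stores drain at bounded physiological rates."""
        y0 = steady_state(healthy_params, anthro)
        anchor = build_anchor(healthy_params, anthro)
        dy = rhs(0.0, y0, healthy_params, anchor, None)
        slow = {"hepatic_glycogen", "muscle_protein"}
        for name, d in zip(STATE_NAMES, dy):
            if name in slow:
                continue
            assert abs(d) < 1e-10, f"{name} derivative {d} at basal"
        # hepatic glycogen drains, but below ~0.5 mmol/L/min
        assert -0.5 < dy[_IX["hepatic_glycogen"]] <= 0.0

    def test_requested_basal_values_are_honoured(self, healthy_params, anthro):
        y = steady_state(healthy_params, anthro, basal_glucose=5.0,
                         basal_insulin=40.0)
        assert y[_IX["plasma_glucose"]] == pytest.approx(5.0)
        assert y[_IX["plasma_insulin"]] == pytest.approx(40.0)

    def test_fed_start_glycogen_inside_fed_window(self, healthy_params, anthro):
        y = steady_state(healthy_params, anthro, fed=True)
        assert 200.0 <= y[_IX["hepatic_glycogen"]] <= 350.0

    def test_one_hour_basal_drift_is_small(self, healthy_params, anthro):
        y0 = steady_state(healthy_params, anthro)
        sim = simulate(healthy_params, anthro, None, (0.0, 1.0), init=y0)
        dG = abs(sim.state("plasma_glucose")[-1] - y0[_IX["plasma_glucose"]])
        assert dG < 0.05

    def test_nonphysiological_basal_rejected(self, healthy_params, anthro):
        with pytest.raises(ValueError):
            steady_state(healthy_params, anthro, basal_glucose=20.0)

    def test_infeasible_balance_names_the_constraint(self, anthro):
        # synthesis demand above basal hepatic uptake leaves no glycolysis
        p = ParameterSet.healthy(v_glycogen_synthesis=1.5)
        with pytest.raises(ValueError, match="glycogen synthesis"):
            steady_state(p, anthro)


class TestRhs:
    def test_empty_stores_produce_nothing(self, healthy_params, anthro):
        anchor = build_anchor(healthy_params, anthro)
        y = steady_state(healthy_params, anthro)
        y[_IX["hepatic_glycogen"]] = 0.0
        y[_IX["renal_glycogen"]] = 0.0
        f = compute_fluxes(0.0, y, healthy_params, anchor, None)
        assert f["glycogenolysis_liver"] == 0.0
        assert f["glycogenolysis_kidney"] == 0.0
        assert f["ra_meal_glucose"] == 0.0  # gut is empty too

    def test_insulin_resistance_reduces_insulin_dependent_uptake(
            self, healthy_params, anthro):
        anchor = build_anchor(healthy_params, anthro)
        y = steady_state(healthy_params, anthro)
        f_base = compute_fluxes(0.0, y, healthy_params, anchor, None)
        doubled = healthy_params.with_personal(insulin_resistance=2.0)
        f_res = compute_fluxes(0.0, y, doubled, anchor, None)
        assert f_res["uptake_muscle"] < f_base["uptake_muscle"]
        assert f_res["uptake_other"] < f_base["uptake_other"]

    def test_nonfinite_state_raises_blowup_error(self, healthy_params, anthro):
        anchor = build_anchor(healthy_params, anthro)
        y = steady_state(healthy_params, anthro)
        y[_IX["plasma_glucose"]] = np.inf
        with pytest.raises(SimulationError):
            rhs(0.0, y, healthy_params, anchor, None)


class TestSimulate:
    def test_meal_carbohydrate_mass_is_conserved(self, meal_sim, anthro):
        """Cumulative glucose appearance equals the 87 g eaten (0.1%)."""
        ra = meal_sim.fluxes["ra_meal_glucose"] * anthro.weight_kg / 1000.0
        absorbed_mmol = np.trapezoid(ra, meal_sim.t * 60.0)
        assert absorbed_mmol * 0.180156 == pytest.approx(87.0, rel=1e-3)

    def test_meal_protein_mass_is_conserved(self, meal_sim, anthro):
        aa = meal_sim.fluxes["aa_absorption"] * anthro.weight_kg / 1000.0
        absorbed_mmol = np.trapezoid(aa, meal_sim.t * 60.0)
        assert absorbed_mmol * 0.110 == pytest.approx(23.0, rel=2e-3)

    def test_fast_glucose_declines_from_finite_stores(self, fast48_sim):
        G = fast48_sim.state("plasma_glucose")
        t = fast48_sim.t
        assert G.max() <= G[0] + 1e-6          # monotone non-increase
        assert G[t >= 48.0][-1] < G[np.searchsorted(t, 12.0)]
        gly = fast48_sim.state("hepatic_glycogen")
        assert np.all(np.diff(gly) <= 1e-9)    # store only drains

    def test_states_stay_nonnegative_and_finite(self, fast48_sim, meal_sim,
                                                week_sim):
        for sim in (fast48_sim, meal_sim, week_sim):
            assert np.isfinite(sim.states).all()
            assert sim.states.min() >= -1e-9

    def test_adaptive_solver_matches_fixed_step_reference(
            self, healthy_params, anthro):
        """LSODA with meal-boundary restarts agrees with a plain fixed-step
        RK4 integration of the same right-hand side to within 0.5%."""
        sched = DietSchedule(
            meals=(MealEvent(1.0, carb_g=87.0, protein_g=23.0, fat_g=20.0),),
            horizon_days=0.5)
        a = simulate(healthy_params, anthro, sched, (0.0, 12.0), init="basal")
        b = simulate_fixed_step(healthy_params, anthro, sched, (0.0, 12.0),
                                init="basal", dt_min=0.25)
        for kind in ("plasma_glucose", "plasma_insulin", "hepatic_glycogen"):
            ya, yb = a.state(kind), b.state(kind)
            rel = np.abs(ya - yb).max() / np.abs(ya).max()
            assert rel < 5e-3, f"{kind} mismatch {rel:.2e}"
        rel = (np.abs(a.fluxes["egp"] - b.fluxes["egp"]).max()
               / np.abs(a.fluxes["egp"]).max())
        assert rel < 5e-3

    def test_meal_outside_span_is_an_error(self, healthy_params, anthro):
        sched = DietSchedule(meals=(MealEvent(30.0, carb_g=50.0),),
                             horizon_days=2.0)
        with pytest.raises(ValueError, match="outside"):
            simulate(healthy_params, anthro, sched, (0.0, 24.0))

    def test_oversized_meal_triggers_warning(self, healthy_params, anthro):
        sched = DietSchedule(
            meals=(MealEvent(1.0, carb_g=200.0, protein_g=60.0, fat_g=60.0),),
            horizon_days=0.5)
        with pytest.warns(UserWarning, match="kcal"):
            simulate(healthy_params, anthro, sched, (0.0, 6.0),
                     grid_minutes=5.0)

    def test_time_grid_is_strictly_increasing_and_aligned(self, meal_sim):
        assert np.all(np.diff(meal_sim.t) > 0)
        assert len(meal_sim.t) == meal_sim.states.shape[0]
        assert meal_sim.t[0] == 0.0 and meal_sim.t[-1] == pytest.approx(14.0)
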