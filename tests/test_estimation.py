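import numpy as np
import pandas as pd
import pytest

from glucotwin import (Anthropometry, ParameterSet, chi2_test, chi2_threshold,
                       cost, ensemble_bands, evaluate_penalties, fit_global,
                       sem, simulate)
from glucotwin.estimation import PENALTY_CONSTANT, StudyDataset
from glucotwin.fluxes import FluxBreakdown
from glucotwin.study_fixtures import generate_study, standard_meal_fixture


class TestSem:
    @pytest.mark.parametrize("sigma, n, expected", [(2, 4, 1.0), (0, 5, 0.0),
                                                    (3, 9, 1.0)])
    def test_sigma_over_root_n(self, sigma, n, expected):
        assert sem(sigma, n) == pytest.approx(expected)

    def test_invalid_replicate_count(self):
        with pytest.raises(ValueError):
            sem(1.0, 0)


class TestChi2:
    @pytest.mark.parametrize("dof, printed", [
        (126, 153), (190, 223), (83, 105), (14, 24), (35, 50), (44, 60)])
    def test_thresholds_match_printed_values(self, dof, printed):
        assert round(chi2_threshold(0.05, dof)) == printed

    @pytest.mark.parametrize("cost_value, dof, verdict", [
        (175, 190, True),   # healthy-estimation verdict
        (300, 190, False),
        (61, 83, True),     # diabetic-estimation verdict
    ])
    def test_verdicts(self, cost_value, dof, verdict):
        assert chi2_test(cost_value, dof) is verdict

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            chi2_threshold(0.0, 10)
        with pytest.raises(ValueError):
            chi2_threshold(0.05, 0)


def _dataset_from_sim(sim, times, observable="plasma_glucose", offset=0.0,
                      semv=1.0):
    yhat = np.interp(times, sim.t, sim.observable(observable))
    records = pd.DataFrame({
        "time_h": times, "observable": observable, "value": yhat + offset,
        "sd": semv, "n": 1, "sem": semv,
    })
    return StudyDataset("unit", "healthy", records, sim.schedule,
                        (sim.t[0], sim.t[-1]))


class TestCost:
    def test_perfect_agreement_costs_zero(self, meal_sim):
        ds = _dataset_from_sim(meal_sim, np.array([1.0, 2.0, 5.0]))
        assert cost(ds, meal_sim) == pytest.approx(0.0, abs=1e-18)

    def test_one_sem_residual_per_record_costs_n(self, meal_sim):
        times = np.array([0.5, 2.0, 4.0, 8.0])
        ds = _dataset_from_sim(meal_sim, times, offset=1.0, semv=1.0)
        assert cost(ds, meal_sim) == pytest.approx(len(times))

    def test_single_point_arithmetic(self, meal_sim):
        ds = _dataset_from_sim(meal_sim, np.array([3.0]), offset=2.0, semv=1.0)
        assert cost(ds, meal_sim) == pytest.approx(4.0)

    def test_zero_sem_record_is_rejected(self, meal_sim):
        ds = _dataset_from_sim(meal_sim, np.array([1.0]))
        ds.records.loc[:, "sem"] = 0.0
        with pytest.raises(ValueError, match="SEM"):
            cost(ds, meal_sim)

    def test_sem_floor_lifts_tiny_errors(self, meal_sim):
        times = np.array([1.0, 2.0, 3.0, 6.0])
        ds = _dataset_from_sim(meal_sim, times, semv=1e-6)
        floored = ds.floor_sems(0.05)
        rng = ds.records["value"].max() - ds.records["value"].min()
        assert (floored.records["sem"] >= 0.05 * rng - 1e-12).all()


class TestPenalties:
    def test_compliant_simulation_has_zero_penalty(self, week_sim, fast48_sim):
        pen, report = evaluate_penalties(
            fast48_sim, fast_window=(46.0, 48.0),
            post_absorptive_window=(10.0, 14.0))
        assert pen == 0.0 and all(report.values())
        pen, report = evaluate_penalties(week_sim, fed_window=(164.0, 166.0))
        assert pen == 0.0 and all(report.values())

    def test_insulin_excursion_flags_constraint(self, meal_sim):
        import copy
        doctored = copy.copy(meal_sim)
        doctored.states = meal_sim.states.copy()
        doctored.states[:, 6] *= 100.0  # plasma insulin above 3000 pmol/L
        pen, report = evaluate_penalties(doctored)
        assert not report["insulin_below_3000"]
        assert pen >= PENALTY_CONSTANT

    def test_renal_overproduction_flags_constraint(self, meal_sim):
        fx = FluxBreakdown.from_simulation(meal_sim)
        fx.rgp = fx.hgp.copy()  # renal share 50% of EGP
        pen, report = evaluate_penalties(meal_sim, fluxes=fx)
        assert not report["rgp_below_40pct"]
        assert pen >= PENALTY_CONSTANT

    def test_fed_glycogen_window_violation(self, fast48_sim):
        # at the end of a 48 h fast the store is far below the fed window
        pen, report = evaluate_penalties(fast48_sim, fed_window=(46.0, 48.0))
        assert not report["fed_glycogen_window"]
        assert pen >= PENALTY_CONSTANT


@pytest.fixture(scope="module")
def fixture_dataset():
    spec = standard_meal_fixture(seed=11)
    ds, truth = generate_study(spec)
    return spec, ds


_TINY = dict(preset="smoke", swarm_size=8, max_iters=4, polish=False,
             grid_minutes=4.0)


class TestFitGlobal:
    def test_same_seed_reproduces_best_cost(self, fixture_dataset):
        _, ds = fixture_dataset
        free = ("k_absorb_carb", "sec_hill")
        a = fit_global([ds], free_params=free, seed=5, **_TINY)
        b = fit_global([ds], free_params=free, seed=5, **_TINY)
        assert a.best_cost == b.best_cost
        np.testing.assert_array_equal(a.best_x, b.best_x)

    def test_reported_cost_excludes_penalties(self, fixture_dataset):
        """The chi-square verdict must audit the unpenalised cost."""
        _, ds = fixture_dataset
        fit = fit_global([ds], free_params=("k_absorb_carb",), seed=1, **_TINY)
        ps = fit.parameter_set()
        sim = simulate(ps, Anthropometry(), ds.protocol, ds.t_span,
                       grid_minutes=4.0)
        assert fit.best_cost == pytest.approx(cost(ds, sim), rel=1e-9)
        assert fit.best_cost < PENALTY_CONSTANT

    def test_population_mismatch_rejected(self, fixture_dataset):
        _, ds = fixture_dataset
        with pytest.raises(ValueError, match="population"):
            fit_global([ds], population="t2d", **_TINY)

    def test_inverted_bounds_rejected(self, fixture_dataset):
        _, ds = fixture_dataset
        with pytest.raises(ValueError, match="bounds"):
            fit_global([ds], free_params=("sec_hill",),
                       bounds={"sec_hill": (5.0, 1.0)}, **_TINY)

    def test_smoke_fit_passes_chi2_on_fixture(self, fixture_dataset):
        """Self-consistency: fitting the generator's own model family to a
        fixture study reaches a chi-square-acceptable cost."""
        _, ds = fixture_dataset
        fit = fit_global([ds], free_params=("k_absorb_carb", "sec_hill"),
                         preset="smoke", swarm_size=12, max_iters=10,
                         seed=2, grid_minutes=3.0)
        assert fit.chi2_pass
        assert len(fit.ensemble) > 0
        assert (fit.ensemble_costs <= fit.threshold).all()


class TestEnsembleBands:
    """Band properties on a hand-built accepted ensemble (parameter vectors
    perturbed around the defaults)."""

    @staticmethod
    def _fit_with_ensemble(ds, members):
        from glucotwin.estimation import FitResult
        members = np.asarray(members, dtype=float)
        return FitResult(
            param_names=("k_absorb_carb", "sec_hill"),
            best_x=members[0].copy(), best_cost=0.0, best_penalty=0.0,
            ensemble=members, ensemble_costs=np.zeros(len(members)),
            per_study_costs={}, dof=ds.n_points,
            threshold=chi2_threshold(0.05, ds.n_points), chi2_pass=True,
            penalty_report={}, n_evaluations=0, seed=0,
            base=ParameterSet.healthy())

    def test_band_collapses_for_singleton_ensemble(self, fixture_dataset):
        _, ds = fixture_dataset
        fit = self._fit_with_ensemble(ds, [[0.022, 3.5]])
        bands = ensemble_bands(fit, ds.protocol, ds.t_span,
                               observables=("plasma_glucose",),
                               grid_minutes=4.0)
        b = bands["plasma_glucose"]
        member = simulate(fit.parameter_set(fit.ensemble[0]), Anthropometry(),
                          ds.protocol, ds.t_span, grid_minutes=4.0)
        np.testing.assert_allclose(b["lo"], b["hi"])
        np.testing.assert_allclose(b["lo"], member.state("plasma_glucose"))

    def test_larger_ensemble_never_narrows_the_band(self, fixture_dataset):
        _, ds = fixture_dataset
        members = [[0.020, 3.3], [0.022, 3.5], [0.025, 3.8]]
        small = self._fit_with_ensemble(ds, members[:2])
        big = self._fit_with_ensemble(ds, members)
        kw = dict(observables=("plasma_glucose",), grid_minutes=4.0)
        b_small = ensemble_bands(small, ds.protocol, ds.t_span, **kw)
        b_big = ensemble_bands(big, ds.protocol, ds.t_span, **kw)
        assert (b_big["plasma_glucose"]["lo"]
                <= b_small["plasma_glucose"]["lo"] + 1e-12).all()
        assert (b_big["plasma_glucose"]["hi"]
                >= b_small["plasma_glucose"]["hi"] - 1e-12).all()

    def test_every_member_lies_inside_the_band(self, fixture_dataset):
        _, ds = fixture_dataset
        members = [[0.020, 3.3], [0.025, 3.8]]
        fit = self._fit_with_ensemble(ds, members)
        b = ensemble_bands(fit, ds.protocol, ds.t_span,
                           observables=("plasma_glucose",),
                           grid_minutes=4.0)["plasma_glucose"]
        for m in members:
            traj = simulate(fit.parameter_set(np.array(m)), Anthropometry(),
                            ds.protocol, ds.t_span,
                            grid_minutes=4.0).state("plasma_glucose")
            assert (b["lo"] <= traj + 1e-12).all()
            assert (traj <= b["hi"] + 1e-12).all()

    def test_empty_ensemble_is_an_error(self, fixture_dataset):
        _, ds = fixture_dataset
        fit = self._fit_with_ensemble(ds, [[0.022, 3.5]])
        fit.ensemble = fit.ensemble[:0]
        with pytest.raises(ValueError, match="empty"):
            ensemble_bands(fit, ds.protocol, ds.t_span)
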