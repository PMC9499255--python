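import pytest
from hypothesis import HealthCheck, settings

from glucotwin import (Anthropometry, DietSchedule, DigitalTwin, MealEvent,
                       ParameterSet, simulate)

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_params():
    p = ParameterSet.healthy()
    p.validate()
    return p


@pytest.fixture(scope="session")
def t2d_params():
    p = ParameterSet.t2d()
    p.validate()
    return p


@pytest.fixture(scope="session")
def anthro():
    return Anthropometry(sex="male", weight_kg=80.0, height_m=1.80)


@pytest.fixture(scope="session")
def twin(healthy_params, anthro):
    return DigitalTwin(params=healthy_params, anthropometry=anthro)


@pytest.fixture(scope="session")
def fast48_sim(healthy_params, anthro):
    """48 h fast from the fed basal state, 1-min grid."""
    return simulate(healthy_params, anthro, None, (0.0, 48.0), init="basal")


@pytest.fixture(scope="session")
def meal_sim(healthy_params, anthro):
    """Mixed meal (87 g carbohydrate / 23 g protein) at t = 1 h, 14 h span."""
    sched = DietSchedule(
        meals=(MealEvent(1.0, carb_g=87.0, protein_g=23.0, fat_g=20.0),),
        horizon_days=1.0)
    return simulate(healthy_params, anthro, sched, (0.0, 14.0), init="basal")


@pytest.fixture(scope="session")
def week_sim(healthy_params, anthro):
    """Seven standard diet days (3 meals/day, 2000 kcal), 2-min grid."""
    from glucotwin import build_diet
    sched = build_diet("SFM", 2000.0, days=7)
    return simulate(healthy_params, anthro, sched, (0.0, 168.0), init="basal",
                    grid_minutes=2.0)


@pytest.fixture(scope="session")
def week_sim_t2d(t2d_params):
    from glucotwin import build_diet
    sched = build_diet("SFM", 2000.0, days=7)
    return simulate(t2d_params, Anthropometry(diabetic=True), sched,
                    (0.0, 168.0), init="basal", grid_minutes=2.0)


@pytest.fixture(scope="session")
def fast48_sim_t2d(t2d_params):
    return simulate(t2d_params, Anthropometry(diabetic=True), None,
                    (0.0, 48.0), init="basal")


@pytest.fixture(scope="session")
def optt_result(twin):
    from glucotwin import run_optt_fast_optt
    return run_optt_fast_optt(twin)
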