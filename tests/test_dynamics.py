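"""Develop/mutate phase dynamics: rates, attractors, eliminations, transfers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evosoc.dynamics import (
    EnvironmentParams,
    ScenarioConfig,
    SocietyState,
    competing_strength,
    derivative,
    develop,
    eligible_targets,
    environmental_restriction,
    mutate,
    step,
)
from evosoc.network import equilibrium_productivity, spectral_radius_and_perron

from conftest import make_config, random_irreducible

CYCLE2 = np.array([[0.0, 1.0], [1.0, 0.0]])


def test_competing_strength():
    np.testing.assert_allclose(competing_strength([50.0, 50.0], CYCLE2, 100.0), [5000.0, 5000.0])
    # an unsupported occupation (all-zero row) wields no strength
    assert competing_strength([1.0, 1.0], np.array([[0, 0], [1, 0]]), 10.0)[0] == 0.0
    # inactive supporters (x=0) contribute nothing
    assert competing_strength([50.0, 0.0], CYCLE2, 100.0)[0] == 0.0
    with pytest.raises(ValueError):
        competing_strength([1.0], CYCLE2, 1.0)


def test_environmental_restriction_is_linear():
    assert environmental_restriction(100.0, 1.0) == 100.0
    assert environmental_restriction(0.0, 2.0) == 0.0
    assert environmental_restriction(200.0, 1.0) == 2 * environmental_restriction(100.0, 1.0)
    with pytest.raises(ValueError):
        environmental_restriction(-1.0, 1.0)


@pytest.mark.parametrize("rate_form", ["ratio", "product"])
def test_derivative_zero_at_equilibrium(rate_form):
    C = random_irreducible(6, 0.5, 3)
    env = EnvironmentParams(a=100.0, b=1.0)
    x = equilibrium_productivity(C, env.a, env.b)
    f = derivative(x, C, env, rate_form=rate_form)
    assert np.max(np.abs(f)) < 1e-6


def test_derivative_closed_forms():
    env = EnvironmentParams(a=100.0, b=1.0)
    # single self-supporter: dx/dt = a - b x
    f = derivative(np.array([50.0]), np.array([[1.0]]), env)
    assert f[0] == pytest.approx(100.0 - 50.0)
    # an active occupation nobody supports always declines at rate -bX
    f = derivative(np.array([5.0, 5.0]), np.array([[0, 0], [1, 0]], dtype=float), env)
    assert f[0] == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        derivative(np.array([0.0]), np.array([[1.0]]), env, active=np.array([True]))


# --- develop ----------------------------------------------------------------


@pytest.mark.parametrize("method", ["relax", "euler"])
@pytest.mark.parametrize("rate_form", ["ratio", "product"])
def test_develop_reaches_closed_form_attractors(method, rate_form):
    cfg = make_config(method=method, rate_form=rate_form, limina=0.01)
    env = cfg.env()
    out = develop(SocietyState.from_x([1.0]), np.array([[1.0]]), env, cfg)
    assert out.x[0] == pytest.approx(100.0, rel=1e-6)
    out = develop(SocietyState.from_x([1.0, 1.0]), CYCLE2, env, cfg)
    np.testing.assert_allclose(out.x, [50.0, 50.0], rtol=1e-6)


@pytest.mark.parametrize("method", ["relax", "euler"])
@pytest.mark.parametrize("rate_form", ["ratio", "product"])
def test_develop_matches_eigen_oracle_on_random_fixture(method, rate_form):
    C = random_irreducible(8, 0.4, 17)
    cfg = make_config(method=method, rate_form=rate_form, limina=1e-6)
    xstar = equilibrium_productivity(C, 100.0, 1.0)
    out = develop(SocietyState.from_x(np.full(8, 3.0)), C, cfg.env(), cfg)
    np.testing.assert_allclose(out.x, xstar, rtol=1e-6)


def test_develop_eliminates_unsupported_and_reequilibrates():
    # occupation 1 has no supporter: it starves; occupation 0 re-equilibrates
    C = np.array([[1.0, 0.0], [0.0, 0.0]])
    cfg = make_config(limina=1.0)
    out = develop(SocietyState.from_x([2.0, 2.0]), C, cfg.env(), cfg)
    assert not out.active[1] and out.x[1] == 0.0
    assert out.x[0] == pytest.approx(100.0, rel=1e-6)


def test_develop_extinct_state_is_flagged_not_raised():
    C = np.zeros((2, 2))
    cfg = make_config(limina=1.0)
    out = develop(SocietyState.from_x([2.0, 2.0]), C, cfg.env(), cfg)
    assert out.extinct and np.all(out.x == 0)
    # developing an extinct state is a no-op
    again = develop(out, C, cfg.env(), cfg)
    assert again.extinct


def test_develop_never_increases_active_count():
    rng = np.random.default_rng(0)
    cfg = make_config(limina=1.0)
    for seed in range(10):
        n = int(rng.integers(3, 10))
        C = (np.random.default_rng(seed).random((n, n)) < 0.4).astype(float)
        x = 1.0 + 5 * np.random.default_rng(seed + 50).random(n)
        st = SocietyState.from_x(x)
        out = develop(st, C, cfg.env(), cfg)
        assert out.n_active <= st.n_active
        # phase-boundary invariant: functioning or gone
        assert np.all((out.x == 0) | (out.x >= cfg.limina - 1e-12))


def test_shared_environment_competition_selects_larger_spectral_radius():
    """Two non-interacting blocks: the lower-lambda block is driven extinct."""
    A = np.ones((2, 2))  # lambda = 2
    B = CYCLE2  # lambda = 1
    C = np.zeros((4, 4))
    C[:2, :2], C[2:, 2:] = A, B
    cfg = make_config(limina=0.5)
    out = develop(SocietyState.from_x([10.0, 10.0, 10.0, 10.0]), C, cfg.env(), cfg)
    assert out.total == pytest.approx(100.0 * 2.0, rel=1e-6)
    assert not out.active[2:].any() and out.active[:2].all()


# --- eligible targets and mutation -------------------------------------------


def test_eligible_targets_follow_active_support():
    # occupation 0 supports 1 and 2; only 0 active
    C = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 0]], dtype=float)
    st = SocietyState.from_x([5.0, 0.0, 0.0])
    assert set(eligible_targets(st, C, source=0)) == {1, 2}
    # nobody active supports anything
    st2 = SocietyState(np.array([0.0, 0.0, 5.0]), np.array([False, False, True]))
    assert eligible_targets(st2, C, source=2).size == 0
    # fully active complete society: all non-source indices
    C4 = np.ones((4, 4))
    st3 = SocietyState.from_x(np.full(4, 5.0))
    assert set(eligible_targets(st3, C4, source=1)) == {0, 2, 3}


def test_mutate_conserves_total_and_respects_threshold(rng):
    C = np.ones((5, 5))
    cfg = make_config(p_m=1.0, limina=1.0)
    st = SocietyState.from_x(np.array([5.0, 3.0, 2.5, 0.0, 0.0]))
    out, events = mutate(st, C, cfg, rng)
    assert out.total == pytest.approx(st.total, rel=1e-12)
    assert events  # p_m=1 with eligible sources must fire
    for ev in events:
        assert ev.amount == cfg.limina and ev.source != ev.target
    assert np.all((out.x == 0) | (out.x >= cfg.limina - 1e-12))


def test_mutate_source_at_one_and_a_half_limina_cannot_fire(rng):
    C = np.ones((3, 3))
    cfg = make_config(p_m=1.0, limina=1.0)
    st = SocietyState.from_x(np.array([1.5, 0.0, 0.0]))
    out, events = mutate(st, C, cfg, rng)
    assert events == [] and np.all(out.x == st.x)
    # strictly-greater rule: exactly 2*limina still cannot fire
    st2 = SocietyState.from_x(np.array([2.0, 0.0, 0.0]))
    _, events2 = mutate(st2, C, cfg, rng)
    assert events2 == []


def test_mutate_creates_target_at_exactly_limina():
    C = np.ones((3, 3))
    cfg = make_config(p_m=1.0, limina=1.0)
    st = SocietyState.from_x(np.array([9.0, 0.0, 0.0]))
    out, events = mutate(st, C, cfg, np.random.default_rng(0))
    assert len(events) == 1
    tgt = events[0].target
    assert out.active[tgt] and out.x[tgt] == pytest.approx(cfg.limina)


def test_mutate_is_deterministic_given_seed():
    C = np.ones((6, 6))
    cfg = make_config(p_m=0.5, limina=1.0)
    st = SocietyState.from_x(np.array([9.0, 8.0, 7.0, 0.0, 0.0, 0.0]))
    a, ea = mutate(st, C, cfg, np.random.default_rng(99))
    b, eb = mutate(st, C, cfg, np.random.default_rng(99))
    np.testing.assert_array_equal(a.x, b.x)
    assert ea == eb


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    p_m=st.floats(0.0, 1.0),
    limina=st.floats(0.1, 2.0),
)
def test_mutation_invariants_property(seed, p_m, limina):
    """Conservation and the limina quantum hold for arbitrary configs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    C = (rng.random((n, n)) < 0.5).astype(float)
    x = np.where(rng.random(n) < 0.7, limina * (1 + 4 * rng.random(n)), 0.0)
    if not (x > 0).any():
        x[0] = limina
    st = SocietyState.from_x(x)
    cfg = make_config(p_m=p_m, limina=limina)
    out, events = mutate(st, C, cfg, rng)
    assert out.total == pytest.approx(st.total, rel=1e-12, abs=1e-12)
    assert np.all((out.x == 0) | (out.x >= limina - 1e-9))
    assert out.n_active >= st.n_active  # mutation only creates, never destroys
    assert out.n_active <= st.n_active + len(events)


# --- step --------------------------------------------------------------------


def test_step_without_mutation_holds_equilibrium():
    C = random_irreducible(5, 0.5, 8)
    cfg = make_config(p_m=0.0, limina=0.01)
    env = cfg.env()
    st = SocietyState.from_x(np.full(5, 2.0))
    s1, ev1 = step(st, C, env, cfg, np.random.default_rng(0))
    s2, ev2 = step(s1, C, env, cfg, np.random.default_rng(1))
    assert ev1 == [] and ev2 == []
    np.testing.assert_allclose(s1.x, s2.x, rtol=1e-9)
    np.testing.assert_allclose(s2.x, equilibrium_productivity(C, env.a, env.b), rtol=1e-6)
    assert s2.phase_index == 2


def test_step_extinct_passthrough():
    cfg = make_config()
    st = SocietyState(np.zeros(3), np.zeros(3, dtype=bool), phase_index=4)
    out, events = step(st, np.ones((3, 3)), cfg.env(), cfg, np.random.default_rng(0))
    assert out.extinct and events == [] and out.phase_index == 5


def test_step_scheduled_pulse_scales_equilibrium():
    C = np.array([[1.0]])
    cfg = make_config(p_m=0.0, limina=1.0)
    env = EnvironmentParams(a=100.0, b=1.0, disturbance_schedule={0: 4.0})
    out, _ = step(SocietyState.from_x([100.0]), C, env, cfg, np.random.default_rng(0))
    assert out.x[0] == pytest.approx(25.0, rel=1e-6)
    # next phase: restriction back to normal, recovers
    out2, _ = step(out, C, env, cfg, np.random.default_rng(0))
    assert out2.x[0] == pytest.approx(100.0, rel=1e-6)


def test_trajectory_determinism_with_structure_change(rng):
    C = random_irreducible(8, 0.4, 21)
    cfg = make_config(p_m=0.3, limina=1.0)
    env = cfg.env()

    def run(seed):
        g = np.random.default_rng(seed)
        s = SocietyState.from_x(np.where(np.arange(8) < 4, 3.0, 0.0))
        xs = []
        for _ in range(20):
            s, _ = step(s, C, env, cfg, g)
            xs.append(s.x.copy())
        return np.array(xs)

    np.testing.assert_array_equal(run(5), run(5))
    assert not np.array_equal(run(5), run(6))
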