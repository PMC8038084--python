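"""Unit and property tests for the two-stage trail stepper."""

import numpy as np
import pandas as pd
import pytest

from conftest import cyclic_order, fresh_state
from reference import naive_step

from anttrail.core_model import (
    AntPopulation,
    ModelParams,
    TrailState,
    accumulate,
    advance_positions,
    compute_velocity,
    evaporate,
    inject_ant,
    run,
    step,
)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"L": 0},
        {"re": -0.1},
        {"re": 1.5},
        {"vmin": 0.0},
        {"P": 1.2},
        {"inflow": 0.0},
        {"tau": 0.0},
        {"sigma_sat": -1.0},
        {"a": 0.02},  # a*sigma_sat + vmin = 1.75 > 1
        {"deposit_rule": "sometimes"},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)


def test_vsat_is_velocity_ceiling():
    p = ModelParams()
    assert p.vsat == pytest.approx(0.95)


# ---------------------------------------------------------------------------
# the four-case velocity rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "prev, occupied, sigma, draw, expected",
    [
        # occupied next cell wins over everything
        (0.5, True, 70.0, 0.1, 0.0),
        # differentiable pheromone: deterministic chemotaxis
        (0.5, False, 40.0, 0.1, 0.55),
        # saturating pheromone: capped at vmin + a*sigma_sat
        (0.5, False, 200.0, 0.1, 0.95),
        # meager pheromone, slowdown branch (draw < P)
        (0.5, False, 0.5, 0.2, 0.4),
        # meager pheromone, keep-velocity branch (draw >= P)
        (0.5, False, 0.5, 0.9, 0.5),
        # slowdown floors at vmin
        (0.2, False, 0.0, 0.0, 0.15),
        # a previously blocked ant restarts from vmin
        (0.0, False, 0.5, 0.9, 0.15),
        # exactly at the differentiable threshold: chemotaxis applies
        (0.5, False, 1.0, 0.0, 0.16),
    ],
)
def test_compute_velocity_cases(prev, occupied, sigma, draw, expected):
    p = ModelParams()
    assert compute_velocity(prev, occupied, sigma, p, draw) == pytest.approx(expected)


def test_compute_velocity_rejects_negative_pheromone():
    with pytest.raises(ValueError):
        compute_velocity(0.5, False, -1.0, ModelParams(), 0.1)


# ---------------------------------------------------------------------------
# position update
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pos, vel, expected",
    [
        (3.2, 0.55, 3.75),  # within-cell move
        (3.9, 0.95, 4.85),  # single boundary crossing
        (999.5, 0.95, 0.45),  # periodic wrap of the last cell
    ],
)
def test_advance_positions(pos, vel, expected):
    out = advance_positions(np.array([pos]), np.array([vel]), 1000)
    assert out[0] == pytest.approx(expected)


def test_advance_positions_detects_collision():
    with pytest.raises(RuntimeError):
        advance_positions(np.array([3.2, 4.9]), np.array([0.9, 0.0]), 1000)


# ---------------------------------------------------------------------------
# pheromone stage
# ---------------------------------------------------------------------------


def test_evaporate_values_and_errors():
    out = evaporate(np.array([50.0, 0.0, 80.0]), 0.02)
    assert out == pytest.approx([49.0, 0.0, 78.4])
    assert evaporate(np.array([80.0]), 1.0)[0] == 0.0
    with pytest.raises(ValueError):
        evaporate(np.array([1.0]), 1.5)
    with pytest.raises(ValueError):
        evaporate(np.array([-1.0]), 0.5)


def test_accumulate_deposit_and_clamp():
    p = ModelParams()
    # additive deposit below saturation
    out = accumulate(np.array([49.0]), np.array([1]), np.array([0.55]), p)
    assert out[0] == pytest.approx(50.0)
    # evaporate-then-deposit order: a deposit may not push past saturation
    out = accumulate(np.array([79.5]), np.array([1]), np.array([0.55]), p)
    assert out[0] == pytest.approx(80.0)
    # empty cell untouched
    out = accumulate(np.array([49.0]), np.array([0]), np.array([0.0]), p)
    assert out[0] == pytest.approx(49.0)


def test_accumulate_deposit_rules_for_blocked_ants():
    # velocity-gated variant: blocked occupants deposit nothing
    p_moving = ModelParams(deposit_rule="moving")
    out = accumulate(np.array([49.0]), np.array([1]), np.array([0.0]), p_moving)
    assert out[0] == pytest.approx(49.0)
    # default variant: every occupant of an unsaturated cell deposits
    p_occ = ModelParams()
    out = accumulate(np.array([49.0]), np.array([1]), np.array([0.0]), p_occ)
    assert out[0] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# injection
# ---------------------------------------------------------------------------


def test_inject_ant_gates():
    p = ModelParams(L=10, inflow=0.001)
    state, pop = fresh_state(p)
    pop.positions[0] = 5.0
    state.occupancy[:] = 0
    state.occupancy[5] = 1
    assert inject_ant(state, pop, p, draw=0.0005)  # empty entry, draw passes
    assert pop.count == 2 and pop.ids[-1] == 1 and pop.velocities[-1] == p.vmin
    assert not inject_ant(state, pop, p, draw=0.0005)  # entry now occupied
    state2, pop2 = fresh_state(p)
    pop2.positions[0] = 5.0
    state2.occupancy[:] = 0
    state2.occupancy[5] = 1
    assert not inject_ant(state2, pop2, p, draw=0.5)  # probability gate
    assert pop2.count == 1


# ---------------------------------------------------------------------------
# single-step composition
# ---------------------------------------------------------------------------


def test_vacated_cell_decays_from_deposit():
    """A cell a moving ant has left holds tau*(1-re) one evaporation later."""
    p = ModelParams(L=10, re=0.02, inflow=1e-12)
    state, pop = fresh_state(p)
    pop.positions[0] = 0.9
    rng = np.random.default_rng(0)
    # pheromone-free trail: ant moves at ~vmin and crosses into cell 1
    step(state, pop, p, rng)
    assert int(np.floor(pop.positions[0])) == 1
    assert state.pheromone[0] == pytest.approx(p.tau)  # deposit on leaving step
    step(state, pop, p, rng)
    # no occupant in cell 0 anymore: pure evaporation of the deposit
    assert state.pheromone[0] == pytest.approx(p.tau * (1.0 - p.re))


def test_exclusion_blocks_follower():
    p = ModelParams(L=10, inflow=1e-12)
    state = TrailState.empty(10)
    pop = AntPopulation(
        ids=np.array([0, 1]),
        positions=np.array([3.0, 2.0]),
        velocities=np.array([p.vmin, p.vmin]),
    )
    state.occupancy[[3, 2]] = 1
    rng = np.random.default_rng(0)
    step(state, pop, p, rng)
    assert pop.velocities[1] == 0.0  # follower pinned
    assert pop.velocities[0] > 0.0  # leader free


def test_chained_exclusion():
    """A blocked leader blocks its follower in the same step."""
    p = ModelParams(L=10, inflow=1e-12)
    state = TrailState.empty(10)
    pop = AntPopulation(
        ids=np.array([0, 1, 2]),
        positions=np.array([4.0, 3.0, 2.0]),
        velocities=np.array([0.0, p.vmin, p.vmin]),
    )
    state.occupancy[[4, 3, 2]] = 1
    rng = np.random.default_rng(0)
    step(state, pop, p, rng)
    assert pop.velocities[1] == 0.0 and pop.velocities[2] == 0.0


def test_step_with_empty_population_only_evaporates():
    p = ModelParams(L=10, inflow=1e-12, re=0.5)
    state = TrailState.empty(10)
    state.pheromone[3] = 8.0
    pop = AntPopulation()
    rng = np.random.default_rng(1)
    step(state, pop, p, rng)
    assert state.t == 1
    assert state.pheromone[3] == pytest.approx(4.0)
    assert state.occupancy.sum() == 0


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def test_run_is_deterministic_under_fixed_seed():
    p = ModelParams(L=50, inflow=0.05, seed=123)
    a = run(p).metrics
    b = run(p).metrics
    pd.testing.assert_frame_equal(a, b)


def test_run_density_monotone_and_bounded():
    r = run(ModelParams(L=50, inflow=0.05, seed=5))
    d = r.metrics["density"].to_numpy()
    assert (np.diff(d) >= 0).all()
    assert d[-1] <= 1.0
    assert not r.truncated
    assert r.termination == "gridlock"


def test_run_truncates_at_step_cap():
    r = run(ModelParams(L=50, inflow=0.05, seed=5, max_steps=100))
    assert r.truncated and r.steps == 100
    assert r.termination == "max_steps"


def test_run_matches_manual_stepping():
    """The compiled run loop reproduces the granular stepper's metrics."""
    p = ModelParams(L=40, inflow=0.02, seed=3, max_steps=2500)
    state, pop = fresh_state(p)
    rng = np.random.default_rng(p.seed)
    rows = [step(state, pop, p, rng) for _ in range(p.max_steps)]
    manual = pd.DataFrame(rows, columns=["t", "n_ants", "density", "v_avg", "flow"])
    kernel = run(p).metrics
    assert len(kernel) == len(manual)
    assert (kernel["n_ants"].to_numpy() == manual["n_ants"].to_numpy()).all()
    np.testing.assert_allclose(
        kernel["v_avg"].to_numpy(), manual["v_avg"].to_numpy(), rtol=1e-10, atol=1e-14
    )


# ---------------------------------------------------------------------------
# trajectory-level properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("re", [0.0001, 0.02, 0.5])
def test_naive_and_optimized_steppers_agree_bitwise(re):
    p = ModelParams(L=40, re=re, inflow=0.02, seed=17)
    state_a, pop_a = fresh_state(p)
    state_b, pop_b = fresh_state(p)
    rng_a = np.random.default_rng(p.seed)
    rng_b = np.random.default_rng(p.seed)
    for _ in range(2000):
        step(state_a, pop_a, p, rng_a)
        naive_step(state_b, pop_b, p, rng_b)
        assert np.array_equal(pop_a.positions, pop_b.positions)
        assert np.array_equal(pop_a.velocities, pop_b.velocities)
        assert np.array_equal(state_a.pheromone, state_b.pheromone)
        assert np.array_equal(state_a.occupancy, state_b.occupancy)


@pytest.mark.parametrize("re", [0.0001, 0.02, 0.5])
def test_run_invariants(re, small_params):
    """Exclusion, no overtaking, velocity support and pheromone bounds."""
    p = small_params.with_(re=re)
    state, pop = fresh_state(p)
    rng = np.random.default_rng(p.seed)
    order_before = cyclic_order(pop)
    for _ in range(4000):
        step(state, pop, p, rng)
        cells = pop.cells()
        assert np.unique(cells).size == pop.count  # one ant per cell
        v = pop.velocities
        ok = (v == 0.0) | ((v >= p.vmin - 1e-12) & (v <= p.vsat + 1e-12))
        assert ok.all()
        assert (state.pheromone >= 0.0).all()
        assert (state.pheromone <= p.sigma_sat + 1e-12).all()
        order_now = cyclic_order(pop)
        # previously present ants keep their cyclic order; new ants append
        kept = [i for i in order_now if i in set(order_before)]
        assert kept == order_before or not order_before
        order_before = order_now
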