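import numpy as np
import pytest

from anttrail.core_model import AntPopulation, ModelParams, TrailState


@pytest.fixture
def small_params() -> ModelParams:
    """A trail small enough for per-step assertions over full runs."""
    return ModelParams(L=60, inflow=0.02, seed=11)


def fresh_state(params: ModelParams) -> tuple[TrailState, AntPopulation]:
    """Initial condition of the slow-inflow protocol: ant0, clean trail."""
    state = TrailState.empty(params.L)
    population = AntPopulation.single(0.0, params.vmin)
    state.occupancy[0] = 1
    return state, population


def cyclic_order(population: AntPopulation) -> list[int]:
    """Ant ids in trail order, rotated to start at the smallest id."""
    order = [int(i) for i in population.ids[np.argsort(population.positions)]]
    pivot = order.index(min(order))
    return order[pivot:] + order[:pivot]
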