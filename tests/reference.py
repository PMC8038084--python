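"""Deliberately naive per-ant/per-cell reference stepper.

Used as the independent oracle for trajectory equivalence: plain Python
loops over ants and cells, scalar arithmetic, no vectorisation.  It shares
only the published single-ant velocity rule and the documented RNG draw
order (one uniform per ant in id order, then one for injection) with the
production stepper, so agreement over thousands of steps pins down the
whole two-stage composition.
"""

import numpy as np

from anttrail.core_model import AntPopulation, ModelParams, TrailState, compute_velocity


def naive_step(
    state: TrailState,
    population: AntPopulation,
    params: ModelParams,
    rng: np.random.Generator,
) -> None:
    L = params.L
    n = population.count
    draws = [rng.random() for _ in range(n)]

    # Stage I: velocities from time-t fields, one ant at a time
    old_cells = [int(np.floor(population.positions[j])) for j in range(n)]
    v_new = np.zeros(n, dtype=np.float64)
    for j in range(n):
        nc = (old_cells[j] + 1) % L
        v_new[j] = compute_velocity(
            population.velocities[j],
            bool(state.occupancy[nc]),
            float(state.pheromone[nc]),
            params,
            draws[j],
        )
    new_pos = np.array(
        [(population.positions[j] + v_new[j]) % L for j in range(n)],
        dtype=np.float64,
    )

    # Stage II: evaporate every cell, then deposits into time-t cells
    ph = np.array([s * (1.0 - params.re) for s in state.pheromone])
    for j in range(n):
        c = old_cells[j]
        if ph[c] < params.sigma_sat and (
            params.deposit_rule != "moving" or v_new[j] > 0.0
        ):
            ph[c] = ph[c] + params.tau
        if ph[c] > params.sigma_sat:
            ph[c] = params.sigma_sat

    occ = np.zeros(L, dtype=np.int8)
    for j in range(n):
        c = int(np.floor(new_pos[j]))
        assert occ[c] == 0, "naive stepper: two ants in one cell"
        occ[c] = 1

    state.pheromone = ph
    state.occupancy = occ
    population.positions = new_pos
    population.velocities = v_new

    # injection
    draw = rng.random()
    if state.occupancy[0] == 0 and draw < params.inflow:
        population.ids = np.append(population.ids, np.int64(n))
        population.positions = np.append(population.positions, 0.0)
        population.velocities = np.append(population.velocities, params.vmin)
        state.occupancy[0] = 1
    state.t += 1
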