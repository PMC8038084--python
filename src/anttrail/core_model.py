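"""Stochastic ant-trail model (ATM) on a periodic one-dimensional lattice.

The trail is a ring of ``L`` unit cells, each holding at most one ant
(hard-core exclusion inherited from the TASEP).  Ants carry a continuous
position and velocity; the velocity toward the next cell is set by what the
ant perceives ahead:

* next cell occupied            -> velocity 0 (no overtaking);
* pheromone ahead below the differentiable level (sigma < 1)
                                -> with probability ``P`` slow down by 0.1
                                   (floored at ``vmin``), else keep the
                                   previous velocity;
* differentiable pheromone (1 <= sigma < sigma_sat)
                                -> deterministic chemotaxis,
                                   v = vmin + a * sigma;
* saturating pheromone (sigma >= sigma_sat)
                                -> v = vmin + a * sigma_sat (the antenna
                                   cannot differentiate further).

Each time step has two stages.  Stage I computes all velocities in parallel
from the time-``t`` occupancy and pheromone fields and advances every
position by its velocity (mod ``L``).  Stage II updates the pheromone field:
every cell first loses the fraction ``re`` to evaporation, then each cell
that held an ant at time ``t`` receives a deposit ``tau``, clamped at the
antenna saturation level ``sigma_sat``.  Two deposit conventions are
provided (see ``ModelParams.deposit_rule``): the default ``"occupied"``
rule deposits from every occupant, which makes the stationary pheromone of
a dense platoon converge to the geometric-series value ``tau*(1-re)/re``
and produces the congestion-free velocity plateau, the rise-up spike and
the critical-density optimum near ``re = 0.02``; the ``"moving"`` variant
additionally requires the occupant's Stage-I velocity to be positive, so
exclusion-blocked ants deposit nothing.  Finally a new ant may be
injected at the entry cell with probability ``inflow`` if that cell is
empty.  Runs start from a single ant on a pheromone-free trail and sweep
density all the way to gridlock (density 1), so one run traces out the full
fundamental diagram.

Randomness: each step consumes exactly ``N`` uniforms (one per ant, in ant
id order, used only in the meager-pheromone case) followed by one uniform
for the injection gate, so trajectories are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "ModelParams",
    "TrailState",
    "AntPopulation",
    "RunResult",
    "compute_velocity",
    "advance_positions",
    "evaporate",
    "accumulate",
    "inject_ant",
    "step",
    "run",
]

#: conceptual upper velocity bound; never used directly because parameter
#: validation enforces vmin + a * sigma_sat <= 1.
VMAX = 1.0

#: fixed velocity decrement of the meager-pheromone slowdown branch.
SLOWDOWN = 0.1


@dataclass(frozen=True)
class ModelParams:
    """All fixed constants and protocol settings for one simulation.

    Parameters
    ----------
    L : int
        Trail length in cells.
    re : float
        Pheromone evaporation rate, fraction lost per cell per time step.
    tau : float
        Pheromone emitted per moving ant per time step (p units).
    sigma_sat : float
        Antenna saturation concentration (p units / cell).
    vmin : float
        Minimum velocity (cells / time step).
    a : float
        Pheromone-to-velocity prefactor (cells / time step / p unit);
        must satisfy ``a * sigma_sat + vmin <= 1``.
    P : float
        Slowdown probability in the meager-pheromone case.
    inflow : float
        Per-step injection probability at the entry cell.
    deposit_rule : str
        ``"occupied"`` (default): every ant deposits ``tau`` into its cell
        each step while the cell is below saturation, so platoon pheromone
        aggregates to the converged geometric-series level.  ``"moving"``:
        only ants with positive Stage-I velocity deposit; blocked ants
        leave the field untouched.
    seed : int
        RNG seed; the whole run is reproducible from it.
    max_steps : int
        Hard step cap bounding runtime at extreme parameters.
    """

    L: int = 1000
    re: float = 0.02
    tau: float = 1.0
    sigma_sat: float = 80.0
    vmin: float = 0.15
    a: float = 0.01
    P: float = 0.7
    inflow: float = 0.001
    deposit_rule: str = "occupied"
    seed: int = 0
    max_steps: int = 5_000_000

    def __post_init__(self) -> None:
        if self.deposit_rule not in ("occupied", "moving"):
            raise ValueError(
                f"deposit_rule must be 'occupied' or 'moving', got {self.deposit_rule!r}"
            )
        if not (isinstance(self.L, (int, np.integer)) and self.L > 0):
            raise ValueError(f"L must be a positive integer, got {self.L!r}")
        if not 0.0 <= self.re <= 1.0:
            raise ValueError(f"re must lie in [0, 1], got {self.re}")
        if not 0.0 < self.vmin <= 1.0:
            raise ValueError(f"vmin must lie in (0, 1], got {self.vmin}")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError(f"P must lie in [0, 1], got {self.P}")
        if not 0.0 < self.inflow <= 1.0:
            raise ValueError(f"inflow must lie in (0, 1], got {self.inflow}")
        if self.tau <= 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.sigma_sat <= 0.0:
            raise ValueError(f"sigma_sat must be positive, got {self.sigma_sat}")
        if self.a < 0.0:
            raise ValueError(f"a must be non-negative, got {self.a}")
        if self.a * self.sigma_sat + self.vmin > VMAX + 1e-12:
            raise ValueError(
                "a * sigma_sat + vmin must not exceed 1 "
                f"(got {self.a * self.sigma_sat + self.vmin})"
            )
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")

    @property
    def vsat(self) -> float:
        """Velocity at antenna saturation, ``vmin + a * sigma_sat``."""
        return self.vmin + self.a * self.sigma_sat

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class TrailState:
    """Per-cell occupancy and pheromone fields plus the time counter."""

    occupancy: np.ndarray  # int8, length L, 0/1
    pheromone: np.ndarray  # float64, length L, in [0, sigma_sat]
    t: int = 0

    @classmethod
    def empty(cls, L: int) -> "TrailState":
        return cls(
            occupancy=np.zeros(L, dtype=np.int8),
            pheromone=np.zeros(L, dtype=np.float64),
            t=0,
        )


@dataclass
class AntPopulation:
    """Per-ant identity, continuous position and instantaneous velocity.

    Ants are stored in injection order, so the array index of an ant is its
    id ``j`` (ant0 is index 0).  At most one ant occupies any cell
    (``floor(position)``), and the cyclic order of ants never changes.
    """

    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    velocities: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def count(self) -> int:
        return self.positions.size

    def cells(self) -> np.ndarray:
        """Occupied cell index of each ant: ``floor(position)``."""
        return np.floor(self.positions).astype(np.int64)

    @classmethod
    def single(cls, position: float, velocity: float) -> "AntPopulation":
        return cls(
            ids=np.array([0], dtype=np.int64),
            positions=np.array([position], dtype=np.float64),
            velocities=np.array([velocity], dtype=np.float64),
        )


@dataclass
class RunResult:
    """Per-step metrics of a full density sweep plus run bookkeeping."""

    metrics: pd.DataFrame  # columns: t, n_ants, density, v_avg, flow
    params: ModelParams
    steps: int
    truncated: bool

    @property
    def termination(self) -> str:
        return "max_steps" if self.truncated else "gridlock"

    def summary(self) -> dict:
        """JSON-serialisable echo of the run configuration and outcome."""
        from dataclasses import asdict

        return {
            "params": asdict(self.params),
            "seed": self.params.seed,
            "steps": self.steps,
            "termination": self.termination,
            "truncated": self.truncated,
            "final_density": float(self.metrics["density"].iloc[-1])
            if len(self.metrics)
            else 0.0,
        }


def compute_velocity(
    prev_velocity: float,
    next_cell_occupied: bool,
    next_cell_pheromone: float,
    params: ModelParams,
    draw: float,
) -> float:
    """Velocity of one ant toward its next cell, by the four-case rule.

    ``draw`` is a uniform random number in [0, 1); it is only consulted in
    the meager-pheromone case.  A blocked ant (``prev_velocity == 0``)
    carries ``vmin`` into that case, since the rule's "previous velocity"
    is otherwise ill-defined after a stop.
    """
    if next_cell_pheromone < 0.0:
        raise ValueError("pheromone concentration must be non-negative")
    if next_cell_occupied:
        return 0.0
    sigma = next_cell_pheromone
    if sigma < 1.0:
        carried = params.vmin if prev_velocity == 0.0 else prev_velocity
        if draw < params.P:
            return max(carried - SLOWDOWN, params.vmin)
        return carried
    if sigma < params.sigma_sat:
        return params.vmin + params.a * sigma
    return params.vmin + params.a * params.sigma_sat


def advance_positions(
    positions: np.ndarray, velocities: np.ndarray, L: int
) -> np.ndarray:
    """New positions ``(p + v) mod L``; raises if two ants land in one cell.

    Velocities below 1 guarantee at most one cell-boundary crossing, and
    only the unique ant immediately behind an empty cell can claim it, so a
    duplicate cell here indicates a stepper bug rather than bad luck.
    """
    new_pos = (np.asarray(positions, dtype=np.float64) + velocities) % L
    cells = np.floor(new_pos).astype(np.int64)
    if np.unique(cells).size != cells.size:
        raise RuntimeError("exclusion violated: two ants mapped to one cell")
    return new_pos


def evaporate(pheromone: np.ndarray, re: float) -> np.ndarray:
    """Geometric decay of every cell's pheromone: ``sigma * (1 - re)``."""
    if not 0.0 <= re <= 1.0:
        raise ValueError(f"re must lie in [0, 1], got {re}")
    ph = np.asarray(pheromone, dtype=np.float64)
    if np.any(ph < 0.0):
        raise ValueError("pheromone concentrations must be non-negative")
    return ph * (1.0 - re)


def accumulate(
    pheromone: np.ndarray,
    occupancy: np.ndarray,
    velocity: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Pheromone deposit by moving ants, clamped at ``sigma_sat``.

    ``occupancy`` and ``velocity`` are per-cell Stage-I values of the
    current step: the cells occupied at time ``t`` and the velocity of each
    occupant (any value for empty cells; it is masked out).  Occupied cells
    whose evaporated concentration is still below saturation gain ``tau``
    (under ``deposit_rule="moving"`` only if the occupant's velocity is
    positive); every occupied cell is clamped at ``sigma_sat``; all other
    cells keep the evaporated value.
    """
    ph = np.array(pheromone, dtype=np.float64, copy=True)
    occ = np.asarray(occupancy).astype(bool)
    v = np.asarray(velocity, dtype=np.float64)
    deposit = occ & (ph < params.sigma_sat)
    if params.deposit_rule == "moving":
        deposit &= v > 0.0
    ph[deposit] += params.tau
    ph[occ] = np.minimum(ph[occ], params.sigma_sat)
    return ph


def inject_ant(
    state: TrailState,
    population: AntPopulation,
    params: ModelParams,
    draw: float,
    entry_cell: int = 0,
) -> bool:
    """Maybe append a new ant at the entry cell; returns True on injection.

    The new ant gets id ``N`` (the population count before injection),
    position at the left edge of the entry cell, and velocity ``vmin``.
    Mutates ``state`` and ``population`` in place.
    """
    if state.occupancy[entry_cell] != 0 or draw >= params.inflow:
        return False
    n = population.count
    population.ids = np.append(population.ids, np.int64(n))
    population.positions = np.append(population.positions, float(entry_cell))
    population.velocities = np.append(population.velocities, params.vmin)
    state.occupancy[entry_cell] = 1
    return True


def step(
    state: TrailState,
    population: AntPopulation,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[int, int, float, float, float]:
    """Advance the model by one time step, in place.

    Stage I: all velocities are computed in parallel from the time-``t``
    occupancy and pheromone, then all positions advance.  Stage II:
    evaporation, then accumulation using the time-``t`` occupancy and the
    Stage-I velocities.  Then injection.  Returns the per-step metrics
    tuple ``(t, n_ants, density, v_avg, flow)`` where ``t`` is the time
    after the step and ``n_ants`` counts the ants that took part in it
    (pre-injection).
    """
    L = params.L
    n = population.count

    draws = rng.random(n)
    if n:
        cells = population.cells()
        nxt = cells + 1
        nxt[nxt == L] = 0
        occ_next = state.occupancy[nxt].astype(bool)
        ph_next = state.pheromone[nxt]
        prev = population.velocities
        carried = np.where(prev == 0.0, params.vmin, prev)
        slowed = np.maximum(carried - SLOWDOWN, params.vmin)
        v = np.where(draws < params.P, slowed, carried)
        differentiable = ph_next >= 1.0
        v = np.where(
            differentiable,
            params.vmin + params.a * np.minimum(ph_next, params.sigma_sat),
            v,
        )
        v[occ_next] = 0.0

        new_pos = (population.positions + v) % L
        new_cells = np.floor(new_pos).astype(np.int64)

        # Stage II on the time-t occupancy with Stage-I velocities.
        ph = state.pheromone * (1.0 - params.re)
        deposit = ph[cells] < params.sigma_sat
        if params.deposit_rule == "moving":
            deposit &= v > 0.0
        ph[cells[deposit]] += params.tau
        ph[cells] = np.minimum(ph[cells], params.sigma_sat)

        occ = np.zeros(L, dtype=np.int8)
        occ[new_cells] = 1
        if int(occ.sum()) != n:
            raise RuntimeError("exclusion violated: two ants mapped to one cell")

        state.pheromone = ph
        state.occupancy = occ
        population.positions = new_pos
        population.velocities = v
        v_avg = float(v.mean())
    else:
        state.pheromone = state.pheromone * (1.0 - params.re)
        v_avg = 0.0

    inject_ant(state, population, params, rng.random())
    state.t += 1

    density = n / L
    return state.t, n, density, v_avg, density * v_avg


@njit(cache=True)
def _run_kernel(
    rng,
    occupancy,
    pheromone,
    positions,
    velocities,
    cells,
    n0,
    L,
    q,
    tau,
    sigma_sat,
    vmin,
    a,
    P,
    inflow,
    deposit_moving,
    n_target,
    max_steps,
    n_out,
    v_out,
):
    """Tight loop behind :func:`run`; same update semantics as :func:`step`.

    Scalar per-ant arithmetic uses the exact expressions of the vectorized
    stepper (and consumes the RNG stream in the same order), so both paths
    produce bit-identical trajectories.  Returns ``(n, t, k, code)`` with
    ``code`` 0 = reached target density, 1 = step cap, 2 = exclusion bug.
    """
    n = n0
    t = 0
    k = 0
    Lf = float(L)
    vel_new = np.empty(L)
    while True:
        n_pre = n
        vsum = 0.0
        for j in range(n_pre):
            c = cells[j]
            nc = c + 1
            if nc == L:
                nc = 0
            draw = rng.random()
            if occupancy[nc] == 1:
                v = 0.0
            else:
                s = pheromone[nc]
                if s >= 1.0:
                    sm = s if s < sigma_sat else sigma_sat
                    v = vmin + a * sm
                else:
                    prev = velocities[j]
                    carried = vmin if prev == 0.0 else prev
                    if draw < P:
                        v = carried - SLOWDOWN
                        if v < vmin:
                            v = vmin
                    else:
                        v = carried
            vel_new[j] = v
            vsum += v
        for i in range(L):
            pheromone[i] *= q
        for j in range(n_pre):
            c = cells[j]
            if pheromone[c] < sigma_sat:
                if (not deposit_moving) or vel_new[j] > 0.0:
                    pheromone[c] += tau
            if pheromone[c] > sigma_sat:
                pheromone[c] = sigma_sat
        for j in range(n_pre):
            v = vel_new[j]
            velocities[j] = v
            if v > 0.0:
                p = (positions[j] + v) % Lf
                c_new = int(p)
                positions[j] = p
                c_old = cells[j]
                if c_new != c_old:
                    occupancy[c_old] = 0
                    if occupancy[c_new] == 1:
                        return n, t, k, 2
                    occupancy[c_new] = 1
                    cells[j] = c_new
        draw = rng.random()
        if occupancy[0] == 0 and draw < inflow and n < L:
            cells[n] = 0
            positions[n] = 0.0
            velocities[n] = vmin
            occupancy[0] = 1
            n += 1
        t += 1
        n_out[k] = n_pre
        v_out[k] = vsum / n_pre
        k += 1
        if n >= n_target:
            return n, t, k, 0
        if t >= max_steps:
            return n, t, k, 1


def run(params: ModelParams, stop_density: float = 1.0) -> RunResult:
    """Full density sweep: one ant on a clean trail, stepped to gridlock.

    Starts from ant0 at the entry cell with velocity ``vmin`` and zero
    pheromone everywhere, and iterates the stepper until the density
    reaches ``stop_density`` (default 1, i.e. ``N == L``) or ``max_steps``
    is hit, in which case the partial sweep is flagged as truncated.
    Fully reproducible from ``params.seed``; the compiled loop matches
    :func:`step` bit-for-bit.
    """
    if not 0.0 < stop_density <= 1.0:
        raise ValueError("stop_density must lie in (0, 1]")
    L = params.L
    rng = np.random.default_rng(params.seed)
    occupancy = np.zeros(L, dtype=np.int8)
    pheromone = np.zeros(L, dtype=np.float64)
    positions = np.zeros(L, dtype=np.float64)
    velocities = np.zeros(L, dtype=np.float64)
    cells = np.zeros(L, dtype=np.int64)
    velocities[0] = params.vmin
    occupancy[0] = 1

    n_target = int(np.ceil(stop_density * L))
    n_out = np.empty(params.max_steps, dtype=np.int64)
    v_out = np.empty(params.max_steps, dtype=np.float64)
    n, t, k, code = _run_kernel(
        rng,
        occupancy,
        pheromone,
        positions,
        velocities,
        cells,
        1,
        L,
        1.0 - params.re,
        params.tau,
        params.sigma_sat,
        params.vmin,
        params.a,
        params.P,
        params.inflow,
        params.deposit_rule == "moving",
        n_target,
        params.max_steps,
        n_out,
        v_out,
    )
    if code == 2:
        raise RuntimeError("exclusion violated: two ants mapped to one cell")

    n_arr = n_out[:k].copy()
    v_arr = v_out[:k].copy()
    density = n_arr / L
    metrics = pd.DataFrame(
        {
            "t": np.arange(1, k + 1, dtype=np.int64),
            "n_ants": n_arr,
            "density": density,
            "v_avg": v_arr,
            "flow": density * v_arr,
        }
    )
    return RunResult(
        metrics=metrics, params=params, steps=t, truncated=code == 1
    )
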