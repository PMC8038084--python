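"""Closed-form pheromone calculus and the three communication states.

Pheromone on a trail cell is a geometric process: each step the cell keeps
the fraction ``(1 - re)`` of its concentration and, while a platoon streams
through, gains a deposit ``tau``.  The concentration a following ant senses
after M platoon steps is therefore the geometric sum

    sigma(M) = tau * sum_{k=1..M} (1 - re)**k,

which for an infinitely long platoon converges to ``tau * (1 - re) / re``
(clamped at the antenna saturation ``sigma_sat``).  After the platoon has
passed the cell depletes as ``sigma0 * (1 - re)**D``; the time for it to
fall to the differentiable threshold (concentration 1) is
``D = -ln(sigma0) / ln(1 - re)``.

Comparing these time scales against the one-cell traversal time of a
follower moving at ``vmin`` partitions the evaporation rate axis into three
communication regimes:

* **minimal** — pheromone vanishes before even an adjacent follower can
  read it; ants fall back on exclusion alone and travel near ``vmin``;
* **active** — pheromone encodes the traffic flow of the recent past;
  platoons and congestion-free traffic emerge;
* **inactive** — pheromone saturates, becoming insensitive to local
  conditions; every ant runs near the saturation velocity.

With the default parameters (tau = 1, sigma_sat = 80, vmin = 0.15) the
boundaries evaluate to re = 0.012 (inactive/active) and re = 0.19
(active/minimal); the boundaries themselves belong to the active state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import bisect

__all__ = [
    "AggregationScenario",
    "DepletionScenario",
    "StateLabel",
    "finite_aggregation",
    "converged_aggregation",
    "depletion_time",
    "min_traversal_time",
    "minimal_state_boundary",
    "inactive_state_boundary",
    "saturation_tau",
    "classify_state",
    "analytics_report",
]

#: concentration below which an ant can detect but not differentiate
#: pheromone; the "information erased" threshold of the depletion analysis.
DIFFERENTIABLE_LEVEL = 1.0


@dataclass(frozen=True)
class AggregationScenario:
    """A platoon of M ants streaming through one always-occupied cell."""

    tau: float
    re: float
    M: float  # may be math.inf for the converged scenario
    sigma_sat: float


@dataclass(frozen=True)
class DepletionScenario:
    """Evaporation of an aggregated concentration down to threshold 1."""

    sigma0: float
    re: float
    D: float


@dataclass(frozen=True)
class StateLabel:
    """Communication-state classification with the boundaries behind it."""

    label: str  # "minimal" | "active" | "inactive"
    boundary_minimal: float
    boundary_inactive: float
    re: float
    tau: float
    sigma_sat: float
    vmin: float


def finite_aggregation(tau: float, re: float, M: int) -> float:
    """Concentration sensed after an M-step platoon passage (unclamped).

    Evaluates ``tau * sum_{k=1..M} (1 - re)**k``: each of the M deposits has
    evaporated at least once by the time a follower reads the cell.
    """
    if M < 0 or int(M) != M:
        raise ValueError(f"M must be a non-negative integer, got {M}")
    if not 0.0 <= re <= 1.0:
        raise ValueError(f"re must lie in [0, 1], got {re}")
    q = 1.0 - re
    return tau * sum(q**k for k in range(1, int(M) + 1))


def converged_aggregation(tau: float, re: float, sigma_sat: float) -> float:
    """Limit concentration behind an infinite platoon, clamped at saturation.

    The geometric series converges for ``re > 0`` to ``tau * (1 - re) / re``;
    the antenna cannot register anything above ``sigma_sat``.
    """
    if not 0.0 < re <= 1.0:
        raise ValueError(
            f"series diverges: re must lie in (0, 1], got {re}"
        )
    return min(tau * (1.0 - re) / re, sigma_sat)


def depletion_time(sigma0: float, re: float) -> float:
    """Steps for a concentration to evaporate to the differentiable level.

    Solves ``sigma0 * (1 - re)**D = 1`` for D, i.e.
    ``D = -ln(sigma0) / ln(1 - re)``; a concentration already at or below
    the threshold needs no time (D = 0).
    """
    if sigma0 <= 0.0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    if not 0.0 < re < 1.0:
        raise ValueError(f"re must lie strictly in (0, 1), got {re}")
    return max(0.0, -math.log(sigma0) / math.log(1.0 - re))


def min_traversal_time(distance: float, velocity: float) -> float:
    """Time for an ant to cover ``distance`` cells at constant velocity."""
    if distance <= 0.0 or velocity <= 0.0:
        raise ValueError("distance and velocity must be positive")
    return distance / velocity


def minimal_state_boundary(tau: float, vmin: float) -> float:
    """Evaporation rate above which communication collapses to minimal.

    At the boundary, the converged aggregation behind a platoon decays to
    the differentiable level exactly within the one-cell traversal time of
    a follower at ``vmin`` (headway one cell, the tightest exclusion gap):

        tau * (1 - re) / re * (1 - re)**(1 / vmin) = 1.

    The root in (0, 1) is found by bisection to absolute tolerance 1e-8.
    For tau = 1, vmin = 0.15 this gives re = 0.19 (two decimals).
    """
    if tau <= 0.0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not 0.0 < vmin <= 1.0:
        raise ValueError(f"vmin must lie in (0, 1], got {vmin}")
    exponent = 1.0 + 1.0 / vmin

    def residual(re: float) -> float:
        # log form keeps the residual well-scaled across (0, 1)
        return math.log(tau) + exponent * math.log1p(-re) - math.log(re)

    lo, hi = 1e-6, 1.0 - 1e-6
    if residual(lo) < 0.0 or residual(hi) > 0.0:
        raise ValueError("no minimal-state boundary in (0, 1) for these inputs")
    return float(bisect(residual, lo, hi, xtol=1e-8))


def inactive_state_boundary(tau: float, sigma_sat: float) -> float:
    """Evaporation rate below which the aggregated pheromone saturates.

    Solves ``tau * (1 - re) / re = sigma_sat`` in closed form:
    ``re = tau / (sigma_sat + tau)``.  For tau = 1, sigma_sat = 80 this is
    1/81, printed as 0.012.
    """
    if tau <= 0.0 or sigma_sat <= 0.0:
        raise ValueError("tau and sigma_sat must be positive")
    return tau / (sigma_sat + tau)


def saturation_tau(re: float, sigma_sat: float) -> float:
    """Emission rate at which the converged aggregation first saturates.

    The algebraic inverse of :func:`inactive_state_boundary`:
    ``tau = sigma_sat * re / (1 - re)``.  For re = 0.02, sigma_sat = 80
    this is 1.6327, printed as 1.63.
    """
    if not 0.0 < re < 1.0:
        raise ValueError(f"re must lie strictly in (0, 1), got {re}")
    if sigma_sat <= 0.0:
        raise ValueError(f"sigma_sat must be positive, got {sigma_sat}")
    return sigma_sat * re / (1.0 - re)


def classify_state(
    re: float, tau: float = 1.0, sigma_sat: float = 80.0, vmin: float = 0.15
) -> StateLabel:
    """Label an evaporation rate as minimal, active or inactive.

    Both boundaries are computed from the operations above; the boundaries
    themselves belong to the active state (closed interval).
    """
    if not 0.0 <= re <= 1.0:
        raise ValueError(f"re must lie in [0, 1], got {re}")
    b_min = minimal_state_boundary(tau, vmin)
    b_inact = inactive_state_boundary(tau, sigma_sat)
    if b_inact >= b_min:
        raise ValueError(
            "no active window: inactive boundary "
            f"{b_inact:.4g} >= minimal boundary {b_min:.4g}"
        )
    if re > b_min:
        label = "minimal"
    elif re < b_inact:
        label = "inactive"
    else:
        label = "active"
    return StateLabel(
        label=label,
        boundary_minimal=b_min,
        boundary_inactive=b_inact,
        re=re,
        tau=tau,
        sigma_sat=sigma_sat,
        vmin=vmin,
    )


def analytics_report(
    re: float, tau: float = 1.0, sigma_sat: float = 80.0, vmin: float = 0.15
) -> dict:
    """Full closed-form report for one parameter set, JSON-serialisable."""
    raw = tau * (1.0 - re) / re if re > 0 else math.inf
    clamped = min(raw, sigma_sat)
    state = classify_state(re, tau, sigma_sat, vmin)
    return {
        "inputs": {"re": re, "tau": tau, "sigma_sat": sigma_sat, "vmin": vmin},
        "converged_aggregation_raw": raw,
        "converged_aggregation": clamped,
        "depletion_time": depletion_time(clamped, re)
        if 0.0 < re < 1.0
        else None,
        "one_cell_traversal_time": min_traversal_time(1.0, vmin),
        "boundary_minimal": state.boundary_minimal,
        "boundary_inactive": state.boundary_inactive,
        "saturation_tau": saturation_tau(re, sigma_sat)
        if 0.0 < re < 1.0
        else None,
        "state": state.label,
    }
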