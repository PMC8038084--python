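"""Traffic observables: fundamental diagrams, critical density, platoons.

The simulator's slow-inflow protocol sweeps density from ~0 to 1 within a
single run, so the per-step metrics table already samples every density.
Binning mean velocity and flow by density yields the two fundamental
diagrams (average velocity-density and flow-density); the critical density
— the junction between the free-flow and jamming phases — is estimated as
the density bin maximizing the moving-average-smoothed binned flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_model import AntPopulation, ModelParams, run

__all__ = [
    "StepMetrics",
    "FundamentalDiagram",
    "PlatoonSet",
    "step_metrics",
    "bin_fundamental_diagram",
    "critical_density",
    "detect_platoons",
    "sweep_evaporation",
    "sweep_tau",
]


class StepMetrics(NamedTuple):
    """Traffic observables of a single time step."""

    t: int
    n_ants: int
    density: float
    v_avg: float
    flow: float


@dataclass
class FundamentalDiagram:
    """Density-binned mean velocity and flow of one (or more) runs."""

    bin_centers: np.ndarray
    mean_v: np.ndarray
    mean_flow: np.ndarray
    counts: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_v": self.mean_v,
                "mean_flow": self.mean_flow,
                "count": self.counts,
            }
        )


@dataclass
class PlatoonSet:
    """Partition of the population into platoons on the ring.

    ``members`` lists, per platoon, the ant ids in trail order; ``spans``
    is each platoon's extent in cells (first to last occupied cell,
    inclusive); ``gaps`` is the number of empty cells between a platoon's
    last ant and the next platoon ahead of it.
    """

    members: list[np.ndarray]
    spans: np.ndarray
    gaps: np.ndarray
    gap_threshold: int

    @property
    def count(self) -> int:
        return len(self.members)


def step_metrics(
    population: AntPopulation, velocities: np.ndarray, L: int, t: int = 0
) -> StepMetrics:
    """Metrics of one step: density N/L, mean displacement, flow d*v_avg.

    The mean includes blocked ants (velocity 0); the flow identity
    ``flow = density * v_avg`` holds exactly.
    """
    n = population.count
    if n == 0:
        raise ValueError("metrics are undefined for an empty population")
    v_avg = float(np.mean(velocities))
    density = n / L
    return StepMetrics(t, n, density, v_avg, density * v_avg)


def bin_fundamental_diagram(
    metrics: pd.DataFrame, bin_width: float = 0.005, burn_in: int = 0
) -> FundamentalDiagram:
    """Group per-step metrics into density bins covering (0, 1].

    Bin ``k`` is the half-open interval ``(k*w, (k+1)*w]`` (right-closed so
    the gridlock density 1 falls in the last bin); rows with ``t < burn_in``
    are dropped first.  Only occupied bins are returned, sorted by center.
    """
    if not 0.0 < bin_width <= 0.5:
        raise ValueError(f"bin_width must lie in (0, 0.5], got {bin_width}")
    df = metrics[metrics["t"] >= burn_in]
    if df.empty:
        raise ValueError("no metrics rows remain after burn-in")
    idx = np.ceil(df["density"].to_numpy() / bin_width).astype(np.int64) - 1
    idx = np.maximum(idx, 0)
    grouped = (
        pd.DataFrame({"idx": idx, "v": df["v_avg"].to_numpy(), "f": df["flow"].to_numpy()})
        .groupby("idx")
        .agg(mean_v=("v", "mean"), mean_flow=("f", "mean"), count=("v", "size"))
        .sort_index()
    )
    centers = (grouped.index.to_numpy() + 0.5) * bin_width
    return FundamentalDiagram(
        bin_centers=centers,
        mean_v=grouped["mean_v"].to_numpy(),
        mean_flow=grouped["mean_flow"].to_numpy(),
        counts=grouped["count"].to_numpy(),
        bin_width=bin_width,
    )


def critical_density(fd: FundamentalDiagram, smooth_window: int = 5) -> float:
    """Density at the free-flow/jamming junction: argmax of smoothed flow.

    The binned flow is smoothed with a centered moving average over
    ``smooth_window`` occupied bins; ties break toward lower density.
    """
    n_bins = fd.bin_centers.size
    if n_bins < smooth_window:
        raise ValueError(
            f"need at least {smooth_window} occupied bins, got {n_bins}"
        )
    smoothed = (
        pd.Series(fd.mean_flow)
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return float(fd.bin_centers[int(np.argmax(smoothed))])


def detect_platoons(
    population: AntPopulation, L: int, gap_threshold: int = 2
) -> PlatoonSet:
    """Maximal runs of ants separated by at most ``gap_threshold`` empty cells.

    Computed on the ring: two ants belong to the same platoon when the
    number of empty cells between their occupied cells is at most the
    threshold.  If every inter-ant gap is within the threshold the whole
    population is a single platoon (including the single-ant case).
    """
    n = population.count
    if n == 0:
        raise ValueError("platoons are undefined for an empty population")
    cells = population.cells()
    order = np.argsort(cells)
    sorted_cells = cells[order]
    sorted_ids = population.ids[order]
    if n == 1:
        return PlatoonSet(
            members=[sorted_ids], spans=np.array([1]), gaps=np.array([L - 1]),
            gap_threshold=gap_threshold,
        )
    # empty cells between ant k and the next ant ahead (ring-wrapped)
    gaps = np.empty(n, dtype=np.int64)
    gaps[:-1] = np.diff(sorted_cells) - 1
    gaps[-1] = sorted_cells[0] + L - sorted_cells[-1] - 1
    breaks = np.flatnonzero(gaps > gap_threshold)
    if breaks.size == 0:
        span = int(sorted_cells[-1] - sorted_cells[0] + 1)
        return PlatoonSet(
            members=[sorted_ids], spans=np.array([span]),
            gaps=np.array([0]), gap_threshold=gap_threshold,
        )
    members, spans, platoon_gaps = [], [], []
    # platoons run from just after one break to the next break (inclusive),
    # wrapping around the ring
    for b_prev, b in zip(np.roll(breaks, 1), breaks):
        start = (b_prev + 1) % n
        if start <= b:
            sel = np.arange(start, b + 1)
        else:
            sel = np.concatenate([np.arange(start, n), np.arange(0, b + 1)])
        members.append(sorted_ids[sel])
        first, last = sorted_cells[sel[0]], sorted_cells[sel[-1]]
        spans.append(int((last - first) % L + 1))
        platoon_gaps.append(int(gaps[b]))
    return PlatoonSet(
        members=members,
        spans=np.asarray(spans),
        gaps=np.asarray(platoon_gaps),
        gap_threshold=gap_threshold,
    )


def _sweep_field(
    params_base: ModelParams,
    fieldname: str,
    grid: Sequence[float],
    seeds: Sequence[int],
    bin_width: float = 0.005,
    smooth_window: int = 5,
    burn_in: int = 0,
) -> pd.DataFrame:
    rows = []
    for value in sorted(grid):
        for seed in seeds:
            result = run(params_base.with_(**{fieldname: value, "seed": int(seed)}))
            fd = bin_fundamental_diagram(
                result.metrics, bin_width=bin_width, burn_in=burn_in
            )
            rows.append(
                {
                    fieldname: value,
                    "seed": int(seed),
                    "critical_density": critical_density(fd, smooth_window),
                    "truncated": result.truncated,
                }
            )
    return pd.DataFrame(rows)


def sweep_evaporation(
    params_base: ModelParams,
    re_grid: Sequence[float],
    seeds: Sequence[int],
    **kwargs,
) -> pd.DataFrame:
    """Critical density for each evaporation rate in ``re_grid``.

    Runs the full slow-inflow protocol once per (re, seed) pair and returns
    one row per run: ``re, seed, critical_density, truncated``, sorted by
    ``re``.  Extra keyword arguments are forwarded to the binning and
    smoothing (``bin_width``, ``smooth_window``, ``burn_in``).
    """
    if any(not 0.0 <= g <= 1.0 for g in re_grid):
        raise ValueError("re grid values must lie in [0, 1]")
    return _sweep_field(params_base, "re", re_grid, seeds, **kwargs)


def sweep_tau(
    params_base: ModelParams,
    tau_grid: Sequence[float],
    seeds: Sequence[int],
    **kwargs,
) -> pd.DataFrame:
    """Critical density for each emission rate in ``tau_grid``."""
    if any(g <= 0.0 for g in tau_grid):
        raise ValueError("tau grid values must be positive")
    return _sweep_field(params_base, "tau", tau_grid, seeds, **kwargs)
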