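"""Stochastic logistic branching process with a time-dependent rate.

Each cell is an individual particle.  With population size N and rate
curve r(t), the birth hazard is lambda = N r(t) and the death hazard is
mu = N (N-1) r(t) / K — a density-dependent death rate equivalent to
pairwise competition, whose mean dynamics are logistic.  N = 0 is
absorbing.

Event times are drawn exactly by inverting the integrated hazard: both
hazards share the factor r(t), so between events the total hazard is
c(N) * r(t) with c(N) = N + N(N-1)/K, and the waiting time solves
c * [R(t + dt) - R(t)] = Exp(1), which is a per-segment quadratic since
R is piecewise quadratic.  The birth/death split N : N(N-1)/K is
time-independent given N, so it is a plain Bernoulli draw.  No thinning
is needed for non-negative piecewise-linear rates.

The event loop is JIT-compiled (numba); simulation is practical for
populations below roughly 2e6 cells, above which every division and
death being an individual event makes it slow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .growth import CultureModel, RateCurve, Trajectory

__all__ = ["BranchingConfig", "simulate_branching", "ensemble"]


@dataclass(frozen=True)
class BranchingConfig:
    """Inputs for one stochastic simulation.

    ``max_events`` is a runaway guard: the simulation fails rather than
    silently truncating if the event count exceeds it.
    """

    model: CultureModel
    curve: RateCurve
    t_end: float
    seed: int
    max_events: int = 2_000_000

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.curve.control_values):
            raise ValueError("stochastic simulation requires non-negative rates "
                             "(clamp the curve first)")
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")
        if self.model.carrying_capacity < 1:
            raise ValueError("carrying capacity must be >= 1 cell")
        if self.model.initial_population != int(self.model.initial_population):
            raise ValueError("initial population must be an integer cell count")


@njit(cache=True)
def _event_loop(seed, n0, k_cap, t_end, grid_t, grid_r, max_events):  # pragma: no cover - jitted
    np.random.seed(seed)
    times = np.empty(max_events)
    sizes = np.empty(max_events, np.int64)
    n_seg = grid_t.shape[0] - 1
    t = 0.0
    n = n0
    m = 0
    seg = 0
    overflow = 0
    while n > 0:
        c = n + n * (n - 1.0) / k_cap
        target = np.random.exponential() / c  # required integral of r(t)
        tt = t
        j = seg
        hit = False
        while j < n_seg:
            a = grid_t[j]
            b = grid_t[j + 1]
            ra = grid_r[j]
            rb = grid_r[j + 1]
            pos = tt if tt > a else a
            slope = (rb - ra) / (b - a)
            r0 = ra + slope * (pos - a)
            area = 0.5 * (r0 + rb) * (b - pos)
            if target <= area:
                if abs(slope) < 1e-14:
                    dt = target / r0
                else:
                    disc = r0 * r0 + 2.0 * slope * target
                    if disc < 0.0:
                        disc = 0.0
                    dt = (np.sqrt(disc) - r0) / slope
                tt = pos + dt
                hit = True
                break
            target -= area
            j += 1
        if not hit:
            break  # hazard exhausted before t_end: no further events
        t = tt
        seg = j
        if t >= t_end:
            break
        if np.random.random() * c < n:
            n += 1
        else:
            n -= 1
        if m >= max_events:
            overflow = 1
            break
        times[m] = t
        sizes[m] = n
        m += 1
    return times[:m], sizes[:m], overflow


def _rate_grid(curve: RateCurve, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoint grid covering [0, t_end] on which r(t) is linear."""
    knots = curve.knots
    inner = knots[(knots > 0.0) & (knots < t_end)]
    grid = np.concatenate([[0.0], inner, [t_end]])
    grid = np.unique(grid)
    return grid, np.asarray(curve.rate_at(grid), dtype=float)


def simulate_branching(cfg: BranchingConfig) -> Trajectory:
    """One exact realization of the logistic branching process.

    Returns the piecewise-constant trajectory of (event time, size)
    pairs, starting at (0, N0).  Identical config (incl. seed) gives a
    bitwise-identical trajectory.
    """
    n0 = int(cfg.model.initial_population)
    grid_t, grid_r = _rate_grid(cfg.curve, cfg.t_end)
    times, sizes, overflow = _event_loop(
        int(cfg.seed) % (2**32), n0, float(cfg.model.carrying_capacity),
        float(cfg.t_end), grid_t, grid_r, cfg.max_events,
    )
    if overflow:
        raise RuntimeError(f"event count exceeded max_events={cfg.max_events}; "
                           "population likely too large for the stochastic simulator")
    return Trajectory(np.concatenate([[0.0], times]),
                      np.concatenate([[n0], sizes]).astype(np.int64))


def replicate_seed(base_seed: int, index: int) -> int:
    """Counter-based per-replicate seed: reproducible and order-independent."""
    return int(np.random.SeedSequence(base_seed, spawn_key=(index,)).generate_state(1)[0])


def sample_trajectory(traj: Trajectory, times) -> np.ndarray:
    """Sample a piecewise-constant trajectory by last-event carry-forward."""
    times = np.asarray(times, dtype=float)
    if np.any(times < traj.times[0]):
        raise ValueError("requested times precede the trajectory start")
    idx = np.searchsorted(traj.times, times, side="right") - 1
    return np.asarray(traj.sizes)[idx]


def ensemble(cfg: BranchingConfig, n_reps: int, times) -> np.ndarray:
    """Independent replicates sampled on a common time grid.

    Returns an (n_reps, len(times)) integer matrix.  Replicate seeds are
    derived from ``cfg.seed`` by a counter-based scheme, so the ensemble
    is reproducible and each replicate is independent of how many others
    are run.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    times = np.asarray(times, dtype=float)
    out = np.empty((n_reps, len(times)), dtype=np.int64)
    for i in range(n_reps):
        rep = BranchingConfig(cfg.model, cfg.curve, cfg.t_end,
                              replicate_seed(cfg.seed, i), cfg.max_events)
        out[i] = sample_trajectory(simulate_branching(rep), times)
    return out
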