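"""Exact stochastic simulation of the self-activating gene.

The circuit is a one-species birth-death process: synthesis A -> A+1 with
propensity f(A) (Hill-type positive feedback) and degradation A -> A-1 with
propensity gamma*A.  Trajectories are generated with the Gillespie direct
method over one cell life span (tau = 4 dimensionless time units by default,
i.e. four cell-cycle times).

The inner loops are numba-compiled; per-cell random streams are derived from
a master seed and the (generation, cell index) pair with a splitmix64 hash,
so population simulations are reproducible regardless of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .circuit_models import Genotype

__all__ = [
    "Trajectory",
    "RngStream",
    "derive_seeds",
    "simulate_cell",
    "simulate_population",
    "empirical_distribution",
    "EventCapExceeded",
]

#: Hard cap on reaction events in a single cell life span; only pathological
#: parameter combinations (k near the upper bound with long tau) approach it.
MAX_EVENTS = 10_000_000

DEFAULT_TAU = 4.0


class EventCapExceeded(RuntimeError):
    """A single life-span simulation exceeded the event cap."""


@dataclass(frozen=True)
class Trajectory:
    """One SSA realization over a cell life span.

    ``times``/``states`` hold the piecewise-constant path (event times and
    the protein count after each event, starting with the initial state at
    time 0); ``final_A`` is the count at ``tau_end`` and ``time_avg_A`` the
    time-weighted mean over [0, tau_end].
    """

    times: np.ndarray
    states: np.ndarray
    final_A: int
    time_avg_A: float

    def to_text(self, path) -> None:
        """Write the trajectory as two-column delimited text (tau, A)."""
        np.savetxt(path, np.column_stack([self.times, self.states]),
                   fmt="%.8g\t%d", comments="", header="tau\tA")


@dataclass(frozen=True)
class RngStream:
    """A named, reproducible random stream identified by an integer seed."""

    seed: int

    def child(self, *keys: int) -> int:
        """Derive a 31-bit child seed from this stream and integer keys."""
        return int(derive_seeds(self.seed, keys[0] if keys else 0,
                                np.asarray([keys[1] if len(keys) > 1 else 0]))[0])


def _splitmix64(z: np.ndarray) -> np.ndarray:
    z = (z + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    return z ^ (z >> np.uint64(31))


def derive_seeds(master_seed: int, generation: int, cell_idx) -> np.ndarray:
    """Per-cell 31-bit seeds mixed from (master seed, generation, cell index)."""
    cell_idx = np.asarray(cell_idx, dtype=np.uint64)
    with np.errstate(over="ignore"):
        base = _splitmix64(np.uint64(master_seed & 0xFFFFFFFFFFFF)
                           + np.uint64(0x1000003) * np.uint64(generation))
        mixed = _splitmix64(base ^ (cell_idx + np.uint64(0x632BE59BD9B4E019)))
    seeds = (mixed & np.uint64(0x7FFFFFFF)).astype(np.int64)
    return np.where(seeds == 0, 1, seeds)


@njit(cache=True)
def _hill_nb(A, n_H, K_D):
    x = (A / K_D) ** n_H
    if x > 1e300:
        return 1.0
    return x / (1.0 + x)


@njit(cache=True)
def _ssa_final(k, n_H, K_D, alpha, gamma, A0, tau_end, seed):
    """Run one life span; return (final_A, time_avg_A); final_A = -1 on cap."""
    np.random.seed(seed)
    A = A0
    t = 0.0
    acc = 0.0
    for _ in range(MAX_EVENTS):
        f = k * (alpha + (1.0 - alpha) * _hill_nb(A, n_H, K_D))
        tot = f + gamma * A
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= tau_end:
            acc += (tau_end - t) * A
            return A, acc / tau_end
        acc += dt * A
        t += dt
        if np.random.random() * tot < f:
            A += 1
        else:
            A -= 1
    return -1, -1.0


@njit(cache=True)
def _ssa_record(k, n_H, K_D, alpha, gamma, A0, tau_end, seed, times, states):
    """As _ssa_final but records the path; returns (n_events, final_A, avg)."""
    np.random.seed(seed)
    A = A0
    t = 0.0
    acc = 0.0
    cap = times.shape[0]
    times[0] = 0.0
    states[0] = A
    n = 1
    while True:
        f = k * (alpha + (1.0 - alpha) * _hill_nb(A, n_H, K_D))
        tot = f + gamma * A
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= tau_end:
            acc += (tau_end - t) * A
            return n, A, acc / tau_end
        acc += dt * A
        t += dt
        if np.random.random() * tot < f:
            A += 1
        else:
            A -= 1
        if n >= cap:
            return -1, A, -1.0
        times[n] = t
        states[n] = A
        n += 1


@njit(cache=True)
def _ssa_final_cached(k, n_H, K_D, alpha, gamma, A0, tau_end, seed,
                      f_cache, stamp, tag):
    """As _ssa_final, memoizing f(A) per visited state (same RNG stream)."""
    np.random.seed(seed)
    A = A0
    t = 0.0
    acc = 0.0
    cap = f_cache.shape[0]
    for _ in range(MAX_EVENTS):
        if A < cap:
            if stamp[A] != tag:
                f_cache[A] = k * (alpha + (1.0 - alpha) * _hill_nb(A, n_H, K_D))
                stamp[A] = tag
            f = f_cache[A]
        else:
            f = k * (alpha + (1.0 - alpha) * _hill_nb(A, n_H, K_D))
        tot = f + gamma * A
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= tau_end:
            acc += (tau_end - t) * A
            return A, acc / tau_end
        acc += dt * A
        t += dt
        if np.random.random() * tot < f:
            A += 1
        else:
            A -= 1
    return -1, -1.0


@njit(cache=True)
def _ssa_population(ks, nHs, KDs, alpha, gamma, A0s, tau_end, seeds, tags,
                    out_final, out_avg):
    cap = 4096
    f_cache = np.empty(cap)
    stamp = np.full(cap, -1, dtype=np.int64)
    for i in range(ks.shape[0]):
        # tags identify genotypes so cells sharing one reuse cached f(A)
        a, m = _ssa_final_cached(ks[i], nHs[i], KDs[i], alpha, gamma,
                                 A0s[i], tau_end, seeds[i], f_cache, stamp,
                                 tags[i])
        out_final[i] = a
        out_avg[i] = m


def simulate_cell(g: Genotype, A0: int, tau_end: float = DEFAULT_TAU,
                  seed: int = 0, record: bool = False) -> Trajectory:
    """Gillespie simulation of one cell for ``tau_end`` time units.

    Waiting times are exponential with rate f(A) + gamma*A; the event is a
    synthesis with probability f(A)/(f(A)+gamma*A).  At A = 0 only synthesis
    can fire (propensity k*alpha > 0), so the count stays non-negative.
    With ``record=False`` only the endpoint and time average are kept and the
    times/states arrays are empty.
    """
    if A0 < 0:
        raise ValueError("initial protein count must be non-negative")
    if tau_end <= 0:
        raise ValueError("tau_end must be positive")
    seed = int(seed) & 0x7FFFFFFF or 1
    if not record:
        a, m = _ssa_final(g.k, g.n_H, g.K_D, g.alpha, g.gamma,
                          int(A0), float(tau_end), seed)
        if a < 0:
            raise EventCapExceeded(f"more than {MAX_EVENTS} events in one life span")
        return Trajectory(np.empty(0), np.empty(0, dtype=np.int64), int(a), float(m))
    scale = g.k / g.gamma + max(A0, g.k / g.gamma)
    cap = int(100 + 20 * (g.k + g.gamma * scale) * tau_end)
    while True:
        times = np.empty(cap)
        states = np.empty(cap, dtype=np.int64)
        n, a, m = _ssa_record(g.k, g.n_H, g.K_D, g.alpha, g.gamma,
                              int(A0), float(tau_end), seed, times, states)
        if n > 0:
            return Trajectory(times[:n].copy(), states[:n].copy(),
                              int(a), float(m))
        cap *= 2
        if cap > 4 * MAX_EVENTS:
            raise EventCapExceeded(
                f"more than {MAX_EVENTS} events in one life span")


def simulate_population(ks, nHs, KDs, A0s, seeds, tau_end: float = DEFAULT_TAU,
                        alpha: float = 0.25, gamma: float = 1.0, tags=None):
    """Vectorized SSA over a population; returns (final_A, time_avg_A) arrays.

    ``tags`` (optional integer array) identifies cells sharing a genotype so
    the kernel can reuse cached propensities; results are identical with or
    without it.  Raises :class:`EventCapExceeded` if any cell hits the
    event cap.
    """
    ks = np.ascontiguousarray(ks, dtype=np.float64)
    nHs = np.ascontiguousarray(nHs, dtype=np.float64)
    KDs = np.ascontiguousarray(KDs, dtype=np.float64)
    A0s = np.ascontiguousarray(A0s, dtype=np.int64)
    seeds = np.ascontiguousarray(seeds, dtype=np.int64)
    if tags is None:
        tags = np.arange(ks.shape[0], dtype=np.int64)
    else:
        tags = np.ascontiguousarray(tags, dtype=np.int64)
    out_final = np.empty(ks.shape[0], dtype=np.int64)
    out_avg = np.empty(ks.shape[0])
    _ssa_population(ks, nHs, KDs, alpha, gamma, A0s, float(tau_end), seeds,
                    tags, out_final, out_avg)
    if np.any(out_final < 0):
        raise EventCapExceeded(f"more than {MAX_EVENTS} events in one life span")
    return out_final, out_avg


def empirical_distribution(g: Genotype, A0: int, tau_end: float, n_reps: int,
                           seed: int = 0, A_max: int | None = None):
    """Normalized histogram of final_A over ``n_reps`` independent cells.

    Returns a :class:`~episwitch.fsp_analysis.DistributionVector` over states
    0..A_max (A_max defaults to the largest observed count); sums to 1.
    """
    from .fsp_analysis import DistributionVector

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = np.full(n_reps, 1.0)
    seeds = derive_seeds(seed, 0, np.arange(n_reps))
    finals, _ = simulate_population(
        g.k * n, g.n_H * n, g.K_D * n, np.full(n_reps, A0, dtype=np.int64),
        seeds, tau_end=tau_end, alpha=g.alpha, gamma=g.gamma)
    hi = int(finals.max()) if A_max is None else int(A_max)
    counts = np.bincount(finals, minlength=hi + 1)
    # counts beyond A_max (if a caller fixed it) are dropped, mirroring FSP leak
    probs = counts[: hi + 1] / n_reps
    return DistributionVector(probs=probs, A_max=hi)
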