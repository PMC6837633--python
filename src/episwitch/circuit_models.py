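"""Deterministic analysis of the self-activating gene circuit.

The circuit is a single gene whose protein product *A* activates its own
synthesis through a Hill function,

    f(A) = k * (alpha + (1 - alpha) * A^n_H / (A^n_H + K_D^n_H)),

with first-order degradation ``gamma * A``.  The deterministic mean-field
dynamics ``dA/dtau = f(A) - gamma*A`` have one or three fixed points; when two
of them are stable the genotype is *bistable* and the stochastic circuit can
behave as an epigenetic switch.

This module provides the rate function, fixed-point/stability analysis, the
closed-form "solution" synthesis rate k* that places a prescribed steady state
at a target expression level, and the analogous reduction for a two-gene
toggle switch used as an alternative bistable architecture.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PARAM_BOUNDS",
    "Genotype",
    "ToggleGenotype",
    "StabilityProfile",
    "synthesis_rate",
    "stability_profile",
    "cached_profile",
    "is_bistable",
    "solution_k",
    "toggle_synthesis_rate",
    "toggle_stability_profile",
    "toggle_solution_kA",
]

#: Physiological range for the evolvable parameters (k, n_H, K_D), typical of
#: a bacterial transcription factor.  Mutations are clamped to this box.
PARAM_BOUNDS = {
    "k": (1e-2, 1e3),
    "n_H": (1e-2, 16.0),
    "K_D": (1e-2, 120.0),
}

#: Absolute tolerance (proteins) to which fixed points are resolved.
ROOT_ATOL = 1e-6


@dataclass(frozen=True)
class Genotype:
    """Evolvable biophysical parameters of the self-activating gene.

    Parameters
    ----------
    k : float
        Maximum synthesis rate (proteins per unit dimensionless time).
    n_H : float
        Hill coefficient (degree of molecular cooperativity).
    K_D : float
        Protein-DNA dissociation constant (proteins).
    alpha : float
        Basal synthesis rate relative to ``k`` (0 < alpha <= 1).
    gamma : float
        Protein degradation rate constant; time is rescaled so gamma = 1.
    """

    k: float
    n_H: float
    K_D: float
    alpha: float = 0.25
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.n_H > 0 and self.K_D > 0):
            raise ValueError("k, n_H and K_D must be strictly positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")

    def within_bounds(self) -> bool:
        """True if (k, n_H, K_D) lie inside the physiological box."""
        return (
            PARAM_BOUNDS["k"][0] <= self.k <= PARAM_BOUNDS["k"][1]
            and PARAM_BOUNDS["n_H"][0] <= self.n_H <= PARAM_BOUNDS["n_H"][1]
            and PARAM_BOUNDS["K_D"][0] <= self.K_D <= PARAM_BOUNDS["K_D"][1]
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "nH": self.n_H,
            "KD": self.K_D,
            "alpha": self.alpha,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genotype":
        return cls(
            k=float(d["k"]),
            n_H=float(d["nH"]),
            K_D=float(d["KD"]),
            alpha=float(d.get("alpha", 0.25)),
            gamma=float(d.get("gamma", 1.0)),
        )


@dataclass(frozen=True)
class ToggleGenotype:
    """Parameters of the mutual-repression toggle switch variant.

    Gene A (selected) is repressed by B, which is in turn repressed by A.
    The repressor is assumed at quasi-steady state B*(A), reducing the system
    to an effective one-variable self-activator.
    """

    k_A: float
    n_A: float
    K_A: float
    alpha_A: float = 0.25
    k_B: float = 50.0
    alpha_B: float = 0.2
    K_B: float = 20.0
    n_B: float = 5.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.k_A, self.n_A, self.K_A, self.alpha_A,
                self.k_B, self.alpha_B, self.K_B, self.n_B, self.gamma)
        if not all(v > 0 for v in vals):
            raise ValueError("all toggle parameters must be positive")


@dataclass(frozen=True)
class StabilityProfile:
    """Fixed points of the one-dimensional flow, with stability labels.

    ``fixed_points`` is sorted ascending; stable and unstable points
    alternate, and (for this bounded, positive-at-zero flow) the first and
    last fixed points are stable.
    """

    fixed_points: tuple = field(default_factory=tuple)  # ((A*, stable), ...)

    @property
    def stable_points(self) -> tuple:
        return tuple(a for a, s in self.fixed_points if s)

    @property
    def unstable_points(self) -> tuple:
        return tuple(a for a, s in self.fixed_points if not s)

    @property
    def n_stable(self) -> int:
        return len(self.stable_points)

    @property
    def is_bistable(self) -> bool:
        return self.n_stable >= 2

    def basin_endpoint(self, A0: float) -> float:
        """Stable fixed point whose basin of attraction contains ``A0``.

        Basin membership is decided by position relative to the unstable
        fixed points; an initial condition exactly on an unstable point is
        assigned to the lower stable state.
        """
        stable = self.stable_points
        if len(stable) == 1:
            return stable[0]
        unstable = self.unstable_points
        # index of the basin: number of unstable points strictly below A0
        i = int(np.searchsorted(unstable, A0, side="left"))
        return stable[min(i, len(stable) - 1)]


def _hill(A, n_H: float, K_D: float):
    """Occupancy A^n / (A^n + K^n), numerically safe for large exponents."""
    A = np.asarray(A, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        x = (A / K_D) ** n_H
        h = np.where(np.isinf(x), 1.0, x / (1.0 + x))
    return h


def synthesis_rate(g: Genotype, A):
    """Hill-type synthesis propensity f(A); monotone, bounded in [k*alpha, k].

    Accepts scalar or array ``A`` (proteins, >= 0).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("protein count A must be non-negative")
    f = g.k * (g.alpha + (1.0 - g.alpha) * _hill(A, g.n_H, g.K_D))
    return float(f) if f.ndim == 0 else f


def _scan_grid(hi: float, n_lin: int = 2001, n_log: int = 400) -> np.ndarray:
    lin = np.linspace(0.0, hi, n_lin)
    log = np.geomspace(max(hi * 1e-8, 1e-8), hi, n_log)
    return np.unique(np.concatenate([lin, log]))


def _profile_from_flow(flow, hi: float) -> StabilityProfile:
    """Root-find flow(A) = 0 on [0, hi] by bracketing + bisection.

    The grid combines linear and log spacing so roots near zero are resolved;
    each sign-change bracket is refined by Brent's method.  Tangential
    (double) roots without a sign change are skipped, so n_stable counts sign
    changes only.
    """
    grid = _scan_grid(hi)
    vals = flow(grid)
    fps = []
    sign = np.sign(vals)
    # treat exact zeros on the grid as roots
    for i in np.nonzero(sign == 0)[0]:
        stable = i + 1 < len(vals) and vals[i + 1] < 0
        fps.append((float(grid[i]), bool(stable)))
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        root = brentq(flow, grid[i], grid[i + 1], xtol=ROOT_ATOL * 1e-3)
        stable = vals[i] > 0  # flow goes + -> - across a stable point
        fps.append((float(root), bool(stable)))
    fps.sort()
    # merge duplicates within tolerance
    merged = []
    for a, s in fps:
        if merged and abs(a - merged[-1][0]) < 10 * ROOT_ATOL:
            continue
        merged.append((a, s))
    return StabilityProfile(fixed_points=tuple(merged))


def stability_profile(g: Genotype) -> StabilityProfile:
    """All fixed points of dA/dtau = f(A) - gamma*A with stability labels.

    At least one fixed point always exists: f(0) = k*alpha > 0 and f is
    bounded above by k, so the flow is positive at 0 and negative beyond
    k/gamma.
    """
    hi = 1.05 * g.k / g.gamma + 1.0
    return _profile_from_flow(
        lambda A: synthesis_rate(g, A) - g.gamma * np.asarray(A, float), hi
    )


@functools.lru_cache(maxsize=1 << 18)
def cached_profile(k: float, n_H: float, K_D: float,
                   alpha: float = 0.25, gamma: float = 1.0) -> StabilityProfile:
    """Memoized stability_profile keyed on the raw parameter tuple."""
    return stability_profile(Genotype(k, n_H, K_D, alpha, gamma))


def is_bistable(g: Genotype) -> bool:
    return cached_profile(g.k, g.n_H, g.K_D, g.alpha, g.gamma).is_bistable


def solution_k(A_star: float, n_H: float, K_D: float,
               alpha: float = 0.25, gamma: float = 1.0,
               check_bounds: bool = True) -> tuple:
    """Synthesis rate k* making ``A_star`` a fixed point, and its validity.

    k* = gamma*A*(A*^n + K_D^n) / (A*^n + alpha*K_D^n).  The genotype
    (k*, n_H, K_D) is a *solution genotype* for an environment whose optimum
    is ``A_star`` only if that fixed point is stable and k* lies within the
    physiological range; ``valid`` reports both checks.

    Returns
    -------
    (k_star, valid)
    """
    if A_star <= 0:
        raise ValueError("A_star must be positive")
    # work with the ratio (A*/K_D)^n to avoid overflow at large n_H
    with np.errstate(over="ignore"):
        x = (A_star / K_D) ** n_H
    if np.isinf(x):
        k_star = gamma * A_star
    else:
        k_star = gamma * A_star * (x + 1.0) / (x + alpha)
    valid = True
    lo, hi = PARAM_BOUNDS["k"]
    if check_bounds and not lo <= k_star <= hi:
        valid = False
    if valid:
        prof = stability_profile(Genotype(k_star, n_H, K_D, alpha, gamma))
        valid = any(s and abs(a - A_star) < 1e-4 * max(1.0, A_star)
                    for a, s in prof.fixed_points)
    return float(k_star), bool(valid)


# ---------------------------------------------------------------------------
# Toggle-switch variant (quasi-steady-state reduction of the repressor)
# ---------------------------------------------------------------------------

def _toggle_B_star(tg: ToggleGenotype, A):
    """Quasi-steady repressor level B*(A) (repression of B by A)."""
    rep = 1.0 - _hill(A, tg.n_B, tg.K_B)  # K_B^n / (K_B^n + A^n)
    return (tg.k_B / tg.gamma) * (tg.alpha_B + (1.0 - tg.alpha_B) * rep)


def toggle_synthesis_rate(tg: ToggleGenotype, A):
    """Effective synthesis rate of gene A with B at quasi-steady state."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("protein count A must be non-negative")
    B = _toggle_B_star(tg, A)
    act = 1.0 - _hill(B, tg.n_A, tg.K_A)  # K_A^n / (K_A^n + B^n)
    f = tg.k_A * (tg.alpha_A + (1.0 - tg.alpha_A) * act)
    return float(f) if f.ndim == 0 else f


def toggle_stability_profile(tg: ToggleGenotype) -> StabilityProfile:
    """Fixed points of the reduced toggle flow f_A(A) - gamma*A."""
    hi = 1.05 * tg.k_A / tg.gamma + 1.0
    return _profile_from_flow(
        lambda A: toggle_synthesis_rate(tg, A) - tg.gamma * np.asarray(A, float),
        hi,
    )


def toggle_solution_kA(A_star: float, tg: ToggleGenotype,
                       k_bounds: tuple = PARAM_BOUNDS["k"]) -> tuple:
    """k_A* placing a fixed point of the reduced toggle at ``A_star``.

    Returns (k_A*, valid) analogously to :func:`solution_k`.
    """
    if A_star <= 0:
        raise ValueError("A_star must be positive")
    B = _toggle_B_star(tg, A_star)
    act = tg.alpha_A + (1.0 - tg.alpha_A) * (1.0 - float(_hill(B, tg.n_A, tg.K_A)))
    k_star = tg.gamma * A_star / act
    valid = k_bounds[0] <= k_star <= k_bounds[1]
    if valid:
        tg2 = ToggleGenotype(k_A=k_star, n_A=tg.n_A, K_A=tg.K_A,
                             alpha_A=tg.alpha_A, k_B=tg.k_B, alpha_B=tg.alpha_B,
                             K_B=tg.K_B, n_B=tg.n_B, gamma=tg.gamma)
        prof = toggle_stability_profile(tg2)
        valid = any(s and abs(a - A_star) < 1e-4 * max(1.0, A_star)
                    for a, s in prof.fixed_points)
    return float(k_star), bool(valid)
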