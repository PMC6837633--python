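"""Solution-genotype manifolds and the genetic-potential map.

For a target steady state A* (the optimum of environment E) and each point
(n_H, K_D) of the parameter plane, the synthesis rate k* that places a fixed
point at A* is unique (see :func:`episwitch.circuit_models.solution_k`); the
resulting genotype theta*(E) = (k*, n_H, K_D) is a *solution genotype* when
that fixed point is stable and k* is physiological.

The *genetic potential* d_M(theta*(E)) of a solution genotype is the minimum
mutational distance to any solution genotype of the alternative environment,
measured as the Euclidean norm in log-base-M parameter space -- i.e. in
units of the maximum single-mutation step.  Cells where
min(d_M(theta*(L)), d_M(theta*(H))) is ~0 are exactly those where one
genotype solves both environments: the bistable epigenetic-switch region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_models import Genotype, ToggleGenotype, solution_k, toggle_solution_kA
from .environments import ENV_HIGH, ENV_LOW, Environment

__all__ = [
    "SolutionGenotype",
    "default_grid",
    "solution_manifold",
    "mutational_distance",
    "potential_map",
    "toggle_solution_manifold",
    "toggle_potential_map",
]


@dataclass(frozen=True)
class SolutionGenotype:
    n_H: float
    K_D: float
    env: str
    k_star: float
    valid: bool


def default_grid(n_nH: int = 40, n_KD: int = 48):
    """Log-spaced (n_H, K_D) grid over the figure axes ranges."""
    return np.geomspace(1.0, 16.0, n_nH), np.geomspace(1.0, 120.0, n_KD)


def solution_manifold(env: Environment, nH_grid, KD_grid,
                      alpha: float = 0.25, gamma: float = 1.0) -> pd.DataFrame:
    """Solution genotypes theta*(env) on the grid, with validity flags."""
    rows = []
    for nH in np.asarray(nH_grid, dtype=float):
        for KD in np.asarray(KD_grid, dtype=float):
            k_star, valid = solution_k(env.A_opt, nH, KD, alpha, gamma)
            rows.append((nH, KD, env.label, k_star, valid))
    return pd.DataFrame(rows, columns=["n_H", "K_D", "env", "k_star", "valid"])


def mutational_distance(a: Genotype, b: Genotype, M: float) -> float:
    """Distance between genotypes in mutation-step units.

    Euclidean norm of (log k, log n_H, log K_D) differences divided by
    log M; a single spherical mutation with step-size M moves a genotype by
    at most 1 in this metric.
    """
    if M <= 1:
        raise ValueError("mutation step-size M must exceed 1")
    d = np.array([
        np.log(a.k / b.k),
        np.log(a.n_H / b.n_H),
        np.log(a.K_D / b.K_D),
    ])
    return float(np.linalg.norm(d) / np.log(M))


def _log_coords(df: pd.DataFrame) -> np.ndarray:
    return np.log(df[["k_star", "n_H", "K_D"]].to_numpy(dtype=float))


def _min_distances(src: pd.DataFrame, alt_valid: pd.DataFrame, M: float) -> np.ndarray:
    """Min log-M distance from each source row to the valid alternative set."""
    if alt_valid.empty:
        raise ValueError("alternative manifold has no valid solution genotypes")
    A = _log_coords(src)  # (n, 3)
    B = _log_coords(alt_valid)  # (m, 3)
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1)) / np.log(M)


def potential_map(nH_grid, KD_grid, M: float, alpha: float = 0.25,
                  gamma: float = 1.0) -> pd.DataFrame:
    """Genetic-potential map over the (n_H, K_D) grid for step-size M.

    For each grid cell: d_L (distance from theta*(L) to the nearest valid
    theta*(H) on the grid), d_H (symmetric), and combined = min(d_L, d_H).
    Distances are NaN where the cell's own solution genotype is invalid;
    the minimum runs over valid alternative genotypes only.
    """
    if M <= 1:
        raise ValueError("mutation step-size M must exceed 1")
    man_L = solution_manifold(ENV_LOW, nH_grid, KD_grid, alpha, gamma)
    man_H = solution_manifold(ENV_HIGH, nH_grid, KD_grid, alpha, gamma)
    d_L = np.full(len(man_L), np.nan)
    d_H = np.full(len(man_H), np.nan)
    d_L[man_L["valid"].to_numpy()] = _min_distances(
        man_L[man_L["valid"]], man_H[man_H["valid"]], M)
    d_H[man_H["valid"].to_numpy()] = _min_distances(
        man_H[man_H["valid"]], man_L[man_L["valid"]], M)
    out = man_L[["n_H", "K_D"]].copy()
    out["d_L"] = d_L
    out["d_H"] = d_H
    out["combined"] = np.fmin(d_L, d_H)  # NaN-ignoring min
    out["valid_L"] = man_L["valid"].to_numpy()
    out["valid_H"] = man_H["valid"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Toggle-switch variant: manifold over (n_A, K_A)
# ---------------------------------------------------------------------------

def toggle_solution_manifold(env: Environment, nA_grid, KA_grid,
                             base: ToggleGenotype | None = None) -> pd.DataFrame:
    """Solution genotypes of the reduced toggle switch on an (n_A, K_A) grid."""
    rows = []
    for nA in np.asarray(nA_grid, dtype=float):
        for KA in np.asarray(KA_grid, dtype=float):
            tg = ToggleGenotype(k_A=1.0, n_A=nA, K_A=KA) if base is None else \
                ToggleGenotype(k_A=1.0, n_A=nA, K_A=KA, alpha_A=base.alpha_A,
                               k_B=base.k_B, alpha_B=base.alpha_B,
                               K_B=base.K_B, n_B=base.n_B, gamma=base.gamma)
            k_star, valid = toggle_solution_kA(env.A_opt, tg)
            rows.append((nA, KA, env.label, k_star, valid))
    return pd.DataFrame(rows, columns=["n_H", "K_D", "env", "k_star", "valid"])


def toggle_potential_map(nA_grid, KA_grid, M: float,
                         base: ToggleGenotype | None = None) -> pd.DataFrame:
    """Genetic-potential map of the toggle switch over (n_A, K_A)."""
    if M <= 1:
        raise ValueError("mutation step-size M must exceed 1")
    man_L = toggle_solution_manifold(ENV_LOW, nA_grid, KA_grid, base)
    man_H = toggle_solution_manifold(ENV_HIGH, nA_grid, KA_grid, base)
    d_L = np.full(len(man_L), np.nan)
    d_H = np.full(len(man_H), np.nan)
    d_L[man_L["valid"].to_numpy()] = _min_distances(
        man_L[man_L["valid"]], man_H[man_H["valid"]], M)
    d_H[man_H["valid"].to_numpy()] = _min_distances(
        man_H[man_H["valid"]], man_L[man_L["valid"]], M)
    out = man_L[["n_H", "K_D"]].rename(columns={"n_H": "n_A", "K_D": "K_A"})
    out["d_L"] = d_L
    out["d_H"] = d_H
    out["combined"] = np.fmin(d_L, d_H)
    out["valid_L"] = man_L["valid"].to_numpy()
    out["valid_H"] = man_H["valid"].to_numpy()
    return out
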