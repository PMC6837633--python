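"""Chemical-master-equation analysis by Finite State Projection (FSP).

The one-species birth-death CME is truncated to protein counts 0..A_max,
giving a tridiagonal generator B with birth rates f(a) and death rates
gamma*a.  The birth rate out of A_max is dropped, so the truncation is
absorbing and the mass that leaks out of the retained states bounds the
truncation error.  Transient distributions are obtained as the action of
the matrix exponential, rho(tau) = exp(B*tau) rho(0).

On top of the propagator this module computes, per genotype:

* the stationary distribution (product-form detailed balance),
* the *noise load* -- the expected fitness decay over one cell life span
  starting from the environment's optimal phenotype, and
* the *epimutation probability* -- the probability that a cell selected at
  one environment's optimum ends its life span with a good fitness score
  (omega >= 0.5) in the alternative environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from scipy.special import logsumexp

from .circuit_models import Genotype, solution_k, synthesis_rate
from .environments import ENV_HIGH, ENV_LOW, Environment, fitness_score

__all__ = [
    "DistributionVector",
    "FSPTruncationError",
    "build_generator",
    "propagate_fsp",
    "auto_A_max",
    "transient_distribution",
    "stationary_distribution",
    "noise_load",
    "epimutation_probability",
    "noise_map",
]

#: default bound on acceptable FSP leak at tau = 4
LEAK_TOL = 1e-8


class FSPTruncationError(RuntimeError):
    """Probability leak exceeded tolerance; enlarge A_max."""


@dataclass(frozen=True)
class DistributionVector:
    """Probability mass over protein counts 0..A_max.

    Entries are non-negative and sum to <= 1; the deficit is the mass that
    leaked past the truncation boundary.
    """

    probs: np.ndarray
    A_max: int

    @property
    def leak(self) -> float:
        return float(1.0 - self.probs.sum())

    @property
    def mean(self) -> float:
        return float(np.arange(self.A_max + 1) @ self.probs)

    @classmethod
    def point_mass(cls, a: int, A_max: int) -> "DistributionVector":
        p = np.zeros(A_max + 1)
        p[a] = 1.0
        return cls(probs=p, A_max=A_max)


def total_variation(p: DistributionVector, q: DistributionVector) -> float:
    """Total-variation distance; supports of different size are zero-padded."""
    n = max(p.A_max, q.A_max) + 1
    a = np.zeros(n)
    b = np.zeros(n)
    a[: p.probs.size] = p.probs
    b[: q.probs.size] = q.probs
    return 0.5 * float(np.abs(a - b).sum())


def build_generator(g: Genotype, A_max: int) -> sp.csc_matrix:
    """Tridiagonal CME generator on states 0..A_max (absorbing truncation).

    Off-diagonals carry births f(a) (a -> a+1, dropped at a = A_max) and
    deaths gamma*a; the diagonal is -(f(a) + gamma*a), so interior column
    sums are zero and the column sum at A_max is -f(A_max).
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    states = np.arange(A_max + 1)
    births = synthesis_rate(g, states)
    deaths = g.gamma * states
    diag = -(births + deaths)
    B = sp.diags(
        [births[:-1], diag, deaths[1:]], offsets=[-1, 0, 1], format="csc"
    )
    return B


def propagate_fsp(gen: sp.spmatrix, rho0: DistributionVector, tau: float,
                  leak_tol: float | None = None) -> DistributionVector:
    """rho(tau) = exp(B*tau) rho(0) via Krylov/Taylor matrix-exponential action.

    Entries are clipped of tiny negative round-off (< 1e-12); if the leaked
    mass exceeds ``leak_tol`` an :class:`FSPTruncationError` is raised so the
    caller can enlarge the state space.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    A_max = gen.shape[0] - 1
    if rho0.probs.size != A_max + 1:
        raise ValueError("rho0 support does not match generator size")
    if tau == 0:
        return rho0
    out = expm_multiply(gen * tau, rho0.probs)
    out = np.where(out < 0, np.where(out > -1e-12, 0.0, out), out)
    if np.any(out < 0):  # pragma: no cover - indicates a solver failure
        raise FSPTruncationError("negative probabilities from propagation")
    total = out.sum()
    if total > 1.0:  # round-off overshoot only; rescale to a probability
        if total > 1.0 + 1e-9:  # pragma: no cover
            raise FSPTruncationError("propagated mass exceeds 1")
        out = out / total
    res = DistributionVector(probs=out, A_max=A_max)
    if leak_tol is not None and res.leak > leak_tol:
        raise FSPTruncationError(
            f"FSP leak {res.leak:.3g} exceeds tolerance {leak_tol:.3g}")
    return res


def transient_distribution(g: Genotype, a0: int, tau: float = 4.0,
                           leak_tol: float = LEAK_TOL) -> DistributionVector:
    """FSP distribution at time ``tau`` from a point mass at ``a0``.

    The truncation starts at max(150, ceil(2k/gamma)) and doubles until the
    leaked mass falls below ``leak_tol``.
    """
    A_max = max(150, int(np.ceil(2 * g.k / g.gamma)), int(a0) + 10)
    while True:
        B = build_generator(g, A_max)
        rho = propagate_fsp(B, DistributionVector.point_mass(int(a0), A_max), tau)
        if rho.leak <= leak_tol:
            return rho
        A_max *= 2
        if A_max > 1 << 16:
            raise FSPTruncationError("A_max grew beyond 65536 without convergence")


def auto_A_max(g: Genotype, tau: float = 4.0, leak_tol: float = LEAK_TOL,
               a0: int | None = None) -> int:
    """Truncation bound at which the leak tolerance is met at time ``tau``."""
    probe = int(round(g.k * g.alpha / g.gamma)) if a0 is None else int(a0)
    return transient_distribution(g, probe, tau=tau, leak_tol=leak_tol).A_max


def stationary_distribution(g: Genotype, A_max: int | None = None) -> DistributionVector:
    """Exact stationary law of the birth-death chain (detailed balance).

    pi(a) is proportional to prod_{j=1..a} f(j-1)/(gamma*j), accumulated in
    log space and normalized; for constant f (alpha = 1) this is Poisson.
    """
    if A_max is None:
        A_max = max(150, int(np.ceil(2 * g.k / g.gamma)))
        # extend until the boundary mass is negligible
        while True:
            states = np.arange(1, A_max + 1)
            logratio = np.log(synthesis_rate(g, states - 1)) - np.log(g.gamma * states)
            logpi = np.concatenate([[0.0], np.cumsum(logratio)])
            logpi -= logsumexp(logpi)
            if logpi[-1] < np.log(1e-12):
                break
            A_max *= 2
    else:
        states = np.arange(1, A_max + 1)
        logratio = np.log(synthesis_rate(g, states - 1)) - np.log(g.gamma * states)
        logpi = np.concatenate([[0.0], np.cumsum(logratio)])
        logpi -= logsumexp(logpi)
    probs = np.exp(logpi)
    probs /= probs.sum()
    return DistributionVector(probs=probs, A_max=int(A_max))


def noise_load(g: Genotype, env: Environment, tau: float = 4.0,
               shape: str = "lorentzian") -> tuple[float, float]:
    """Expected fitness decay over one life span from the optimal phenotype.

    Starting from rho(A = A_opt, 0) = 1, returns
    ``(1 - E[omega_tau], E[omega_tau])`` where the expectation is over the
    FSP-propagated distribution at time ``tau``.  Any leaked mass counts as
    lost fitness (it is below the leak tolerance).
    """
    a0 = int(round(env.A_opt))
    rho = transient_distribution(g, a0, tau=tau)
    omega = fitness_score(np.arange(rho.A_max + 1), env, shape=shape)
    ef = float(omega @ rho.probs)
    return 1.0 - ef, ef


def epimutation_probability(g: Genotype, env_from: Environment,
                            env_to: Environment, tau: float = 4.0,
                            shape: str = "lorentzian") -> float:
    """P[omega^(to)(A_tau) >= 0.5 | A_0 = A_opt^(from)].

    A cell selected at the source environment's optimum that ends its life
    span inside the high-fitness window of the target environment counts as
    an epimutation; the probability is the FSP mass over the integer states
    with omega^(to) >= 0.5.
    """
    if env_from.label == env_to.label:
        raise ValueError("env_from and env_to must differ")
    a0 = int(round(env_from.A_opt))
    rho = transient_distribution(g, a0, tau=tau)
    states = np.arange(rho.A_max + 1)
    window = fitness_score(states, env_to, shape=shape) >= 0.5
    return float(rho.probs[window].sum())


def noise_map(nH_grid, KD_grid, tau: float = 4.0, alpha: float = 0.25,
              gamma: float = 1.0, with_epimutation: bool = True) -> pd.DataFrame:
    """Noise load and epimutation probability over a (n_H, K_D) grid.

    For each grid point and each environment the solution genotype
    theta*(E) = (k*, n_H, K_D) is formed; rows with an unstable or
    out-of-bounds k* are marked invalid (their FSP columns are NaN).

    Returns a tidy frame with columns
    (n_H, K_D, env, k_star, valid, noise_load, epimutation_prob).
    """
    rows = []
    for env in (ENV_LOW, ENV_HIGH):
        other = ENV_HIGH if env.label == "LOW" else ENV_LOW
        for nH in nH_grid:
            for KD in KD_grid:
                k_star, valid = solution_k(env.A_opt, nH, KD, alpha, gamma)
                nl = ep = np.nan
                if valid:
                    g = Genotype(k_star, nH, KD, alpha, gamma)
                    # one propagation serves both quantities
                    rho = transient_distribution(g, int(round(env.A_opt)), tau)
                    states = np.arange(rho.A_max + 1)
                    nl = 1.0 - float(fitness_score(states, env) @ rho.probs)
                    if with_epimutation:
                        window = fitness_score(states, other) >= 0.5
                        ep = float(rho.probs[window].sum())
                rows.append((nH, KD, env.label, k_star, valid, nl, ep))
    return pd.DataFrame(rows, columns=[
        "n_H", "K_D", "env", "k_star", "valid", "noise_load",
        "epimutation_prob"])
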