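"""Selective environments and the individual fitness score.

Two environments alternate: LOW selects for an optimal expression level of
A^(L) = 20 proteins, HIGH for A^(H) = 80.  Fitness of a cell with phenotype
A (its protein count at the end of its life span) is a Lorentzian peaked at
the optimum,

    omega(A) = eps^2 / (eps^2 + (A - A_opt)^2),   eps^2 = 0.2 * A_opt,

with Gaussian and step-function variants of comparable width available for
robustness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Environment", "ENV_LOW", "ENV_HIGH", "other_env", "fitness_score",
           "FITNESS_SHAPES"]

FITNESS_SHAPES = ("lorentzian", "gaussian", "step")

#: floor value of the step-shaped fitness outside its plateau
_STEP_FLOOR = 1e-6


@dataclass(frozen=True)
class Environment:
    """A selective environment: label, optimal phenotype, Lorentzian width."""

    label: str
    A_opt: float
    eps_sq: float

    @classmethod
    def from_optimum(cls, label: str, A_opt: float) -> "Environment":
        return cls(label=label, A_opt=A_opt, eps_sq=0.2 * A_opt)


ENV_LOW = Environment.from_optimum("LOW", 20.0)
ENV_HIGH = Environment.from_optimum("HIGH", 80.0)

_BY_LABEL = {"LOW": ENV_LOW, "HIGH": ENV_HIGH}


def get_env(label: str) -> Environment:
    return _BY_LABEL[label]


def other_env(env: Environment) -> Environment:
    return ENV_HIGH if env.label == "LOW" else ENV_LOW


def fitness_score(A, env: Environment, shape: str = "lorentzian"):
    """Fitness omega(A) in (0, 1], maximal at the environment's optimum.

    ``gaussian`` matches the Lorentzian's full width at half maximum
    (FWHM = 2*eps); ``step`` is 1 on |A - A_opt| <= 2*eps with a small floor
    elsewhere.  Accepts scalar or array ``A``.
    """
    A = np.asarray(A, dtype=float)
    d2 = (A - env.A_opt) ** 2
    if shape == "lorentzian":
        w = env.eps_sq / (env.eps_sq + d2)
    elif shape == "gaussian":
        sigma2 = env.eps_sq / (2.0 * math.log(2.0))  # FWHM = 2*eps
        w = np.exp(-d2 / (2.0 * sigma2))
    elif shape == "step":
        w = np.where(d2 <= 4.0 * env.eps_sq, 1.0, _STEP_FLOOR)
    else:
        raise ValueError(f"unknown fitness shape {shape!r}")
    return float(w) if w.ndim == 0 else w
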