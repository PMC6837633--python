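"""Generational evolutionary algorithm in a fluctuating environment.

A haploid, asexual population of N cells evolves with non-overlapping
generations.  Each generation:

1. every cell expresses the self-activating gene for one life span
   (tau = 4) starting from the protein level inherited from its parent --
   stochastically (Gillespie SSA) or, in CONTROL mode, deterministically
   (the cell relaxes to the stable fixed point whose basin contains the
   inherited level, which realizes hysteresis and forbids epimutation);
2. the Lorentzian fitness of the final protein count is evaluated against
   the current environment's optimum;
3. tournament selection (or truncation / fitness-proportional variants)
   fills the next generation;
4. each cloned cell mutates with probability u: a spherically symmetric
   multiplicative step of at most M-fold in (k, n_H, K_D), clamped to the
   physiological range;
5. the environment alternates between LOW and HIGH every 1/nu generations
   (or switches with probability nu per generation in stochastic mode).

The run emits one record per generation, one summary per complete
environmental cycle (LOW + HIGH epoch), and per-cycle lineage-strategy
fractions from the genealogical archive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit_models import PARAM_BOUNDS, Genotype, cached_profile
from .environments import (ENV_HIGH, ENV_LOW, Environment, fitness_score,
                           get_env)
from .lineage_tracker import (STRATEGY_LABELS, LineageArchive,
                              normalize_transitions)
from .stochastic_kinetics import derive_seeds, simulate_population

__all__ = [
    "Environment", "ENV_LOW", "ENV_HIGH", "fitness_score",
    "EnvironmentSchedule", "EvolutionConfig", "MutationDraw",
    "mutate_genotype", "select_next_generation", "advance_environment",
    "control_phenotype", "cycle_summary", "run_evolution", "EvolutionResult",
]

SELECTION_SCHEMES = ("tournament", "truncation", "proportional")
MUTATION_SCHEMES = ("spherical", "homogeneous_spherical", "cubic", "1d")
PHENOTYPE_MODES = ("final", "time_average")


# ---------------------------------------------------------------------------
# Environment schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentSchedule:
    """Alternation of LOW/HIGH epochs with fluctuation frequency nu.

    Periodic mode: epochs of exactly 1/nu generations (must be integer).
    Stochastic mode: the environment switches with probability nu each
    generation, giving geometric epoch lengths with mean 1/nu.
    """

    nu: float
    mode: str = "periodic"
    start_env: str = "LOW"

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if self.mode not in ("periodic", "stochastic"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "periodic":
            L = 1.0 / self.nu
            if abs(L - round(L)) > 1e-9:
                raise ValueError("periodic schedule needs integer 1/nu")
        if self.start_env not in ("LOW", "HIGH"):
            raise ValueError("start_env must be LOW or HIGH")

    @property
    def epoch_length(self) -> int:
        return int(round(1.0 / self.nu))

    def sequence(self, generations: int, rng: np.random.Generator | None = None):
        """Environment label per generation, plus epoch-end generation indices."""
        labels = np.empty(generations, dtype="U4")
        cur = self.start_env
        epoch_ends = []
        if self.mode == "periodic":
            L = self.epoch_length
            for g in range(generations):
                labels[g] = cur
                if (g + 1) % L == 0:
                    epoch_ends.append(g)
                    cur = "HIGH" if cur == "LOW" else "LOW"
        else:
            if rng is None:
                raise ValueError("stochastic schedule needs an rng")
            flips = rng.random(generations) < self.nu
            for g in range(generations):
                labels[g] = cur
                if flips[g]:
                    epoch_ends.append(g)
                    cur = "HIGH" if cur == "LOW" else "LOW"
        return labels, np.asarray(epoch_ends, dtype=int)


def advance_environment(schedule: EnvironmentSchedule, g: int,
                        rng: np.random.Generator | None = None) -> Environment:
    """Environment of generation ``g`` under a periodic schedule.

    (Stochastic schedules are realized once per run via
    :meth:`EnvironmentSchedule.sequence`; sampling them per call would not
    be reproducible.)
    """
    if schedule.mode != "periodic":
        raise ValueError("advance_environment is defined for periodic mode; "
                         "use EnvironmentSchedule.sequence for stochastic runs")
    L = schedule.epoch_length
    first = schedule.start_env
    second = "HIGH" if first == "LOW" else "LOW"
    return get_env(first if (g // L) % 2 == 0 else second)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EvolutionConfig:
    """All knobs of one evolutionary run."""

    N: int = 1000
    s_t: int = 40
    u: float = 0.03
    M: float = 1.1
    nu: float = 0.1
    generations: int = 2000
    tau: float = 4.0
    theta0: Genotype = field(default_factory=lambda: Genotype(80.0, 1.0, 10.0))
    selection_scheme: str = "tournament"
    mutation_scheme: str = "spherical"
    fitness_shape: str = "lorentzian"
    phenotype_mode: str = "final"
    control_mode: bool = False
    env_mode: str = "periodic"
    start_env: str = "LOW"
    master_seed: int = 0

    def validate(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if not 1 <= self.s_t <= self.N:
            raise ValueError("tournament size s_t must lie in [1, N]")
        if not 0 <= self.u <= 1:
            raise ValueError("mutation probability u must lie in [0, 1]")
        if self.M <= 1:
            raise ValueError("mutation step-size M must exceed 1")
        if self.tau <= 0:
            raise ValueError("life span tau must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.selection_scheme not in SELECTION_SCHEMES:
            raise ValueError(f"unknown selection scheme {self.selection_scheme!r}")
        if self.mutation_scheme not in MUTATION_SCHEMES:
            raise ValueError(f"unknown mutation scheme {self.mutation_scheme!r}")
        if self.phenotype_mode not in PHENOTYPE_MODES:
            raise ValueError(f"unknown phenotype mode {self.phenotype_mode!r}")
        # constructing the schedule validates nu/env_mode/start_env
        self.schedule()

    def schedule(self) -> EnvironmentSchedule:
        return EnvironmentSchedule(nu=self.nu, mode=self.env_mode,
                                   start_env=self.start_env)


@dataclass(frozen=True)
class MutationDraw:
    """The random variates of one spherical mutation event."""

    r: float
    phi1: float
    phi2: float


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def _clamp(val: float, lo: float, hi: float) -> float:
    return min(max(val, lo), hi)


def mutate_genotype(g: Genotype, M: float, scheme: str = "spherical",
                    rng: np.random.Generator | None = None,
                    draw: MutationDraw | None = None) -> Genotype:
    """One multiplicative mutation of (k, n_H, K_D), clamped to bounds.

    Spherical scheme: with r ~ U(0,1), phi1 ~ U(-1,1), phi2 ~ U(0,2pi),

        k   *= M^(r sqrt(1-phi1^2) cos phi2)
        n_H *= M^(r sqrt(1-phi1^2) sin phi2)
        K_D *= M^(r phi1)

    so the displacement in log-M space has norm exactly r <= 1.
    ``homogeneous_spherical`` substitutes r -> r^(1/3) (uniform density in
    the mutation ball); ``cubic`` uses three independent U(-1,1) exponents;
    ``1d`` mutates one uniformly chosen parameter by M^U(-1,1).
    """
    if M <= 1:
        raise ValueError("mutation step-size M must exceed 1")
    if scheme in ("spherical", "homogeneous_spherical"):
        if draw is None:
            draw = MutationDraw(r=rng.uniform(0, 1), phi1=rng.uniform(-1, 1),
                                phi2=rng.uniform(0, 2 * math.pi))
        r = draw.r ** (1.0 / 3.0) if scheme == "homogeneous_spherical" else draw.r
        s = math.sqrt(max(0.0, 1.0 - draw.phi1 ** 2))
        ek = r * s * math.cos(draw.phi2)
        en = r * s * math.sin(draw.phi2)
        eK = r * draw.phi1
    elif scheme == "cubic":
        ek, en, eK = rng.uniform(-1, 1, size=3)
    elif scheme == "1d":
        ek = en = eK = 0.0
        which = rng.integers(3)
        e = rng.uniform(-1, 1)
        if which == 0:
            ek = e
        elif which == 1:
            en = e
        else:
            eK = e
    else:
        raise ValueError(f"unknown mutation scheme {scheme!r}")
    return Genotype(
        k=_clamp(g.k * M ** ek, *PARAM_BOUNDS["k"]),
        n_H=_clamp(g.n_H * M ** en, *PARAM_BOUNDS["n_H"]),
        K_D=_clamp(g.K_D * M ** eK, *PARAM_BOUNDS["K_D"]),
        alpha=g.alpha,
        gamma=g.gamma,
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_next_generation(fitness: np.ndarray, s_t: int,
                           rng: np.random.Generator,
                           scheme: str = "tournament") -> np.ndarray:
    """Parent index for each of the N offspring slots.

    Tournament: N independent tournaments, each drawing s_t *distinct* cells
    uniformly; the fittest wins (ties broken uniformly at random via an
    infinitesimal random jitter).  Truncation: parents drawn uniformly from
    the top ceil(N/s_t) cells by fitness.  Proportional: parents drawn with
    probability fitness_i / sum(fitness).
    """
    fitness = np.asarray(fitness, dtype=float)
    N = fitness.size
    if not 1 <= s_t <= N:
        raise ValueError("s_t must lie in [1, N]")
    if scheme == "tournament":
        if s_t == 1:
            return rng.integers(0, N, size=N)
        # distinct cohort per tournament: first s_t of a random permutation
        keys = rng.random((N, N))
        cohorts = np.argpartition(keys, s_t - 1, axis=1)[:, :s_t]
        jitter = rng.random((N, s_t)) * 1e-12
        winners = np.argmax(fitness[cohorts] + jitter, axis=1)
        return cohorts[np.arange(N), winners]
    if scheme == "truncation":
        n_top = math.ceil(N / s_t)
        jitter = rng.random(N) * 1e-12
        top = np.argsort(fitness + jitter)[::-1][:n_top]
        return top[rng.integers(0, n_top, size=N)]
    if scheme == "proportional":
        p = fitness / fitness.sum()
        return rng.choice(N, size=N, p=p)
    raise ValueError(f"unknown selection scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Deterministic CONTROL phenotype
# ---------------------------------------------------------------------------

def control_phenotype(g: Genotype, A_inherited: float) -> float:
    """Steady-state phenotype of a noise-free cell (hysteresis).

    The cell relaxes to the stable fixed point whose basin contains its
    inherited protein level; an inherited level exactly at an unstable point
    goes to the lower stable state.
    """
    prof = cached_profile(g.k, g.n_H, g.K_D, g.alpha, g.gamma)
    return prof.basin_endpoint(A_inherited)


# ---------------------------------------------------------------------------
# Cycle summaries
# ---------------------------------------------------------------------------

def cycle_summary(records: pd.DataFrame, cycle_index: int) -> dict:
    """Geometric-mean fitness and per-cycle means over one complete cycle.

    W_cycle = (prod_g w_g)^(1/L); the raw log-product is kept alongside.
    """
    w = records["w"].to_numpy(dtype=float)
    L = w.size
    if L == 0:
        raise ValueError("cycle has no generations")
    logs = np.log(np.maximum(w, 1e-300))
    return {
        "cycle": cycle_index,
        "W_cycle": float(np.exp(logs.mean())),
        "log_w_product": float(logs.sum()),
        "mean_nH": float(records["mean_nH"].mean()),
        "mean_KD": float(records["mean_KD"].mean()),
        "mean_fB": float(records["f_B"].mean()),
    }


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

class _GenotypeTable:
    """Append-only registry of genotypes with cached bistability flags."""

    def __init__(self, g0: Genotype):
        self.genotypes: list[Genotype] = [g0]
        self.k = [g0.k]
        self.n_H = [g0.n_H]
        self.K_D = [g0.K_D]
        self._bistable: dict[int, bool] = {}

    def add(self, g: Genotype) -> int:
        self.genotypes.append(g)
        self.k.append(g.k)
        self.n_H.append(g.n_H)
        self.K_D.append(g.K_D)
        return len(self.genotypes) - 1

    def arrays(self):
        return (np.asarray(self.k), np.asarray(self.n_H), np.asarray(self.K_D))

    def bistable(self, gid: int) -> bool:
        flag = self._bistable.get(gid)
        if flag is None:
            g = self.genotypes[gid]
            flag = cached_profile(g.k, g.n_H, g.K_D, g.alpha, g.gamma).is_bistable
            self._bistable[gid] = flag
        return flag

    def bistable_of(self, gids: np.ndarray) -> np.ndarray:
        uniq = np.unique(gids)
        lut = {int(u): self.bistable(int(u)) for u in uniq}
        return np.fromiter((lut[int(i)] for i in gids), dtype=bool,
                           count=len(gids))

    def profile(self, gid: int):
        g = self.genotypes[gid]
        return cached_profile(g.k, g.n_H, g.K_D, g.alpha, g.gamma)


@dataclass
class EvolutionResult:
    """Outputs of one evolutionary run."""

    generations: pd.DataFrame  # g, env, w, f_B, mean_k, mean_nH, mean_KD
    cycles: pd.DataFrame  # cycle, W_cycle, log_w_product, means
    lineages: pd.DataFrame  # cycle, frac_ES/BA/GA/STATIC
    transitions: pd.DataFrame  # row-normalized previous -> current strategy
    archive: LineageArchive
    final_genotype_ids: np.ndarray
    genotype_table: _GenotypeTable


def run_evolution(config: EvolutionConfig,
                  progress: bool = False) -> EvolutionResult:
    """Run the full evolutionary simulation described in the module docstring.

    The founder population is isogenic at ``config.theta0`` with phenotypes
    at the deterministic stable state nearest the starting environment's
    optimum (rounded to an integer for stochastic runs).  Seeded runs are
    bit-reproducible: per-cell SSA streams are derived from
    (master_seed, generation, cell index) and the engine's own randomness
    uses dedicated SeedSequence children.
    """
    config.validate()
    N = config.N
    schedule = config.schedule()
    ss = np.random.SeedSequence(config.master_seed)
    rng_engine, rng_env = [np.random.default_rng(c) for c in ss.spawn(2)]
    env_labels, epoch_ends = schedule.sequence(config.generations, rng_env)
    # a cycle = two consecutive epochs; its end is every second epoch end
    cycle_ends = epoch_ends[1::2]

    table = _GenotypeTable(config.theta0)
    archive = LineageArchive(table.bistable_of)

    start_env = get_env(schedule.start_env)
    prof0 = table.profile(0)
    stable0 = np.asarray(prof0.stable_points)
    A_init = float(stable0[np.argmin(np.abs(stable0 - start_env.A_opt))])

    gid = np.zeros(N, dtype=np.int64)
    if config.control_mode:
        A_inherit = np.full(N, A_init)
    else:
        A_inherit = np.full(N, int(round(A_init)), dtype=np.int64)
    mutated = np.zeros(N, dtype=bool)
    archive.record(0, None, mutated, gid)

    gen_rows = []
    lineage_rows = []
    trans_counts = None
    n_trans_cycles = 0
    cycle_end_list = list(cycle_ends)
    cycle_ptr = 0

    for g in range(config.generations):
        env = get_env(env_labels[g])
        # --- express ------------------------------------------------------
        if config.control_mode:
            phen = np.empty(N)
            for u_gid in np.unique(gid):
                prof = table.profile(int(u_gid))
                mask = gid == u_gid
                stable = np.asarray(prof.stable_points)
                if stable.size == 1:
                    phen[mask] = stable[0]
                else:
                    unstable = np.asarray(prof.unstable_points)
                    basin = np.searchsorted(unstable, A_inherit[mask],
                                            side="left")
                    phen[mask] = stable[np.minimum(basin, stable.size - 1)]
        else:
            ks, nHs, KDs = table.arrays()
            seeds = derive_seeds(config.master_seed, g, np.arange(N))
            finals, avgs = simulate_population(
                ks[gid], nHs[gid], KDs[gid], A_inherit, seeds,
                tau_end=config.tau, alpha=config.theta0.alpha,
                gamma=config.theta0.gamma, tags=gid)
            phen = avgs if config.phenotype_mode == "time_average" else finals
        # --- fitness ------------------------------------------------------
        fit = fitness_score(phen, env, shape=config.fitness_shape)
        f_B = float(table.bistable_of(gid).mean())
        ks_, nHs_, KDs_ = table.arrays()
        gen_rows.append((g, env.label, float(np.mean(fit)), f_B,
                         float(ks_[gid].mean()), float(nHs_[gid].mean()),
                         float(KDs_[gid].mean())))
        # --- lineage statistics at cycle ends ----------------------------
        if cycle_ptr < len(cycle_end_list) and g == cycle_end_list[cycle_ptr]:
            c = cycle_ptr
            if c >= 2:
                t, t1, t2 = (cycle_end_list[c], cycle_end_list[c - 1],
                             cycle_end_list[c - 2])
                fr = archive.strategy_fractions(t, t1, t2)
                lineage_rows.append((c, fr["ES"], fr["BA"], fr["GA"],
                                     fr["STATIC"]))
            if c >= 3:
                t3 = cycle_end_list[c - 3]
                counts = archive.transition_counts(
                    cycle_end_list[c], cycle_end_list[c - 1],
                    cycle_end_list[c - 2], t3)
                trans_counts = counts if trans_counts is None else \
                    trans_counts + counts
                n_trans_cycles += 1
                archive.prune(t3)
            if progress:
                print(f"cycle {c} (gen {g}): w={np.mean(fit):.3f} f_B={f_B:.3f}")
            cycle_ptr += 1
        # --- reproduce ----------------------------------------------------
        if g == config.generations - 1:
            break
        parents = select_next_generation(fit, config.s_t, rng_engine,
                                         scheme=config.selection_scheme)
        new_gid = gid[parents]
        mut_mask = rng_engine.random(N) < config.u
        for i in np.nonzero(mut_mask)[0]:
            child = mutate_genotype(table.genotypes[int(new_gid[i])],
                                    config.M, config.mutation_scheme,
                                    rng_engine)
            new_gid[i] = table.add(child)
        if config.control_mode:
            A_inherit = np.asarray(phen, dtype=float)[parents]
        else:
            A_inherit = np.asarray(phen if config.phenotype_mode == "final"
                                   else finals, dtype=np.int64)[parents]
        gid = new_gid
        archive.record(g + 1, parents, mut_mask, gid)

    generations = pd.DataFrame(
        gen_rows, columns=["g", "env", "w", "f_B", "mean_k", "mean_nH",
                           "mean_KD"])
    # --- cycle summaries -------------------------------------------------
    cyc_rows = []
    prev_end = -1
    for c, t in enumerate(cycle_end_list):
        block = generations.iloc[prev_end + 1: t + 1]
        cyc_rows.append(cycle_summary(block, c))
        prev_end = t
    cycles = pd.DataFrame(cyc_rows) if cyc_rows else pd.DataFrame(
        columns=["cycle", "W_cycle", "log_w_product", "mean_nH", "mean_KD",
                 "mean_fB"])
    lineages = pd.DataFrame(
        lineage_rows,
        columns=["cycle", "frac_ES", "frac_BA", "frac_GA", "frac_STATIC"])
    if trans_counts is not None:
        transitions = normalize_transitions(trans_counts / n_trans_cycles)
    else:
        transitions = pd.DataFrame(0.0, index=list(STRATEGY_LABELS),
                                   columns=list(STRATEGY_LABELS))
    return EvolutionResult(
        generations=generations, cycles=cycles, lineages=lineages,
        transitions=transitions, archive=archive,
        final_genotype_ids=gid, genotype_table=table)
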