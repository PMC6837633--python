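"""Genealogy recording and adaptation-strategy classification.

Every generation the parent index, mutated-at-birth flag and genotype id of
each cell are archived.  At the end of an environmental cycle the ancestry
of each surviving cell is traced back two (or three) cycle boundaries and
the ancestral window between the 2-cycle and 1-cycle ancestors is
classified:

* **ES** (epigenetic switching): every genotype on the window bistable and
  zero mutations accumulated -- the lineage adapted purely by noise-induced
  state switching.
* **BA** (bistable adaptation): all bistable, but at least one mutation.
* **GA** (genetic adaptation): at least one monostable genotype and at
  least one mutation.
* **STATIC**: monostable with zero mutations; this satisfies none of the
  three definitions above and is reported as its own category (it can be
  folded into GA for three-way summaries).

Fractions are progeny-weighted: each surviving cell contributes the label
of its own ancestral window, shared ancestors counting once per descendant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["STRATEGY_LABELS", "LineageArchive", "classify_strategy",
           "StrategyReport"]

STRATEGY_LABELS = ("ES", "BA", "GA", "STATIC")


def classify_strategy(bistable_flags, mutation_flags) -> str:
    """Label one ancestral window.

    Parameters
    ----------
    bistable_flags : sequence of bool
        Bistability of the genotypes of the ancestors at every generation of
        the window, *including both endpoints* (length L+1 for an L-generation
        window).
    mutation_flags : sequence of bool
        Whether a mutation occurred at each birth inside the window
        (length L).
    """
    bistable_flags = np.asarray(bistable_flags, dtype=bool)
    mutation_flags = np.asarray(mutation_flags, dtype=bool)
    if bistable_flags.size == 0:
        raise ValueError("window must cover at least one generation")
    all_bi = bool(bistable_flags.all())
    mutated = bool(mutation_flags.any())
    if all_bi:
        return "BA" if mutated else "ES"
    return "GA" if mutated else "STATIC"


@dataclass
class _GenRecord:
    parent: np.ndarray | None  # index into previous generation (None at g=0)
    mutated: np.ndarray  # mutated at birth
    genotype_id: np.ndarray


@dataclass
class StrategyReport:
    """Per-cycle strategy fractions and the strategy-transition matrix."""

    fractions: pd.DataFrame  # columns: cycle, frac_ES, frac_BA, frac_GA, frac_STATIC
    transitions: pd.DataFrame | None = None  # row-normalized previous -> current

    @property
    def mean_fractions(self) -> pd.Series:
        return self.fractions[[f"frac_{s}" for s in STRATEGY_LABELS]].mean()

    def three_way(self) -> pd.DataFrame:
        """Three-way ES/BA/GA partition with STATIC lineages folded into GA."""
        out = self.fractions.copy()
        out["frac_GA"] = out["frac_GA"] + out["frac_STATIC"]
        return out.drop(columns=["frac_STATIC"])


class LineageArchive:
    """Bounded genealogical archive over the trailing environmental cycles.

    ``bistable_of`` maps an array of genotype ids to bistability flags; it is
    supplied by the evolution engine which owns the genotype table.
    """

    def __init__(self, bistable_of):
        self._gens: dict[int, _GenRecord] = {}
        self._bistable_of = bistable_of

    def record(self, g: int, parent, mutated, genotype_id) -> None:
        self._gens[g] = _GenRecord(
            parent=None if parent is None else np.asarray(parent, dtype=np.int32),
            mutated=np.asarray(mutated, dtype=bool),
            genotype_id=np.asarray(genotype_id, dtype=np.int64),
        )

    def prune(self, min_gen: int) -> None:
        """Drop generations before ``min_gen`` (ring-buffer memory bound)."""
        for g in [g for g in self._gens if g < min_gen]:
            del self._gens[g]

    def covers(self, g: int) -> bool:
        return g in self._gens

    def trace(self, t_from: int, t_to: int, idx: np.ndarray) -> np.ndarray:
        """Ancestor indices at generation ``t_to`` of cells ``idx`` at ``t_from``."""
        for g in range(t_from, t_to, -1):
            idx = self._gens[g].parent[idx]
        return idx

    def window_labels(self, t: int, t1: int, t2: int) -> np.ndarray:
        """Strategy label of the (t2, t1] ancestral window per cell alive at t.

        ``t1``/``t2`` are the 1-cycle and 2-cycle ancestor generations; the
        window genotypes include both endpoints, mutations are counted at
        births in (t2, t1].
        """
        if not (t2 < t1 <= t):
            raise ValueError("need t2 < t1 <= t")
        if not self.covers(t2):
            raise ValueError(f"archive does not cover generation {t2}")
        n = self._gens[t].genotype_id.size
        idx = self.trace(t, t1, np.arange(n))
        all_bi = np.asarray(
            self._bistable_of(self._gens[t1].genotype_id[idx]), dtype=bool
        ).copy()
        n_mut = np.zeros(n, dtype=np.int64)
        for g in range(t1, t2, -1):
            n_mut += self._gens[g].mutated[idx]
            idx = self._gens[g].parent[idx]
            all_bi &= self._bistable_of(self._gens[g - 1].genotype_id[idx])
        labels = np.where(
            all_bi,
            np.where(n_mut > 0, "BA", "ES"),
            np.where(n_mut > 0, "GA", "STATIC"),
        )
        return labels

    def strategy_fractions(self, t: int, t1: int, t2: int) -> dict[str, float]:
        """Progeny-weighted fraction of each strategy among cells alive at t."""
        labels = self.window_labels(t, t1, t2)
        n = labels.size
        return {s: float((labels == s).sum()) / n for s in STRATEGY_LABELS}

    def transition_counts(self, t: int, t1: int, t2: int, t3: int) -> pd.DataFrame:
        """Joint (previous, current) strategy counts for cells alive at t.

        Current strategy: window (t2, t1]; previous: window (t3, t2], both
        along each surviving cell's own ancestry.
        """
        cur = self.window_labels(t, t1, t2)
        prev = self.window_labels(t, t2, t3)
        mat = pd.DataFrame(0.0, index=list(STRATEGY_LABELS),
                           columns=list(STRATEGY_LABELS))
        for p, c in zip(prev, cur):
            mat.loc[p, c] += 1.0
        return mat


def normalize_transitions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a (previous -> current) count matrix; empty rows -> 0."""
    sums = counts.sum(axis=1)
    out = counts.div(sums.where(sums > 0, 1.0), axis=0)
    return out
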