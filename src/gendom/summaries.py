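"""Statistics over terminal states and replicate ensembles.

The headline observables of a constructionist run are the set of
*common alleles* (frequency strictly above a cutoff, 0.01 by default),
the population mean fitness, a centrality index of the common-allele
frequency vector, the heterozygote-versus-homozygote fitness contrast,
and, in random-alpha mode, the distribution of the weightings attached
to genotypes of common alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_model import PopulationState
from .engine import ReplicateRecord
from .equilibrium import broken_stick_batch

__all__ = [
    "common_alleles",
    "centrality",
    "broken_stick_null_I",
    "het_advantage_summary",
    "alpha_values_of_common",
    "ensemble_stats",
    "HetAdvantageSummary",
    "EnsembleStats",
]

DEFAULT_COMMON_CUTOFF = 0.01


def _frequencies(state_or_p) -> np.ndarray:
    if isinstance(state_or_p, PopulationState):
        return state_or_p.frequencies
    return np.asarray(state_or_p, dtype=float)


def common_alleles(state_or_p, cutoff: float = DEFAULT_COMMON_CUTOFF,
                   ) -> np.ndarray:
    """Indices of alleles at frequency strictly above the cutoff."""
    p = _frequencies(state_or_p)
    return np.flatnonzero(p > cutoff)


def centrality(p_common, renormalize: bool = False) -> float:
    """Centrality index ``I = sum_i (p_i - 1/n_c)^2`` over common alleles.

    ``I = 0`` means perfectly even frequencies; larger values mean a
    more lopsided polymorphism.  By default the raw common-allele
    frequencies are compared to ``1/n_c`` even though they need not sum
    to one once rare alleles are excluded; with ``renormalize=True`` the
    common frequencies are first rescaled to sum to one (a secondary
    variant, reported alongside the raw one in the CLI outputs).
    """
    p = np.asarray(p_common, dtype=float)
    if p.size == 0:
        raise ValueError("centrality needs at least one common allele")
    if renormalize:
        p = p / p.sum()
    return float(np.sum((p - 1.0 / p.size) ** 2))


def broken_stick_null_I(n_c: int, n_draws: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Null distribution of I for random (uniform-simplex) frequencies."""
    if n_c < 1:
        raise ValueError("need at least one common allele")
    draws = broken_stick_batch(n_c, n_draws, rng)
    return np.sum((draws - 1.0 / n_c) ** 2, axis=1)


@dataclass(frozen=True)
class HetAdvantageSummary:
    """Heterozygote/homozygote mean-fitness contrast among common alleles.

    The primary means weight each genotype by its random-mating
    frequency (p_i p_j, restricted to common alleles and renormalized);
    the unweighted means average the distinct genotype fitnesses
    directly.
    """

    mean_het_fitness: float
    mean_hom_fitness: float
    advantage: bool
    mean_het_fitness_unweighted: float
    mean_hom_fitness_unweighted: float


def het_advantage_summary(state: PopulationState,
                          cutoff: float = DEFAULT_COMMON_CUTOFF,
                          ) -> HetAdvantageSummary:
    """Compare mean heterozygote and homozygote fitness among common alleles."""
    idx = common_alleles(state, cutoff)
    if idx.size < 2:
        raise ValueError("heterozygote contrast needs at least two common alleles")
    p = state.frequencies[idx]
    W = state.fitness_matrix[np.ix_(idx, idx)]
    k = idx.size
    outer = np.outer(p, p)
    off = ~np.eye(k, dtype=bool)
    het_w = float(np.sum(outer[off] * W[off]) / np.sum(outer[off]))
    hom_w = float(np.sum(p ** 2 * np.diag(W)) / np.sum(p ** 2))
    iu = np.triu_indices(k, k=1)
    het_u = float(np.mean(W[iu]))
    hom_u = float(np.mean(np.diag(W)))
    return HetAdvantageSummary(mean_het_fitness=het_w,
                               mean_hom_fitness=hom_w,
                               advantage=het_w > hom_w,
                               mean_het_fitness_unweighted=het_u,
                               mean_hom_fitness_unweighted=hom_u)


def alpha_values_of_common(record_or_state,
                           cutoff: float = DEFAULT_COMMON_CUTOFF,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Weightings of genotypes whose component alleles are all common.

    Returns ``(alpha_ii, alpha_ij)``: the homozygote weightings of each
    common allele and the heterozygote weightings of each common pair.
    Only meaningful in random-alpha mode (per-genotype weighting matrix).
    """
    state = (record_or_state.final_state
             if isinstance(record_or_state, ReplicateRecord)
             else record_or_state)
    model = state.model
    if model is None or not model.random_alpha:
        raise ValueError("per-genotype weightings require a random-alpha model")
    idx = common_alleles(state, cutoff)
    A = model.weighting
    alpha_ii = np.array([A[i, i] for i in idx])
    alpha_ij = np.array([A[i, j] for k, i in enumerate(idx)
                         for j in idx[k + 1:]])
    return alpha_ii, alpha_ij


@dataclass(frozen=True, eq=False)
class EnsembleStats:
    """Summary of the terminal states of a replicate ensemble."""

    n_replicates: int
    histogram: dict[int, int]
    mode_n_common: int
    mode_tied: bool
    mean_n_common: float
    mean_fitness_by_n_common: dict[int, tuple[float, float, int]]
    alpha_ii_values: np.ndarray | None = None
    alpha_ij_values: np.ndarray | None = None

    @property
    def mean_alpha_ii(self) -> float | None:
        if self.alpha_ii_values is None or self.alpha_ii_values.size == 0:
            return None
        return float(self.alpha_ii_values.mean())

    @property
    def mean_alpha_ij(self) -> float | None:
        if self.alpha_ij_values is None or self.alpha_ij_values.size == 0:
            return None
        return float(self.alpha_ij_values.mean())


def ensemble_stats(records: Sequence[ReplicateRecord] | Iterable[ReplicateRecord],
                   cutoff: float = DEFAULT_COMMON_CUTOFF) -> EnsembleStats:
    """Histogram, mode and means of terminal common-allele counts.

    The modal ``n_c`` breaks ties toward the smallest count, with the
    tie reported explicitly.  In random-alpha mode the weightings of all
    genotypes among terminal common alleles are pooled across replicates.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one replicate record")
    ncs = np.array([int(np.sum(r.final_state.frequencies > cutoff))
                    for r in records])
    values, counts = np.unique(ncs, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    mode = int(values[tied[0]])
    wbar_by_nc: dict[int, tuple[float, float, int]] = {}
    wbars = np.array([r.terminal_mean_fitness for r in records])
    for v in values:
        sel = wbars[ncs == v]
        wbar_by_nc[int(v)] = (float(sel.mean()),
                              float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                              int(sel.size))
    random_alpha = all(r.config.random_alpha for r in records)
    aii = aij = None
    if random_alpha:
        ii_parts, ij_parts = [], []
        for r in records:
            a_ii, a_ij = alpha_values_of_common(r, cutoff)
            ii_parts.append(a_ii)
            ij_parts.append(a_ij)
        aii = np.concatenate(ii_parts) if ii_parts else np.empty(0)
        aij = np.concatenate(ij_parts) if ij_parts else np.empty(0)
    return EnsembleStats(n_replicates=len(records), histogram=hist,
                         mode_n_common=mode, mode_tied=len(tied) > 1,
                         mean_n_common=float(ncs.mean()),
                         mean_fitness_by_n_common=wbar_by_nc,
                         alpha_ii_values=aii, alpha_ij_values=aij)
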