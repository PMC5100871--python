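"""Genotype fitnesses under generalized dominance, and viability selection.

A single diploid locus carries alleles :math:`A_1, \\dots, A_n`.  Each
allele has a *primary effect* :math:`X_i \\in [0, 1]`, each genotype an
*interaction effect* :math:`Y_{ij} \\in [0, 1]`, and the viability of
:math:`A_i A_j` is the weighted sum

.. math:: w_{ij} = \\alpha_{ij} (X_i + X_j) + (1 - 2\\alpha_{ij}) Y_{ij},

with the weighting :math:`\\alpha \\in [0, 1/2]` either one shared scalar
or a per-genotype symmetric matrix.  At :math:`\\alpha = 0` all genotype
fitnesses are independent; at :math:`\\alpha = 1/2` fitness is purely
additive in the primary effects, so a heterozygote's fitness is the mean
of the corresponding homozygote fitnesses.  Because genotypes sharing an
allele share that allele's primary effect, their fitnesses are
positively correlated for any :math:`\\alpha > 0`.

Selection follows the standard one-locus viability recurrence in a
large, randomly mating population:

.. math:: p_i' = \\frac{p_i \\sum_j w_{ij} p_j}{\\bar w},
          \\qquad \\bar w = \\sum_i \\sum_j p_i p_j w_{ij}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitnessModel",
    "PopulationState",
    "build_fitness_matrix",
    "pairwise_fitness_correlation",
    "selection_step",
    "mean_fitness",
    "has_pairwise_het_advantage",
]

SIMPLEX_TOL = 1e-12


def build_fitness_matrix(X, Y, alpha) -> np.ndarray:
    """Build the symmetric genotype fitness matrix W.

    Parameters
    ----------
    X : (n,) array_like
        Primary effects, each in [0, 1].
    Y : (n, n) array_like
        Symmetric interaction effects, each in [0, 1].  The diagonal
        Y_ii is used for homozygotes.
    alpha : float or (n, n) array_like
        Weighting of the primary effects, in [0, 1/2]; a scalar applies
        one weighting to every genotype, a symmetric matrix gives each
        genotype its own.

    Returns
    -------
    (n, n) ndarray
        W with ``w_ij = alpha_ij*(X_i + X_j) + (1 - 2*alpha_ij)*Y_ij``.
        Entries are guaranteed to lie in [0, 1] by the input ranges.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 1:
        raise ValueError("X must be a 1-d vector of primary effects")
    n = X.size
    if Y.shape != (n, n):
        raise ValueError(f"Y must be {n}x{n} to match X, got {Y.shape}")
    if not np.allclose(Y, Y.T, atol=1e-12):
        raise ValueError("interaction matrix Y must be symmetric")
    A = np.asarray(alpha, dtype=float)
    if A.ndim not in (0, 2):
        raise ValueError("alpha must be a scalar or an n x n matrix")
    if A.ndim == 2:
        if A.shape != (n, n):
            raise ValueError(f"alpha matrix must be {n}x{n}, got {A.shape}")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("alpha matrix must be symmetric")
    if np.any(A < 0.0) or np.any(A > 0.5):
        raise ValueError("alpha must lie in [0, 1/2]")
    if np.any(X < 0.0) or np.any(X > 1.0):
        raise ValueError("primary effects X must lie in [0, 1]")
    if np.any(Y < 0.0) or np.any(Y > 1.0):
        raise ValueError("interaction effects Y must lie in [0, 1]")
    W = A * (X[:, None] + X[None, :]) + (1.0 - 2.0 * A) * Y
    return W


def pairwise_fitness_correlation(alpha: float) -> float:
    """Correlation between the fitnesses of two genotypes sharing one allele.

    For genotypes A_iA_j and A_iA_k (j != k) with X and Y drawn i.i.d.
    uniform on [0, 1] and a common scalar weighting,

    ``Cor(w_ij, w_ik) = alpha**2 / (1 - 4*alpha + 6*alpha**2)``.

    The correlation rises from 0 (independent fitnesses at alpha = 0) to
    1/2 in the additive limit alpha = 1/2.
    """
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must lie in [0, 1/2]")
    if alpha == 0.0:
        return 0.0
    return alpha ** 2 / (1.0 - 4.0 * alpha + 6.0 * alpha ** 2)


@dataclass(frozen=True, eq=False)
class FitnessModel:
    """Primary effects, interaction effects and weighting for living alleles.

    ``weighting`` is either a scalar (fixed-alpha mode) or a symmetric
    per-genotype matrix (random-alpha mode).  The fitness matrix is
    derived once at construction and kept index-aligned with the
    effects.
    """

    primary_effects: np.ndarray
    interaction_effects: np.ndarray
    weighting: float | np.ndarray
    fitness_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        X = np.asarray(self.primary_effects, dtype=float)
        Y = np.asarray(self.interaction_effects, dtype=float)
        W = build_fitness_matrix(X, Y, self.weighting)
        object.__setattr__(self, "primary_effects", X)
        object.__setattr__(self, "interaction_effects", Y)
        if np.ndim(self.weighting) == 2:
            object.__setattr__(self, "weighting",
                               np.asarray(self.weighting, dtype=float))
        else:
            object.__setattr__(self, "weighting", float(self.weighting))
        object.__setattr__(self, "fitness_matrix", W)

    @property
    def n_alleles(self) -> int:
        return self.primary_effects.size

    @property
    def random_alpha(self) -> bool:
        return np.ndim(self.weighting) == 2

    def alpha_of(self, i: int, j: int) -> float:
        """Weighting applied to genotype (i, j)."""
        if self.random_alpha:
            return float(self.weighting[i, j])
        return float(self.weighting)

    def restrict(self, indices) -> "FitnessModel":
        """Model restricted to the given allele indices (e.g. survivors)."""
        idx = np.asarray(indices, dtype=int)
        w = self.weighting[np.ix_(idx, idx)] if self.random_alpha else self.weighting
        return FitnessModel(self.primary_effects[idx],
                            self.interaction_effects[np.ix_(idx, idx)], w)

    @classmethod
    def sample(cls, n: int, alpha, rng: np.random.Generator,
               random_alpha: bool = False) -> "FitnessModel":
        """Draw a random model: X, Y ~ U[0,1] (Y symmetric, diagonal included).

        In random-alpha mode each genotype's weighting is an independent
        U[0, 1/2] draw (symmetric), and `alpha` is ignored.
        """
        X = rng.random(n)
        Yfull = rng.random((n, n))
        Y = np.triu(Yfull) + np.triu(Yfull, k=1).T
        if random_alpha:
            Afull = rng.uniform(0.0, 0.5, (n, n))
            A = np.triu(Afull) + np.triu(Afull, k=1).T
            return cls(X, Y, A)
        return cls(X, Y, alpha)

    def to_json(self) -> str:
        """Serialize for reproducibility dumps."""
        payload = {
            "alleles": self.n_alleles,
            "X": self.primary_effects.tolist(),
            "Y": self.interaction_effects.tolist(),
            "alpha": (self.weighting.tolist() if self.random_alpha
                      else self.weighting),
            "mode": "random" if self.random_alpha else "fixed",
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str) -> "FitnessModel":
        d = json.loads(payload)
        alpha = np.asarray(d["alpha"]) if d["mode"] == "random" else d["alpha"]
        return cls(np.asarray(d["X"]), np.asarray(d["Y"]), alpha)


@dataclass(frozen=True, eq=False)
class PopulationState:
    """Allele frequencies plus the fitness model of the living alleles.

    ``allele_ids`` are stable birth-order labels (never reused), so the
    identity of an allele survives extinctions of others.  ``model`` may
    be None when only the frequency dynamics under a bare fitness matrix
    are of interest.
    """

    frequencies: np.ndarray
    model: FitnessModel | None = None
    allele_ids: np.ndarray | None = None
    generation: int = 0
    fitness_matrix_override: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.frequencies, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("frequencies must be a non-empty 1-d vector")
        if np.any(p < 0.0):
            raise ValueError("frequencies must be non-negative")
        if abs(p.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"frequencies must sum to 1 within {SIMPLEX_TOL}, "
                             f"got {p.sum()!r}")
        object.__setattr__(self, "frequencies", p)
        ids = self.allele_ids
        if ids is None:
            ids = np.arange(1, p.size + 1, dtype=np.int64)
        else:
            ids = np.asarray(ids, dtype=np.int64)
            if ids.size != p.size:
                raise ValueError("allele_ids and frequencies must align")
        object.__setattr__(self, "allele_ids", ids)
        if self.generation < 0:
            raise ValueError("generation must be non-negative")
        W = self.fitness_matrix
        if W.shape != (p.size, p.size):
            raise ValueError("fitness matrix must align with frequencies")

    @property
    def fitness_matrix(self) -> np.ndarray:
        if self.fitness_matrix_override is not None:
            return self.fitness_matrix_override
        if self.model is None:
            raise ValueError("state has neither a model nor a fitness matrix")
        return self.model.fitness_matrix

    @property
    def n_alleles(self) -> int:
        return self.frequencies.size

    @classmethod
    def from_matrix(cls, frequencies, W, generation: int = 0,
                    allele_ids=None) -> "PopulationState":
        """State governed by a bare fitness matrix (no X/Y decomposition)."""
        W = np.asarray(W, dtype=float)
        return cls(frequencies=np.asarray(frequencies, dtype=float),
                   model=None, allele_ids=allele_ids, generation=generation,
                   fitness_matrix_override=W)

    def replace_frequencies(self, p, generation=None) -> "PopulationState":
        return PopulationState(
            frequencies=p, model=self.model, allele_ids=self.allele_ids,
            generation=self.generation if generation is None else generation,
            fitness_matrix_override=self.fitness_matrix_override)


def mean_fitness(state: PopulationState) -> float:
    """Population mean fitness ``sum_ij p_i p_j w_ij``."""
    p = state.frequencies
    return float(p @ state.fitness_matrix @ p)


def selection_step(state: PopulationState) -> PopulationState:
    """One deterministic generation of viability selection.

    Applies ``p_i' = p_i (W p)_i / wbar`` and renormalizes defensively;
    raises if the mean fitness is not positive (a degenerate fitness
    set, measure-zero under uniform sampling).
    """
    p = state.frequencies
    W = state.fitness_matrix
    marginal = W @ p
    wbar = float(p @ marginal)
    if wbar <= 0.0:
        raise ValueError("mean fitness is zero; selection undefined")
    p_next = p * marginal / wbar
    p_next /= p_next.sum()
    return state.replace_frequencies(p_next, generation=state.generation + 1)


def has_pairwise_het_advantage(W, i: int, j: int) -> bool:
    """True iff the heterozygote A_iA_j is fitter than both homozygotes.

    At alpha = 1/2 (purely additive fitnesses) this pattern cannot
    arise, since w_ij is then exactly the mean of w_ii and w_jj.
    """
    if i == j:
        raise ValueError("pairwise heterozygote advantage needs i != j")
    W = np.asarray(W, dtype=float)
    return bool(W[i, j] > W[i, i] and W[i, j] > W[j, j])
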