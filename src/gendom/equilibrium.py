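"""Parameter-space analysis: the potential for polymorphism.

For a fixed allele count ``n`` and weighting ``alpha``, fitness sets are
drawn at random (X, Y ~ U[0,1]) and the deterministic selection
recurrence is iterated from a random start on the simplex.  Because any
fully polymorphic equilibrium of the one-locus constant-viability model
is globally stable, the trajectory converges to the n-allele equilibrium
whenever one exists; otherwise some allele is driven out.  The
*potential for polymorphism* is the fraction of fitness sets whose
trajectory converges with all alleles still present.

Two independent routes to the same classification are provided: the
iterative route used by :func:`estimate_potential`, and a linear-algebra
oracle (:func:`internal_equilibrium_oracle`) that solves the
equal-marginal-fitness system directly and checks stability through the
eigenvalue signature of W.  The test suite cross-validates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_model import PopulationState

__all__ = [
    "EquilibriumOutcome",
    "OracleVerdict",
    "PotentialEstimate",
    "broken_stick",
    "iterate_to_equilibrium",
    "internal_equilibrium_oracle",
    "estimate_potential",
    "sample_fitness_matrices",
]

FULL_POLYMORPHISM = "full_polymorphism"
ALLELE_LOST = "allele_lost"
CAP_REACHED = "cap_reached"

_STATUS_NAMES = {
    _kernels.FULL_POLYMORPHISM: FULL_POLYMORPHISM,
    _kernels.ALLELE_LOST: ALLELE_LOST,
    _kernels.CAP_REACHED: CAP_REACHED,
}

#: Default iteration cap.  No equilibrium of interest takes this long to
#: classify; trajectories still active are almost-additive fitness sets
#: whose selection differentials are vanishingly small.
DEFAULT_MAX_GENERATIONS = 10 ** 6


def broken_stick(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random point on the (n-1)-simplex via the broken-stick method.

    Sorts n-1 independent U[0,1] breakpoints and returns the successive
    differences, a vector of n non-negative frequencies summing to 1.
    """
    if n < 1:
        raise ValueError("need at least one allele")
    if n == 1:
        return np.ones(1)
    breaks = np.sort(rng.random(n - 1))
    return np.diff(breaks, prepend=0.0, append=1.0)


@dataclass(frozen=True, eq=False)
class EquilibriumOutcome:
    """Classification of one deterministic trajectory."""

    status: str
    final_state: PopulationState
    generations_used: int

    @property
    def polymorphic(self) -> bool:
        return self.status == FULL_POLYMORPHISM


def iterate_to_equilibrium(p0, W, conv_tol: float = 1e-8,
                           extinct_tol: float = 1e-5,
                           max_generations: int = DEFAULT_MAX_GENERATIONS,
                           ) -> EquilibriumOutcome:
    """Iterate selection until convergence, allele loss, or the cap.

    Terminates with ``full_polymorphism`` the first generation the L1
    frequency change drops below ``conv_tol`` with every allele still at
    or above ``extinct_tol``; with ``allele_lost`` the first generation
    any frequency falls below ``extinct_tol`` (extinction is checked
    before convergence, so a simultaneous hit counts as loss); with
    ``cap_reached`` after ``max_generations``.
    """
    if conv_tol <= 0 or extinct_tol <= 0:
        raise ValueError("tolerances must be positive")
    if max_generations < 1:
        raise ValueError("max_generations must be at least 1")
    p0 = np.asarray(p0, dtype=float)
    W = np.ascontiguousarray(W, dtype=float)
    if W.shape != (p0.size, p0.size):
        raise ValueError("fitness matrix must align with p0")
    status, gens, p_final = _kernels.iterate_batch_kernel(
        W[None, :, :], p0[None, :], conv_tol, extinct_tol, int(max_generations))
    code = int(status[0])
    if code == _kernels.DEGENERATE:
        raise ValueError("mean fitness reached zero; degenerate fitness set")
    state = PopulationState.from_matrix(p_final[0] / p_final[0].sum(), W,
                                        generation=int(gens[0]))
    return EquilibriumOutcome(status=_STATUS_NAMES[code],
                              final_state=state,
                              generations_used=int(gens[0]))


@dataclass(frozen=True, eq=False)
class OracleVerdict:
    """Existence/stability verdict for a fully polymorphic equilibrium."""

    exists: bool
    stable: bool
    p_hat: np.ndarray | None
    singular: bool = False


def internal_equilibrium_oracle(W, eig_tol: float = 1e-10) -> OracleVerdict:
    """Linear-algebra test for a stable interior equilibrium of W.

    An interior equilibrium equalizes the marginal fitnesses of all
    alleles: ``(W p)_i = wbar`` for every i, with p on the simplex.  For
    nonsingular W the candidate is ``p = W^{-1} 1`` normalized; it is an
    admissible equilibrium iff every component is strictly positive.
    The equilibrium is stable (and then globally attracting) iff W has
    exactly one positive eigenvalue, i.e. W is negative definite on the
    tangent space of the simplex.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    ones = np.ones(n)
    if n == 1:
        return OracleVerdict(True, True, np.ones(1))
    # Guard against (near-)singular systems, e.g. exactly additive W.
    if np.linalg.cond(W) > 1e12:
        return OracleVerdict(False, False, None, singular=True)
    z = np.linalg.solve(W, ones)
    total = z.sum()
    if total == 0.0:
        return OracleVerdict(False, False, None, singular=True)
    p_hat = z / total
    exists = bool(np.all(p_hat > 0.0))
    eigs = np.linalg.eigvalsh(W)
    scale = max(1.0, float(np.max(np.abs(eigs))))
    stable = bool(np.sum(eigs > eig_tol * scale) == 1)
    return OracleVerdict(exists, stable, p_hat if exists else None)


@dataclass(frozen=True)
class PotentialEstimate:
    """Monte-Carlo estimate of the potential for polymorphism."""

    n: int
    alpha: float
    n_sets: int
    n_polymorphic: int
    n_allele_lost: int
    n_cap_reached: int

    @property
    def potential(self) -> float:
        return self.n_polymorphic / self.n_sets

    def standard_error(self) -> float:
        q = self.potential
        return float(np.sqrt(q * (1.0 - q) / self.n_sets))


def sample_fitness_matrices(n: int, alpha: float, n_sets: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_sets`` random fitness matrices (X, Y i.i.d. U[0,1])."""
    X = rng.random((n_sets, n))
    Yfull = rng.random((n_sets, n, n))
    upper = np.triu(Yfull)
    Y = upper + np.triu(Yfull, k=1).transpose(0, 2, 1)
    W = alpha * (X[:, :, None] + X[:, None, :]) + (1.0 - 2.0 * alpha) * Y
    return W


def broken_stick_batch(n: int, n_sets: int,
                       rng: np.random.Generator) -> np.ndarray:
    """``n_sets`` independent broken-stick simplex points, as rows."""
    if n == 1:
        return np.ones((n_sets, 1))
    breaks = np.sort(rng.random((n_sets, n - 1)), axis=1)
    padded = np.concatenate([np.zeros((n_sets, 1)), breaks,
                             np.ones((n_sets, 1))], axis=1)
    return np.diff(padded, axis=1)


def estimate_potential(n: int, alpha: float, n_sets: int,
                       rng: np.random.Generator,
                       conv_tol: float = 1e-8, extinct_tol: float = 1e-5,
                       max_generations: int = DEFAULT_MAX_GENERATIONS,
                       ) -> PotentialEstimate:
    """Fraction of random fitness sets maintaining all ``n`` alleles.

    Each set gets one broken-stick start (global stability of interior
    equilibria makes more starts redundant); a trajectory counts toward
    the potential only when it converges with all alleles present.
    Cap-limited trajectories count as not polymorphic.
    """
    if n < 1:
        raise ValueError("need at least one allele")
    if n_sets < 1:
        raise ValueError("need at least one fitness set")
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must lie in [0, 1/2]")
    W = sample_fitness_matrices(n, alpha, n_sets, rng)
    p0 = broken_stick_batch(n, n_sets, rng)
    status, _, _ = _kernels.iterate_batch_kernel(
        np.ascontiguousarray(W), np.ascontiguousarray(p0),
        conv_tol, extinct_tol, int(max_generations))
    n_poly = int(np.sum(status == _kernels.FULL_POLYMORPHISM))
    n_lost = int(np.sum(status == _kernels.ALLELE_LOST))
    n_cap = int(np.sum(status == _kernels.CAP_REACHED))
    return PotentialEstimate(n=n, alpha=alpha, n_sets=n_sets,
                             n_polymorphic=n_poly, n_allele_lost=n_lost,
                             n_cap_reached=n_cap)
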