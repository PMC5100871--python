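"""Constructionist simulations: building polymorphism by recurrent mutation.

Each replicate starts from a monomorphic population (allele A_1 fixed,
homozygote fitness 1/2) and runs for a fixed number of generations.
Every generation a novel mutant allele appears at a small frequency,
taken from one resident allele chosen in proportion to its frequency;
the mutant's primary effect and its interaction effects with every
resident are fresh U[0,1] draws, and its weightings are either the
shared fixed alpha or fresh U[0, 1/2] draws per genotype (random-alpha
mode).  Deterministic viability selection follows, then multinomial
Wright-Fisher drift if the population size N is finite, and finally any
allele whose frequency fell below the extinction threshold is removed.
With finite N both the mutant's initial frequency and the extinction
threshold equal 1/(2N), the frequency of a single gene copy.

Two interchangeable backends run a replicate: a compiled kernel (the
default) and a pure-NumPy reference composed from the public operations
below.  Both consume the identical random stream, so their trajectories
coincide; the test suite asserts this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from joblib import Parallel, delayed

from . import _kernels
from .core_model import FitnessModel, PopulationState, selection_step, mean_fitness

__all__ = [
    "ExperimentConfig",
    "ReplicateRecord",
    "initialize_population",
    "introduce_mutation",
    "drift_step",
    "prune_extinct",
    "run_replicate",
    "run_batch",
]

#: Defaults for the infinite-population experiments.
DEFAULT_GENERATIONS = 10_000
DEFAULT_REPLICATES = 2_000
DEFAULT_MUTATION_FREQUENCY = 1e-4
DEFAULT_EXTINCTION_THRESHOLD = 1e-4
DEFAULT_COMMON_CUTOFF = 0.01


@dataclass(frozen=True)
class ExperimentConfig:
    """All switches, thresholds and counts for one constructionist run.

    ``alpha_mode`` is ``"fixed"`` (requires ``alpha`` in [0, 1/2]) or
    ``"random"`` (each new genotype draws its own weighting from
    U[0, 1/2]; ``alpha`` must then be None).  ``population_size`` of
    None means no drift (infinite N); a finite N forces the mutation
    frequency and extinction threshold to 1/(2N) and it is an error to
    request conflicting explicit values.
    """

    alpha: float | None = None
    alpha_mode: str = "fixed"
    generations: int = DEFAULT_GENERATIONS
    replicates: int = DEFAULT_REPLICATES
    mutation_frequency: float | None = None
    extinction_threshold: float | None = None
    population_size: int | None = None
    common_cutoff: float = DEFAULT_COMMON_CUTOFF
    seed: int = 0

    def __post_init__(self):
        if self.alpha_mode not in ("fixed", "random"):
            raise ValueError("alpha_mode must be 'fixed' or 'random'")
        if self.alpha_mode == "fixed":
            if self.alpha is None:
                raise ValueError("fixed alpha_mode requires an alpha value")
            if not 0.0 <= self.alpha <= 0.5:
                raise ValueError("alpha must lie in [0, 1/2]")
        elif self.alpha is not None:
            raise ValueError("random alpha_mode draws alpha per genotype; "
                             "do not also pass a fixed alpha")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        N = self.population_size
        if N is not None and N <= 0:
            raise ValueError("population size must be positive (or None)")
        per_copy = None if N is None else 1.0 / (2.0 * N)
        mu = self.mutation_frequency
        ext = self.extinction_threshold
        if N is not None:
            for name, value in (("mutation_frequency", mu),
                                ("extinction_threshold", ext)):
                if value is not None and value != per_copy:
                    raise ValueError(
                        f"finite N={N} fixes {name} to 1/(2N)={per_copy!r}, "
                        f"but {value!r} was requested")
            mu = ext = per_copy
        else:
            mu = DEFAULT_MUTATION_FREQUENCY if mu is None else mu
            ext = DEFAULT_EXTINCTION_THRESHOLD if ext is None else ext
        object.__setattr__(self, "mutation_frequency", float(mu))
        object.__setattr__(self, "extinction_threshold", float(ext))
        if not 0.0 < self.mutation_frequency < self.common_cutoff < 1.0:
            raise ValueError("need 0 < mutation_frequency < common_cutoff < 1")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction_threshold must be positive")

    @property
    def random_alpha(self) -> bool:
        return self.alpha_mode == "random"

    def replicate_seed(self, replicate_index: int) -> int:
        """Deterministic, collision-free 32-bit seed for one replicate."""
        ss = np.random.SeedSequence(entropy=int(self.seed),
                                    spawn_key=(int(replicate_index),))
        return int(ss.generate_state(1, dtype=np.uint32)[0])

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, payload: str) -> "ExperimentConfig":
        return cls.from_dict(json.loads(payload))


@dataclass(frozen=True, eq=False)
class ReplicateRecord:
    """Per-generation summaries and the terminal state of one replicate.

    The three series have length ``generations + 1``; index 0 is the
    initial monomorphic state.
    """

    replicate_index: int
    seed: int
    config: ExperimentConfig
    n_alleles_series: np.ndarray
    n_common_series: np.ndarray
    mean_fitness_series: np.ndarray
    final_state: PopulationState
    donor_clamps: int = 0

    def __post_init__(self):
        expected = self.config.generations + 1
        for series in (self.n_alleles_series, self.n_common_series,
                       self.mean_fitness_series):
            if len(series) != expected:
                raise ValueError("series length must equal generations + 1")

    @property
    def terminal_n_common(self) -> int:
        return int(self.n_common_series[-1])

    @property
    def terminal_mean_fitness(self) -> float:
        return float(self.mean_fitness_series[-1])


def _founder_model(config: ExperimentConfig,
                   rng: np.random.RandomState) -> FitnessModel:
    # X_1 = Y_11 = 1/2 gives w_11 = alpha + (1 - 2 alpha)/2 = 1/2 for every
    # weighting, so the founder homozygote fitness is 1/2 in every mode.
    if config.random_alpha:
        a0 = rng.uniform(0.0, 0.5)
        return FitnessModel(np.array([0.5]), np.array([[0.5]]),
                            np.array([[a0]]))
    return FitnessModel(np.array([0.5]), np.array([[0.5]]), config.alpha)


def initialize_population(config: ExperimentConfig,
                          rng: np.random.RandomState | None = None,
                          ) -> PopulationState:
    """Monomorphic start: allele A_1 at frequency 1 with w_11 = 1/2."""
    if rng is None:
        rng = np.random.RandomState(config.replicate_seed(0))
    model = _founder_model(config, rng)
    return PopulationState(frequencies=np.ones(1), model=model,
                           allele_ids=np.array([1], dtype=np.int64),
                           generation=0)


def introduce_mutation(state: PopulationState, config: ExperimentConfig,
                       rng: np.random.RandomState,
                       ) -> tuple[PopulationState, bool]:
    """Append one novel allele at the mutation frequency.

    The mutant's frequency is taken from a resident allele chosen with
    probability proportional to its frequency.  Should the donor carry
    less than the mutation frequency (possible only transiently), the
    transfer is clamped to the donor's entire frequency so the simplex
    sum is preserved exactly; the returned flag reports the clamp.

    Draw order: mutant X ~ U[0,1]; interaction column Y (n+1 values,
    U[0,1]); in random-alpha mode the weighting column (n+1 values,
    U[0,1/2]); one uniform for the donor choice.
    """
    model = state.model
    if model is None:
        raise ValueError("introduce_mutation needs a state with a full model")
    n = state.n_alleles
    p = state.frequencies
    x_new = rng.uniform(0.0, 1.0)
    y_col = rng.uniform(0.0, 1.0, n + 1)
    X = np.append(model.primary_effects, x_new)
    Y = np.zeros((n + 1, n + 1))
    Y[:n, :n] = model.interaction_effects
    Y[:, n] = y_col
    Y[n, :] = y_col
    if config.random_alpha:
        a_col = rng.uniform(0.0, 0.5, n + 1)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = model.weighting
        A[:, n] = a_col
        A[n, :] = a_col
        weighting = A
    else:
        weighting = model.weighting
    new_model = FitnessModel(X, Y, weighting)

    u = rng.uniform(0.0, 1.0)
    donor = int(np.searchsorted(np.cumsum(p), u * p.sum(), side="right"))
    donor = min(donor, n - 1)
    transfer = config.mutation_frequency
    clamped = False
    if p[donor] < transfer:
        transfer = float(p[donor])
        clamped = True
    p_new = np.append(p, transfer)
    p_new[donor] -= transfer
    # Birth-order labels, never reused: the founder is A_1 and the mutant
    # arising in generation g is A_{g+2}, regardless of earlier extinctions.
    ids = np.append(state.allele_ids, state.generation + 2)
    return (PopulationState(frequencies=p_new, model=new_model,
                            allele_ids=ids, generation=state.generation),
            clamped)


def drift_step(state: PopulationState, N: int,
               rng: np.random.RandomState) -> PopulationState:
    """Wright-Fisher drift: multinomial sampling of 2N gene copies.

    Post-selection frequencies are the multinomial probabilities; the
    new frequencies are the sampled counts divided by 2N, so they sum to
    1 exactly.
    """
    if N is None or N <= 0:
        raise ValueError("drift needs a positive finite population size")
    p = state.frequencies
    counts = rng.multinomial(2 * N, p / p.sum())
    return state.replace_frequencies(counts / (2.0 * N))


def prune_extinct(state: PopulationState, threshold: float) -> PopulationState:
    """Remove alleles below the extinction threshold and renormalize.

    Removal is strict (a frequency exactly at the threshold survives).
    The fitness model rows/columns of removed alleles are dropped so the
    state stays index-aligned.
    """
    p = state.frequencies
    keep = np.flatnonzero(p >= threshold)
    if keep.size == 0:
        raise ValueError("all alleles fell below the extinction threshold")
    if keep.size == p.size:
        return state
    p_kept = p[keep]
    model = state.model.restrict(keep) if state.model is not None else None
    override = None
    if state.fitness_matrix_override is not None:
        override = state.fitness_matrix_override[np.ix_(keep, keep)]
    return PopulationState(frequencies=p_kept / p_kept.sum(), model=model,
                           allele_ids=state.allele_ids[keep],
                           generation=state.generation,
                           fitness_matrix_override=override)


def _run_replicate_reference(config: ExperimentConfig, seed: int,
                             ) -> tuple[PopulationState, np.ndarray,
                                        np.ndarray, np.ndarray, int]:
    """Readable replicate loop composed from the public operations.

    Consumes the same random stream as the compiled kernel; used for
    cross-validation and small runs.
    """
    rng = np.random.RandomState(seed)
    state = initialize_population(config, rng)
    gens = config.generations
    ser_n = np.zeros(gens + 1, dtype=np.int64)
    ser_nc = np.zeros(gens + 1, dtype=np.int64)
    ser_w = np.zeros(gens + 1)
    ser_n[0] = 1
    ser_nc[0] = 1
    ser_w[0] = mean_fitness(state)
    clamps = 0
    for g in range(gens):
        state, clamped = introduce_mutation(state, config, rng)
        clamps += int(clamped)
        state = selection_step(state)
        if config.population_size is not None:
            state = drift_step(state, config.population_size, rng)
        state = prune_extinct(state, config.extinction_threshold)
        ser_n[g + 1] = state.n_alleles
        ser_nc[g + 1] = int(np.sum(state.frequencies > config.common_cutoff))
        ser_w[g + 1] = mean_fitness(state)
    return state, ser_n, ser_nc, ser_w, clamps


def run_replicate(config: ExperimentConfig, replicate_index: int,
                  backend: str = "compiled") -> ReplicateRecord:
    """Run one fully reproducible replicate.

    The replicate's random stream is derived deterministically from
    ``(config.seed, replicate_index)``; running the same pair twice
    yields an identical record.  ``backend`` selects the compiled kernel
    (default) or the pure-NumPy reference path.
    """
    seed = config.replicate_seed(replicate_index)
    if backend == "reference":
        state, ser_n, ser_nc, ser_w, clamps = _run_replicate_reference(
            config, seed)
        final = state
    elif backend == "compiled":
        two_n = 0 if config.population_size is None else 2 * config.population_size
        (n, ids, X, Y, A, W, p, ser_n, ser_nc, ser_w,
         clamps) = _kernels.constructionist_kernel(
            seed, config.generations,
            -1.0 if config.random_alpha else float(config.alpha),
            config.random_alpha, config.mutation_frequency,
            config.extinction_threshold, two_n, config.common_cutoff)
        weighting = A if config.random_alpha else float(config.alpha)
        model = FitnessModel(X, Y, weighting)
        final = PopulationState(frequencies=p / p.sum(), model=model,
                                allele_ids=ids,
                                generation=config.generations)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ReplicateRecord(replicate_index=replicate_index, seed=seed,
                           config=config, n_alleles_series=ser_n,
                           n_common_series=ser_nc, mean_fitness_series=ser_w,
                           final_state=final, donor_clamps=clamps)


def run_batch(config: ExperimentConfig, n_jobs: int = 1,
              backend: str = "compiled") -> list[ReplicateRecord]:
    """Run all replicates of a configuration.

    Replicates use independent, index-derived streams, so results do not
    depend on execution order or on ``n_jobs``.
    """
    if n_jobs == 1:
        return [run_replicate(config, r, backend=backend)
                for r in range(config.replicates)]
    return Parallel(n_jobs=n_jobs)(
        delayed(run_replicate)(config, r, backend)
        for r in range(config.replicates))
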