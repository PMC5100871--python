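"""Tests for the constructionist engine: configuration, operations, replicates."""

import numpy as np
import pytest

from gendom import (ExperimentConfig, PopulationState, drift_step,
                    initialize_population, introduce_mutation, mean_fitness,
                    prune_extinct, run_batch, run_replicate)


class TestExperimentConfig:
    def test_defaults_match_standard_conditions(self):
        cfg = ExperimentConfig(alpha=0.0)
        assert cfg.generations == 10_000
        assert cfg.replicates == 2000
        assert cfg.mutation_frequency == 1e-4
        assert cfg.extinction_threshold == 1e-4
        assert cfg.common_cutoff == 0.01
        assert cfg.population_size is None

    def test_finite_population_rescales_thresholds(self):
        cfg = ExperimentConfig(alpha=0.5, population_size=10_000)
        assert cfg.mutation_frequency == 5e-5
        assert cfg.extinction_threshold == 5e-5

    def test_conflicting_thresholds_rejected(self):
        with pytest.raises(ValueError, match="1/\\(2N\\)"):
            ExperimentConfig(alpha=0.5, population_size=10_000,
                             mutation_frequency=1e-4)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(alpha=0.6)

    def test_random_mode_excludes_fixed_alpha(self):
        with pytest.raises(ValueError):
            ExperimentConfig(alpha=0.3, alpha_mode="random")

    def test_json_round_trip(self):
        for cfg in (ExperimentConfig(alpha=1 / 3, seed=9),
                    ExperimentConfig(alpha_mode="random",
                                     population_size=5000, seed=2)):
            assert ExperimentConfig.from_json(cfg.to_json()) == cfg

    def test_replicate_seeds_are_deterministic_and_distinct(self):
        cfg = ExperimentConfig(alpha=0.0, seed=42)
        seeds = [cfg.replicate_seed(r) for r in range(100)]
        assert seeds == [cfg.replicate_seed(r) for r in range(100)]
        assert len(set(seeds)) == 100


class TestInitializePopulation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1 / 3}, {"alpha": 0.5},
        {"alpha_mode": "random"},
    ])
    def test_founder_homozygote_fitness_is_half(self, kwargs):
        cfg = ExperimentConfig(**kwargs)
        state = initialize_population(cfg, np.random.RandomState(1))
        assert state.n_alleles == 1
        assert state.frequencies[0] == 1.0
        assert mean_fitness(state) == pytest.approx(0.5)


class TestIntroduceMutation:
    def test_monomorphic_split(self):
        cfg = ExperimentConfig(alpha=0.2)
        state = initialize_population(cfg, np.random.RandomState(0))
        nxt, clamped = introduce_mutation(state, cfg, np.random.RandomState(0))
        np.testing.assert_allclose(nxt.frequencies, [0.9999, 1e-4])
        assert not clamped
        assert nxt.n_alleles == 2
        W = nxt.fitness_matrix
        assert W.shape == (2, 2) and np.all((W >= 0) & (W <= 1))

    def test_frequency_mass_is_conserved_exactly(self):
        cfg = ExperimentConfig(alpha_mode="random")
        rng = np.random.RandomState(5)
        state = initialize_population(cfg, rng)
        for _ in range(50):
            state, _ = introduce_mutation(state, cfg, rng)
            assert abs(state.frequencies.sum() - 1.0) <= 1e-12

    def test_donor_chosen_in_proportion_to_frequency(self):
        cfg = ExperimentConfig(alpha=0.1)
        rng = np.random.RandomState(17)
        base = initialize_population(cfg, rng)
        for _ in range(2):
            base, _ = introduce_mutation(base, cfg, rng)
        p = np.array([0.5, 0.3, 0.2])
        base = PopulationState(frequencies=p, model=base.model,
                               allele_ids=base.allele_ids)
        trials = 20_000
        hits = 0
        for _ in range(trials):
            nxt, _ = introduce_mutation(base, cfg, rng)
            hits += nxt.frequencies[0] < p[0]
        se = np.sqrt(0.5 * 0.5 / trials)
        assert abs(hits / trials - 0.5) < 3.5 * se


class TestDriftStep:
    def test_fixed_allele_cannot_drift(self):
        state = PopulationState.from_matrix([1.0], [[0.5]])
        out = drift_step(state, 50, np.random.RandomState(0))
        np.testing.assert_array_equal(out.frequencies, [1.0])

    def test_requires_positive_population(self):
        state = PopulationState.from_matrix([1.0], [[0.5]])
        with pytest.raises(ValueError):
            drift_step(state, 0, np.random.RandomState(0))

    def test_multinomial_mean_and_variance(self):
        N = 100
        p = np.array([0.3, 0.7])
        state = PopulationState.from_matrix(p, np.full((2, 2), 0.5))
        rng = np.random.RandomState(8)
        trials = 30_000
        draws = np.array([drift_step(state, N, rng).frequencies[0]
                          for _ in range(trials)])
        se_mean = np.sqrt(p[0] * p[1] / (2 * N) / trials)
        assert abs(draws.mean() - p[0]) < 3 * se_mean
        expected_var = p[0] * p[1] / (2 * N)
        rel = 3 * np.sqrt(2.0 / (trials - 1))
        assert abs(draws.var(ddof=1) / expected_var - 1.0) < rel

    def test_frequencies_sum_to_one_exactly(self):
        p = np.array([0.25, 0.25, 0.5])
        state = PopulationState.from_matrix(p, np.full((3, 3), 0.5))
        out = drift_step(state, 1000, np.random.RandomState(3))
        assert out.frequencies.sum() == 1.0


class TestPruneExtinct:
    def test_removal_and_renormalization(self):
        state = PopulationState.from_matrix([0.99995, 0.00005],
                                            np.full((2, 2), 0.5))
        out = prune_extinct(state, 1e-4)
        np.testing.assert_array_equal(out.frequencies, [1.0])
        assert out.fitness_matrix.shape == (1, 1)

    def test_noop_when_all_above_threshold(self):
        state = PopulationState.from_matrix([0.6, 0.4], np.full((2, 2), 0.5))
        assert prune_extinct(state, 1e-4) is state

    def test_renormalization_arithmetic(self):
        state = PopulationState.from_matrix([0.6, 0.39992, 0.00008],
                                            np.full((3, 3), 0.5))
        out = prune_extinct(state, 1e-4)
        np.testing.assert_allclose(out.frequencies,
                                   [0.6 / 0.99992, 0.39992 / 0.99992])

    def test_boundary_is_strict(self):
        state = PopulationState.from_matrix([0.9999, 1e-4],
                                            np.full((2, 2), 0.5))
        assert prune_extinct(state, 1e-4).n_alleles == 2

    def test_cannot_empty_population(self):
        state = PopulationState.from_matrix([0.5, 0.5], np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            prune_extinct(state, 0.9)


class TestRunReplicate:
    def test_zero_generations_returns_initial_state(self):
        cfg = ExperimentConfig(alpha=0.3, generations=0)
        rec = run_replicate(cfg, 0)
        assert len(rec.n_common_series) == 1
        assert rec.terminal_n_common == 1
        assert rec.terminal_mean_fitness == pytest.approx(0.5)

    def test_determinism(self):
        cfg = ExperimentConfig(alpha_mode="random", generations=400, seed=77)
        a = run_replicate(cfg, 3)
        b = run_replicate(cfg, 3)
        np.testing.assert_array_equal(a.mean_fitness_series,
                                      b.mean_fitness_series)
        np.testing.assert_array_equal(a.final_state.frequencies,
                                      b.final_state.frequencies)
        np.testing.assert_array_equal(a.final_state.allele_ids,
                                      b.final_state.allele_ids)

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1 / 3}, {"alpha_mode": "random"},
        {"alpha": 0.5, "population_size": 10_000},
    ])
    def test_compiled_and_reference_backends_agree(self, kwargs):
        cfg = ExperimentConfig(generations=300, seed=7, **kwargs)
        fast = run_replicate(cfg, 0, backend="compiled")
        ref = run_replicate(cfg, 0, backend="reference")
        np.testing.assert_array_equal(fast.n_alleles_series,
                                      ref.n_alleles_series)
        np.testing.assert_array_equal(fast.n_common_series,
                                      ref.n_common_series)
        np.testing.assert_array_equal(fast.final_state.allele_ids,
                                      ref.final_state.allele_ids)
        np.testing.assert_allclose(fast.mean_fitness_series,
                                   ref.mean_fitness_series, rtol=1e-9)
        np.testing.assert_allclose(fast.final_state.frequencies,
                                   ref.final_state.frequencies, rtol=1e-8)
        assert fast.donor_clamps == ref.donor_clamps

    def test_simplex_invariant_along_trajectory(self):
        cfg = ExperimentConfig(alpha=0.25, generations=500, seed=19)
        rec = run_replicate(cfg, 1)
        assert abs(rec.final_state.frequencies.sum() - 1.0) <= 1e-12

    def test_unknown_backend_rejected(self):
        cfg = ExperimentConfig(alpha=0.1, generations=1)
        with pytest.raises(ValueError):
            run_replicate(cfg, 0, backend="fortran")


class TestRunBatch:
    def test_batch_matches_individual_replicates(self):
        cfg = ExperimentConfig(alpha=0.4, generations=200, replicates=4,
                               seed=5)
        batch = run_batch(cfg)
        assert len(batch) == 4
        solo = run_replicate(cfg, 2)
        np.testing.assert_array_equal(batch[2].mean_fitness_series,
                                      solo.mean_fitness_series)
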