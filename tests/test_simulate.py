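import numpy as np
import pytest

from clonaltraj.diversity import diversity_timeseries
from clonaltraj.core import to_frequencies
from clonaltraj.simulate import (
    SimulationConfig,
    evaluate_recovery,
    fixation_probability,
    make_benchmark_scenario,
    make_fitness_class_config,
    simulate,
)


def tiny_config(**kw):
    defaults = dict(
        population_size=500,
        n_barcodes=20,
        n_generations=30,
        sampling_times=(0, 10, 20, 30),
        reads_per_sample=5000,
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestEngineInvariants:
    def test_population_size_conserved(self):
        res = simulate(tiny_config())
        totals = res.truth.true_frequency.sum(axis=0)
        assert np.allclose(totals, 1.0, atol=1e-12)

    def test_reads_sum_to_depth(self):
        res = simulate(tiny_config())
        assert np.all(res.observed.totals == 5000)

    def test_fixed_seed_bit_identical(self):
        a = simulate(tiny_config(mutation_rate=1e-4, dfe=("exponential", 0.05)))
        b = simulate(tiny_config(mutation_rate=1e-4, dfe=("exponential", 0.05)))
        assert np.array_equal(a.observed.counts, b.observed.counts)
        assert np.array_equal(a.truth.true_frequency, b.truth.true_frequency)
        assert a.truth.mutations.equals(b.truth.mutations)

    def test_different_seeds_differ(self):
        a = simulate(tiny_config(seed=1))
        b = simulate(tiny_config(seed=2))
        assert not np.array_equal(a.observed.counts, b.observed.counts)

    def test_fates_partition(self):
        res = simulate(tiny_config(n_generations=200,
                                   sampling_times=(0, 100, 200)))
        final = res.truth.true_frequency[:, -1]
        assert np.all((res.truth.fate == "extinct") == (final == 0))
        assert set(res.truth.fate) <= {"extinct", "fixed", "segregating"}

    def test_neutral_heterozygosity_decay(self):
        # E[1 - sum f^2] declines by (1 - 1/N) per generation under drift
        N, gens, reps = 200, 15, 300
        ratios = []
        for seed in range(reps):
            cfg = SimulationConfig(N, 10, gens, sampling_times=(0, gens),
                                   reads_per_sample=1000, seed=seed)
            tr = simulate(cfg).truth
            h0 = 1 - np.sum(tr.true_frequency[:, 0] ** 2)
            ht = 1 - np.sum(tr.true_frequency[:, 1] ** 2)
            ratios.append(ht / h0)
        expected = (1 - 1 / N) ** gens
        se = np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ratios) - expected) < 3 * se + 1e-12


class TestMutation:
    def test_poisson_supply_recorded(self):
        res = simulate(tiny_config(population_size=2000, mutation_rate=1e-3,
                                   dfe=("fixed", 0.05)))
        muts = res.truth.mutations
        assert len(muts) > 0
        assert np.all(muts["s"] == 0.05)
        assert muts["generation"].between(1, 30).all()

    def test_scheduled_mutation_applied(self):
        cfg = tiny_config(scheduled_mutations=((0, 5, 0.5, 0.5),))
        res = simulate(cfg)
        muts = res.truth.mutations
        assert list(muts["ID"]) == ["BC000000"]
        assert list(muts["generation"]) == [5]
        # strongly beneficial sub-lineage drags the barcode's mean fitness up
        assert np.nanmax(res.truth.mean_fitness[0]) > 1.05

    def test_founder_fitness_recorded_as_generation_zero(self):
        cfg = tiny_config(founder_fitness=tuple([0.1] + [0.0] * 19))
        muts = simulate(cfg).truth.mutations
        assert list(muts["generation"]) == [0]
        assert list(muts["ID"]) == ["BC000000"]


class TestScenarios:
    def test_neutral_truth_has_no_mutations(self):
        cfg = make_benchmark_scenario("neutral", scale=0.001, seed=3)
        res = simulate(cfg)
        assert res.truth.mutations.empty
        assert np.all(res.truth.founder_fitness == 0)

    def test_full_scale_config_matches_study_design(self):
        cfg = make_benchmark_scenario("fixation", scale=1.0)
        assert cfg.population_size == 10_000_000
        assert cfg.n_generations == 1125
        assert len(cfg.sampling_times) == 17

    def test_fixation_scenario_one_fixer_majority_extinct(self):
        fixed = 0
        for seed in range(5):
            cfg = make_benchmark_scenario("fixation", scale=0.01, seed=seed)
            res = simulate(cfg)
            fixed += int(np.sum(res.truth.fate == "fixed") == 1)
        assert fixed >= 4

    def test_fixation_diversity_collapse(self):
        cfg = make_benchmark_scenario("fixation", scale=0.01, seed=0)
        res = simulate(cfg)
        prof = diversity_timeseries(to_frequencies(res.observed),
                                    orders=(np.inf,))
        assert prof.values[0, -1] < prof.values[0, 0]
        assert prof.values[0, -1] < 2.5  # dominated by the sweep

    def test_clonal_interference_many_beneficial_lineages(self):
        cfg = make_benchmark_scenario("clonal_interference", scale=0.002, seed=1)
        res = simulate(cfg)
        assert len(res.truth.mutations) > 10

    def test_fitness_class_config_shapes(self):
        cfg = make_fitness_class_config(seed=5)
        assert cfg.n_barcodes == 36
        assert sum(cfg.founder_counts) == cfg.population_size
        assert len(set(cfg.barcode_classes)) == 3


class TestRecoveryScoring:
    def _clusters_from_truth(self, res, scramble=None):
        from clonaltraj.clustering import ClonalClusterSet
        import pandas as pd

        labels = res.truth.class_labels()
        rng = np.random.default_rng(0)
        names = {}
        assignment = {}
        for b, lab in zip(res.truth.barcode_ids, labels):
            if scramble is not None:
                lab = scramble.integers(0, 3)
            names.setdefault(lab, f"C{len(names) + 1}")
            assignment[b] = names[lab]
        ranked = sorted(set(assignment.values()))
        return ClonalClusterSet(
            assignment=assignment,
            consensus=pd.DataFrame(columns=["cluster", "Time", "frequency"]),
            rank=ranked,
            final_frequency={c: 0.0 for c in ranked},
            minor={c: False for c in ranked},
            cut_height=0.0,
            timepoints=res.observed.timepoints,
        )

    def test_perfect_assignment_gives_ari_one(self):
        res = simulate(make_fitness_class_config(seed=2))
        cs = self._clusters_from_truth(res)
        assert evaluate_recovery(res, cs).ari == pytest.approx(1.0)

    def test_random_assignment_near_zero(self):
        res = simulate(make_fitness_class_config(seed=2))
        rng = np.random.default_rng(123)
        aris = [
            evaluate_recovery(res, self._clusters_from_truth(res, scramble=rng)).ari
            for _ in range(50)
        ]
        assert abs(np.mean(aris)) < 0.05

    def test_unknown_barcode_rejected(self):
        res = simulate(make_fitness_class_config(seed=2))
        cs = self._clusters_from_truth(res)
        cs.assignment["GHOST"] = "C1"
        with pytest.raises(ValueError, match="absent"):
            evaluate_recovery(res, cs)


class TestFixationProbabilityHelper:
    def test_neutral_fixation_probability_is_one_over_n(self):
        # p_fix of a neutral mutant equals its initial frequency
        p = fixation_probability(100, 0.0, n0=10, n_replicates=4000, seed=1)
        se = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(p - 0.1) < 4 * se

    def test_consistent_with_full_engine_one_step(self):
        # marginal law of the two-type reduction matches the lineage engine
        N, n0, s = 1000, 100, 0.05
        engine = []
        for seed in range(400):
            cfg = SimulationConfig(
                N, 2, 1, sampling_times=(1,), reads_per_sample=10,
                seed=seed, founder_fitness=(s, 0.0),
                founder_counts=(n0, N - n0),
            )
            engine.append(simulate(cfg).truth.true_frequency[0, 0] * N)
        p = n0 * (1 + s) / (N + n0 * s)
        expect, var = N * p, N * p * (1 - p)
        z = (np.mean(engine) - expect) / np.sqrt(var / len(engine))
        assert abs(z) < 4
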