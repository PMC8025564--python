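"""The per-generation cycle: forced paths, binomial oracles, and ledger
conservation."""

import numpy as np
import pytest

from tepop.parameters import InsertionEffectDistribution, make_effect_distribution
from tepop.sim_core import (
    LocusClass,
    Population,
    excise,
    init_population,
    mutate_hosts,
    reproduce,
    step_generation,
    te_death,
    transpose,
)

from conftest import small_params

NEUTRAL_ONLY = InsertionEffectDistribution(0.0, 0.0, 1.0, 0.0)


def make_pop(params, seed=11):
    return init_population(params, np.random.default_rng(seed))


class TestInitPopulation:
    def test_no_initial_tes(self):
        pop = make_pop(small_params(initial_te_per_host=0))
        assert pop.total_active_te() == 0

    def test_total_te_is_capacity_times_per_host(self):
        pop = make_pop(small_params(carrying_capacity=500, initial_te_per_host=5))
        assert pop.total_active_te() == 2500

    def test_noncoding_fraction_before_te_insertion(self):
        pop = make_pop(
            small_params(
                non_coding_fraction=0.7, genome_length=1000, initial_te_per_host=0
            )
        )
        for host in pop.hosts:
            assert host.genome.n_noncoding == 700
            assert host.genome.n_coding == 300

    def test_all_fitness_one_and_genome_grows_by_initial_tes(self):
        params = small_params(genome_length=100, initial_te_per_host=2)
        pop = make_pop(params)
        assert all(h.fitness == 1.0 for h in pop.hosts)
        assert all(len(h.genome) == 102 for h in pop.hosts)

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError, match="non-coding"):
            make_pop(small_params(non_coding_fraction=0.0, initial_te_per_host=1))


class TestTranspose:
    def test_zero_rate_changes_nothing(self):
        pop = make_pop(small_params(transposition_rate=0.0))
        before = [h.genome.loci.copy() for h in pop.hosts]
        log = transpose(pop)
        assert log["insertions"] == 0
        for host, loci in zip(pop.hosts, before):
            assert np.array_equal(host.genome.loci, loci)

    def test_forced_firing_adds_exactly_progeny_copies(self):
        params = small_params(
            carrying_capacity=1,
            initial_te_per_host=1,
            transposition_rate=1.0,
            progeny=2,
            effect_distribution=NEUTRAL_ONLY,
        )
        pop = make_pop(params)
        log = transpose(pop)
        assert log["insertions"] == 2
        assert pop.hosts[0].genome.n_active_te == 3  # original retained
        assert pop.hosts[0].fitness == 1.0

    def test_insertion_bias_hits_noncoding_at_the_set_rate(self):
        # ~1000 firings at bias 0.9; binomial 3-sigma band is about +/-0.03
        params = small_params(
            carrying_capacity=10,
            initial_te_per_host=100,
            genome_length=1000,
            transposition_rate=1.0,
            insertion_bias=0.9,
            effect_distribution=NEUTRAL_ONLY,
        )
        pop = make_pop(params)
        log = transpose(pop)
        frac = log["noncoding_insertions"] / log["insertions"]
        assert frac == pytest.approx(0.9, abs=0.03)

    def test_lethal_insertion_zeroes_fitness(self):
        params = small_params(
            carrying_capacity=5,
            initial_te_per_host=1,
            transposition_rate=1.0,
            effect_distribution=InsertionEffectDistribution(1.0, 0.0, 0.0, 0.0),
        )
        pop = make_pop(params)
        transpose(pop)
        assert all(h.fitness == 0.0 for h in pop.hosts)

    def test_no_fitness_increase_possible_without_beneficial_class(self):
        params = small_params(
            carrying_capacity=30,
            initial_te_per_host=5,
            transposition_rate=0.5,
            effect_distribution=make_effect_distribution(0.0),
        )
        pop = make_pop(params)
        for _ in range(5):
            before = {h.id: h.fitness for h in pop.hosts}
            transpose(pop)
            assert all(h.fitness <= before[h.id] for h in pop.hosts)


class TestExciseAndDeath:
    def test_excision_extremes(self):
        pop = make_pop(small_params(excision_rate=0.0))
        assert excise(pop)["excisions"] == 0
        params = small_params(excision_rate=1.0)
        pop = make_pop(params)
        excise(pop)
        assert pop.total_active_te() == 0
        # excised loci are deleted outright, not converted
        assert all(h.genome.n_dead_te == 0 for h in pop.hosts)

    def test_excision_count_matches_binomial_oracle(self):
        # 10^4 TEs at rate 0.01 -> 100 +/- 30 (3 sigma)
        params = small_params(
            carrying_capacity=100, initial_te_per_host=100, excision_rate=0.01
        )
        pop = make_pop(params)
        log = excise(pop)
        assert 70 <= log["excisions"] <= 130

    def test_death_converts_all_at_rate_one(self):
        params = small_params(death_rate=1.0)
        pop = make_pop(params)
        te_death(pop)
        assert pop.total_active_te() == 0
        assert all(h.genome.n_dead_te == 2 for h in pop.hosts)

    def test_dead_tes_enlarge_the_noncoding_targeting_pool(self):
        params = small_params(death_rate=1.0)
        pop = make_pop(params)
        host = pop.hosts[0]
        nc_before = host.genome.n_noncoding + host.genome.n_dead_te
        te_death(pop)
        assert host.genome.n_noncoding + host.genome.n_dead_te == nc_before + 2


class TestMutateHosts:
    def test_zero_rate_no_change(self):
        pop = make_pop(small_params(mutation_rate=0.0))
        log = mutate_hosts(pop)
        assert log["coding_mutations"] == log["te_inactivations"] == 0

    def test_all_coding_rate_one_closed_form_fitness(self):
        params = small_params(
            carrying_capacity=1,
            genome_length=100,
            non_coding_fraction=0.0,
            initial_te_per_host=0,
            mutation_rate=1.0,
            mutation_effect=0.01,
        )
        pop = make_pop(params)
        mutate_hosts(pop)
        assert pop.hosts[0].fitness == pytest.approx(0.99**100)

    def test_rate_one_inactivates_every_active_te(self):
        params = small_params(mutation_rate=1.0, mutation_effect=0.0)
        pop = make_pop(params)
        mutate_hosts(pop)
        assert pop.total_active_te() == 0
        assert all(h.genome.n_dead_te == 2 for h in pop.hosts)


class TestReproduce:
    def test_population_returns_to_carrying_capacity(self):
        pop = make_pop(small_params(carrying_capacity=20))
        reproduce(pop)
        assert pop.size == 20

    def test_zero_fitness_host_leaves_no_offspring(self):
        pop = make_pop(small_params(carrying_capacity=10))
        doomed = pop.hosts[0].id
        pop.hosts[0].fitness = 0.0
        for _ in range(5):
            reproduce(pop)
            assert doomed not in {h.id for h in pop.hosts}
            if not pop.hosts:
                break

    def test_offspring_share_matches_fitness_ratio(self):
        # fitness 3 vs 1, K=1000 -> share 0.75 +/- 0.04 (3 sigma)
        params = small_params(carrying_capacity=1000, initial_te_per_host=0)
        pop = make_pop(params)
        pop.hosts = pop.hosts[:2]
        pop.hosts[0].fitness = 3.0
        pop.hosts[1].fitness = 1.0
        lineage0 = pop.hosts[0].lineage
        reproduce(pop)
        share = sum(h.lineage == lineage0 for h in pop.hosts) / 1000
        assert share == pytest.approx(0.75, abs=0.04)

    def test_all_zero_fitness_extinguishes_population(self):
        pop = make_pop(small_params())
        for host in pop.hosts:
            host.fitness = 0.0
        log = reproduce(pop)
        assert pop.size == 0
        assert log["host_deaths"] == 20


class TestStepGeneration:
    def test_all_rates_zero_only_advances_the_clock(self):
        pop = make_pop(small_params())
        total = pop.total_active_te()
        rec = step_generation(pop)
        assert rec.generation == 1
        assert rec.total_active_te == total
        assert rec.insertions == rec.excisions == rec.te_deaths == 0

    def test_ledger_balances_over_a_seeded_run(self):
        params = small_params(
            carrying_capacity=30,
            transposition_rate=0.2,
            excision_rate=0.05,
            death_rate=0.02,
            mutation_rate=0.01,
            initial_te_per_host=5,
            effect_distribution=make_effect_distribution(10.0),
        )
        pop = make_pop(params)
        prev_total = pop.total_active_te()
        for _ in range(50):
            rec = step_generation(pop)
            expected = (
                prev_total
                + rec.insertions
                - rec.excisions
                - rec.te_deaths
                - rec.te_inactivations
                + rec.te_repro_delta
            )
            assert rec.total_active_te == expected
            # counts caches agree with fresh tallies
            for host in pop.hosts:
                assert np.array_equal(host.genome.counts, host.genome.tally())
            assert rec.population_size <= params.carrying_capacity
            prev_total = rec.total_active_te
            if prev_total == 0:
                break

    def test_identical_seeds_give_identical_records(self):
        params = small_params(
            carrying_capacity=15,
            transposition_rate=0.3,
            excision_rate=0.05,
            mutation_rate=0.01,
            effect_distribution=make_effect_distribution(5.0),
        )
        runs = []
        for _ in range(2):
            pop = make_pop(params, seed=99)
            runs.append([step_generation(pop) for _ in range(20)])
        assert runs[0] == runs[1]

    def test_te_copies_never_cross_founder_lineages(self):
        # every TE in generation g+1 sits in a host whose lineage tag traces
        # to exactly one founder; a TE-free founder lineage can never gain TEs
        params = small_params(
            carrying_capacity=12,
            transposition_rate=0.5,
            initial_te_per_host=2,
            effect_distribution=NEUTRAL_ONLY,
        )
        pop = make_pop(params)
        te_free = pop.hosts[0].lineage
        pop.hosts[0].genome.convert(
            pop.hosts[0].genome.indices_of(LocusClass.ACTIVE_TE), LocusClass.NONCODING
        )
        founders = {h.lineage for h in pop.hosts}
        for _ in range(15):
            step_generation(pop)
            assert {h.lineage for h in pop.hosts} <= founders
            for host in pop.hosts:
                if host.lineage == te_free:
                    assert host.genome.n_active_te == 0

    def test_mean_fitness_never_rises_without_beneficial_insertions(self):
        # transposition only, p_beneficial = 0: fitness multipliers are all <= 1
        params = small_params(
            carrying_capacity=25,
            transposition_rate=0.5,
            initial_te_per_host=4,
            effect_distribution=make_effect_distribution(0.0),
        )
        pop = make_pop(params)
        fitness_by_id = {h.id: h.fitness for h in pop.hosts}
        for _ in range(20):
            transpose(pop)
            for host in pop.hosts:
                assert host.fitness <= fitness_by_id.get(host.id, 1.0) + 1e-15
            reproduce(pop)
            if not pop.hosts:
                break
            fitness_by_id = {h.id: h.fitness for h in pop.hosts}
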