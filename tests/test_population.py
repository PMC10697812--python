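"""Individuals, producer logic, fitness, frequencies and population files."""

import numpy as np
import pytest
from scipy import stats as sps

from tesim.genome import classify_site
from tesim.population import (
    Individual,
    Population,
    count_by_class,
    exists_fixed_producing_locus,
    fitness,
    fixed_positions,
    generate_base_population,
    insertion_frequency,
    is_fixed,
    is_pirna_producer,
    read_base_population,
    write_base_population,
)


def _random_population(arch, N, mean_copies, rng):
    inds = []
    for _ in range(N):
        k1, k2 = rng.poisson(mean_copies, size=2)
        h1 = np.unique(rng.integers(0, arch.g, size=k1))
        h2 = np.unique(rng.integers(0, arch.g, size=k2))
        inds.append(
            Individual(h1, h2, sex="F" if rng.random() < 0.5 else "M", m=int(rng.random() < 0.5))
        )
    return Population.from_individuals(inds)


class TestCounts:
    def test_empty_individual_counts_zero(self, small_arch):
        ind = Individual(np.array([], int), np.array([], int))
        assert count_by_class(ind, small_arch) == (0, 0, 0, 0, 0)

    def test_mixed_example(self, small_arch):
        # pos 0 in cluster; pos 10_000 paramutable (residue 0 outside clusters)
        ind = Individual(np.array([0]), np.array([10_000]))
        assert count_by_class(ind, small_arch) == (2, 1, 1, 0, 0)

    def test_counts_match_per_site_classification(self, small_arch, rng):
        """Brute-force oracle: classify every insertion one by one."""
        pop = _random_population(small_arch, 20, 8, rng)
        for ind in pop.individuals():
            n, n_clu, n_par, n_tri, n_other = count_by_class(ind, small_arch)
            classes = [classify_site(int(p), small_arch).value for p in ind.positions()]
            assert n == len(classes)
            assert n_clu == classes.count("cluster")
            assert n_par == classes.count("paramutable")
            assert n_tri == classes.count("trigger")
            assert n_other == classes.count("neutral")


class TestProducerLogic:
    CLUSTER_POS = 0  # inside first cluster of small_arch
    PARA_POS = 10_000  # paramutable residue outside clusters
    TRIG_POS = 10_097  # trigger residue
    NEUTRAL_POS = 10_001

    def _ind(self, positions, m):
        return Individual(np.array(sorted(positions), dtype=int), np.array([], int), m=m)

    @pytest.mark.parametrize(
        "m,has_cluster,has_para,expected",
        [
            (0, False, False, False),  # naive individual: TE active
            (0, True, False, True),  # cluster insertion triggers piRNAs
            (0, False, True, False),  # paramutable TE without maternal piRNAs
            (0, True, True, True),
            (1, False, False, False),  # maternal piRNAs alone: TE reactivated
            (1, True, False, True),
            (1, False, True, True),  # paramutated TE
            (1, True, True, True),
        ],
    )
    def test_trap_model_truth_table(self, small_arch, m, has_cluster, has_para, expected):
        """All eight inheritance scenarios of the trap model with paramutations."""
        positions = [self.NEUTRAL_POS]
        if has_cluster:
            positions.append(self.CLUSTER_POS)
        if has_para:
            positions.append(self.PARA_POS)
        ind = self._ind(positions, m)
        assert is_pirna_producer(ind, small_arch, "trap") is expected

    def test_sirna_trigger_alone_is_not_enough(self, small_arch):
        ind = self._ind([self.TRIG_POS], m=0)
        assert not is_pirna_producer(ind, small_arch, "sirna")

    def test_sirna_trigger_plus_paramutable_produces(self, small_arch):
        ind = self._ind([self.TRIG_POS, self.PARA_POS], m=0)
        assert is_pirna_producer(ind, small_arch, "sirna")

    def test_sirna_maternal_channel_still_works(self, small_arch):
        ind = self._ind([self.PARA_POS], m=1)
        assert is_pirna_producer(ind, small_arch, "sirna")

    def test_sirna_ignores_cluster_insertions(self, small_arch):
        ind = self._ind([self.CLUSTER_POS], m=0)
        assert not is_pirna_producer(ind, small_arch, "sirna")


class TestFitness:
    def _ind_with_n(self, n):
        return Individual(np.arange(1, n + 1, dtype=int), np.array([], int))

    def test_te_free_individual_has_unit_fitness(self):
        ind = self._ind_with_n(0)
        assert fitness(ind, 0.1, "linear") == 1.0
        assert fitness(ind, 0.1, "multiplicative") == 1.0

    def test_linear_formula(self):
        assert fitness(self._ind_with_n(10), 0.03, "linear") == pytest.approx(0.7)

    def test_multiplicative_formula(self):
        assert fitness(self._ind_with_n(2), 0.1, "multiplicative") == pytest.approx(0.81)

    def test_linear_clamps_at_zero(self):
        assert fitness(self._ind_with_n(3), 0.5, "linear") == 0.0

    def test_models_agree_to_first_order(self):
        ind = self._ind_with_n(5)
        x = 1e-4
        lin = fitness(ind, x, "linear")
        mult = fitness(ind, x, "multiplicative")
        assert lin == pytest.approx(mult, abs=1e-6)

    def test_cluster_neutral_excludes_cluster_insertions(self, small_arch):
        ind = Individual(np.array([0, 1, 2]), np.array([10_001]))  # 3 cluster + 1 neutral
        w = fitness(ind, 0.1, "linear", cluster_neutral=True, arch=small_arch)
        assert w == pytest.approx(0.9)

    def test_invalid_x_rejected(self):
        with pytest.raises(ValueError):
            fitness(self._ind_with_n(1), 1.5)

    def test_monotone_in_copy_number(self):
        ws = [fitness(self._ind_with_n(n), 0.05, "linear") for n in range(0, 25, 5)]
        assert ws == sorted(ws, reverse=True)


class TestFrequencies:
    def test_single_copy_frequency(self):
        inds = [Individual(np.array([], int), np.array([], int)) for _ in range(1000)]
        inds[0] = Individual(np.array([42]), np.array([], int))
        pop = Population.from_individuals(inds)
        assert insertion_frequency(pop, 42) == pytest.approx(1 / 2000)

    def test_absent_and_fixed(self, small_arch, rng):
        inds = [Individual(np.array([7]), np.array([7]), m=0) for _ in range(10)]
        pop = Population.from_individuals(inds)
        assert insertion_frequency(pop, 123) == 0.0
        assert is_fixed(pop, 7)
        assert np.array_equal(fixed_positions(pop), [7])

    def test_frequencies_match_exhaustive_scan(self, small_arch, rng):
        """Brute-force oracle over every haplotype of a random population."""
        pop = _random_population(small_arch, 15, 5, rng)
        sites = np.unique(pop.positions)
        for pos in sites[:50]:
            manual = sum(
                int(pos in pop.haplotype(h)) for h in range(2 * pop.size)
            ) / (2 * pop.size)
            assert insertion_frequency(pop, int(pos)) == pytest.approx(manual)

    def test_frequency_conservation(self, small_arch, rng):
        pop = _random_population(small_arch, 15, 5, rng)
        total = sum(
            insertion_frequency(pop, int(p)) * 2 * pop.size for p in np.unique(pop.positions)
        )
        assert total == pytest.approx(pop.total_copies)


class TestFixedProducingLocus:
    def test_fixed_cluster_insertion_silences(self, small_arch):
        inds = [Individual(np.array([3]), np.array([3]), m=0) for _ in range(8)]
        pop = Population.from_individuals(inds)
        assert exists_fixed_producing_locus(pop, small_arch, "trap")

    def test_fixed_paramutable_without_universal_producers_does_not(self, small_arch):
        # everyone carries the fixed paramutable TE but one individual has m=0:
        # its TE is active, so silencing is not population-wide
        inds = [Individual(np.array([10_000]), np.array([10_000]), m=1) for _ in range(8)]
        inds[0].m = 0
        pop = Population.from_individuals(inds)
        assert not exists_fixed_producing_locus(pop, small_arch, "trap")
        for ind in inds:
            ind.m = 1
        pop = Population.from_individuals(inds)
        assert exists_fixed_producing_locus(pop, small_arch, "trap")

    def test_no_fixation_no_silencing(self, small_arch, rng):
        pop = _random_population(small_arch, 10, 3, rng)
        if fixed_positions(pop).size == 0:
            assert not exists_fixed_producing_locus(pop, small_arch, "trap")


class TestBasePopulation:
    def test_copies_and_frequency(self, small_arch, rng):
        pop = generate_base_population(small_arch, 50, 30, rng)
        assert pop.size == 50
        assert pop.total_copies == 30
        assert np.all(pop.m == 0)
        for p in np.unique(pop.positions):
            assert insertion_frequency(pop, int(p)) == pytest.approx(1 / 100)

    def test_zero_insertions(self, small_arch, rng):
        pop = generate_base_population(small_arch, 10, 0, rng)
        assert pop.total_copies == 0

    def test_positions_distinct_and_uniform(self, small_arch):
        """Chi-square goodness of fit of pooled founder positions vs uniform."""
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(200):
            pop = generate_base_population(small_arch, 5, 50, rng)
            assert np.unique(pop.positions).size == 50
            draws.append(pop.positions)
        pooled = np.concatenate(draws)
        counts, _ = np.histogram(pooled, bins=20, range=(0, small_arch.g))
        p = sps.chisquare(counts).pvalue
        assert p > 1e-4


class TestPopulationFiles:
    def test_round_trip(self, small_arch, rng, tmp_path):
        pop = _random_population(small_arch, 12, 4, rng)
        path = tmp_path / "pop.txt"
        write_base_population(pop, path)
        back = read_base_population(path, small_arch)
        assert back == pop

    def test_empty_haplotype_field(self, tmp_path):
        path = tmp_path / "pop.txt"
        path.write_text("#sex\tm\thap1\thap2\nF\t0\t\t5,9\n")
        pop = read_base_population(path)
        assert pop.haplotype(0).size == 0
        assert list(pop.haplotype(1)) == [5, 9]

    @pytest.mark.parametrize(
        "line,match",
        [
            ("X\t0\t1\t2", "line 2"),
            ("F\t2\t1\t2", "line 2"),
            ("F\t0\t1,1\t2", "duplicate"),
            ("F\t0\t1", "4 tab-separated"),
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line, match):
        path = tmp_path / "pop.txt"
        path.write_text("#sex\tm\thap1\thap2\n" + line + "\n")
        with pytest.raises(ValueError, match=match):
            read_base_population(path)

    def test_position_beyond_genome_rejected(self, small_arch, tmp_path):
        path = tmp_path / "pop.txt"
        path.write_text(f"F\t0\t{small_arch.g}\t\n")
        with pytest.raises(ValueError, match="line 1"):
            read_base_population(path, small_arch)
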