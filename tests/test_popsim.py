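"""Simulator unit tests: founders, meiosis, drift, trait, selection, datasets."""

import numpy as np
import pytest

from qtlblup import popsim
from qtlblup.popsim import (
    GenomeMap,
    PopulationSchedule,
    SimulationConfig,
    assign_trait,
    compute_tbv,
    init_founders,
    meiosis,
    pseudo_ebv,
    random_mating_generation,
    run_historic_phase,
    run_selection_phase,
    segregating_loci,
    simulate_phenotype,
    simulate_study,
)


class TestGenomeMap:
    def test_default_build_dimensions(self):
        g = GenomeMap.random(seed=0)
        assert g.n_chromosomes == 29
        assert g.n_loci == 29 * 2350
        assert len(g.qtl_loci) == 29 * 350
        assert len(g.snp_loci) == 29 * 2000

    def test_positions_strictly_increasing_within_chromosomes(self, tiny_genome):
        for c in range(tiny_genome.n_chromosomes):
            pos = tiny_genome.position_cM[tiny_genome.chromosome == c]
            assert np.all(np.diff(pos) > 0)
            assert pos.min() >= 0 and pos.max() <= tiny_genome.chrom_length_cM

    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError):
            GenomeMap(
                chromosome=[0, 0], position_cM=[5.0, 2.0], is_qtl=[False, True],
                chrom_length_cM=10.0, n_chromosomes=1,
            )


class TestFounders:
    def test_equal_sex_ratio(self, tiny_genome):
        pop = init_founders(2800, tiny_genome, seed=0)
        assert len(pop.males) == 1400 and len(pop.females) == 1400

    def test_odd_count_rejected(self, tiny_genome):
        with pytest.raises(ValueError):
            init_founders(7, tiny_genome, seed=0)

    def test_dosage_domain(self):
        g = GenomeMap(
            chromosome=[0], position_cM=[1.0], is_qtl=[True],
            chrom_length_cM=10.0, n_chromosomes=1,
        )
        pop = init_founders(2, g, seed=0)
        assert set(pop.dosages().ravel()) <= {0, 1, 2}

    def test_allele_frequencies_binomial(self):
        # 1,000 founders, 1,000 loci: per-locus p is Binomial(2000, .5)/2000
        g = GenomeMap.random(2, 100.0, 100, 400, seed=1)
        pop = init_founders(1000, g, seed=2)
        p = pop.allele_frequencies()
        assert abs(p.mean() - 0.5) < 0.005
        assert abs(p.std() - np.sqrt(0.25 / 2000)) < 0.002


class TestMeiosis:
    def test_zero_length_chromosome_passes_haplotype_intact(self):
        # (near-)zero map length: no recombination is possible, so each
        # gamete is one parental haplotype passed on intact
        pos = np.linspace(0, 1e-9, 5)
        g = GenomeMap(
            chromosome=[0] * 5, position_cM=pos, is_qtl=[False] * 5,
            chrom_length_cM=1e-9, n_chromosomes=1,
        )
        parent = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], dtype=np.uint8)
        for seed in range(20):
            gam = meiosis(parent, g, seed)
            assert gam.sum() in (0, 5)  # one haplotype, intact

    def test_haldane_recombination_fraction(self):
        # two loci d = 0.1 Morgans apart: r = (1 - exp(-0.2)) / 2 = 0.0906
        g = GenomeMap(
            chromosome=[0, 0], position_cM=[10.0, 20.0], is_qtl=[False, False],
            chrom_length_cM=100.0, n_chromosomes=1,
        )
        parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        rng = np.random.default_rng(5)
        n = 40000
        gam = popsim._gametes(np.broadcast_to(parent, (n, 2, 2)), g, rng)
        r_hat = np.mean(gam[:, 0] != gam[:, 1])
        r_exp = 0.5 * (1 - np.exp(-2 * 0.1))
        assert abs(r_hat - r_exp) < 3 * np.sqrt(r_exp * (1 - r_exp) / n)

    def test_mean_crossovers_one_per_morgan(self):
        # dense 100 cM chromosome: observed switch count ~ Poisson mean 1
        g = GenomeMap.random(1, 100.0, 0, 500, seed=3)
        parent = np.zeros((2, 500), dtype=np.uint8)
        parent[1] = 1
        rng = np.random.default_rng(6)
        n = 20000
        gam = popsim._gametes(np.broadcast_to(parent, (n, 2, 500)), g, rng)
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        assert abs(switches.mean() - 1.0) < 0.05

    def test_mendelian_consistency(self, tiny_genome, rng):
        pop = init_founders(20, tiny_genome, seed=7)
        off = random_mating_generation(pop, 40, tiny_genome, rng, 1, 100)
        for i in range(off.n):
            s = np.flatnonzero(pop.ids == off.sire[i])[0]
            d = np.flatnonzero(pop.ids == off.dam[i])[0]
            pat, mat = off.haplotypes[i]
            assert np.all((pat == pop.haplotypes[s, 0]) | (pat == pop.haplotypes[s, 1]))
            assert np.all((mat == pop.haplotypes[d, 0]) | (mat == pop.haplotypes[d, 1]))


class TestHistoricPhase:
    def test_schedule_interpolation_monotone(self):
        s = PopulationSchedule.full().historic_sizes()
        assert s[0] == 2800
        assert abs(s[2249] - 2000) <= 1
        assert abs(s[2499] - 200) <= 1
        assert s[-1] == 10000
        assert np.all(np.diff(s[:2500]) <= 0)  # gradual decrease
        assert np.all(np.diff(s[2499:]) >= 0)  # linear increase

    def test_final_size_mini(self, tiny_genome):
        sched = PopulationSchedule(
            historic_anchors=((1, 40), (10, 20), (15, 60)), n_sires=2, n_dams=10
        )
        pop = run_historic_phase(sched, tiny_genome, seed=0)
        assert pop.n == 60
        assert np.all(pop.generation == 0)

    def test_one_generation_drift_within_binomial_error(self, tiny_genome, rng):
        pop = init_founders(500, tiny_genome, seed=1)
        off = random_mating_generation(pop, 500, tiny_genome, rng, 1, 1000)
        diff = off.allele_frequencies() - pop.allele_frequencies()
        # offspring frequency is a binomial resample: SE <= sqrt(.25/(2n)) * ~sqrt(2)
        assert np.abs(diff).max() < 6 * np.sqrt(0.25 / 500)

    def test_wright_fisher_heterozygosity_decay(self):
        # neutral mini-population: E[het_t] = het_0 * (1 - 1/(2N))^t
        g = GenomeMap.random(1, 100.0, 0, 500, seed=4)
        N, T = 50, 200
        sched = PopulationSchedule(historic_anchors=((1, N), (T, N)))
        ratios = []
        for seed in range(4):
            pop = run_historic_phase(sched, g, seed=seed)
            p = pop.allele_frequencies()
            ratios.append(np.mean(2 * p * (1 - p)) / 0.5)
        expected = (1 - 1 / (2 * N)) ** (T - 1)
        assert abs(np.mean(ratios) - expected) < 0.05


class TestTrait:
    @pytest.fixture(scope="class")
    def pop_and_genome(self):
        g = GenomeMap.random(2, 100.0, 50, 200, seed=9)
        pop = init_founders(2000, g, seed=10)
        return pop, g

    def test_variance_calibration(self, pop_and_genome):
        pop, g = pop_and_genome
        arch = assign_trait(pop, g, seed=0)
        tbv = compute_tbv(pop.dosages(), arch)
        assert np.isclose(tbv.var(), arch.sigma_g2)
        assert np.isclose(arch.sigma_e2, 3.0 * arch.sigma_g2)  # h2 = 0.25

    def test_realized_heritability(self, pop_and_genome):
        pop, g = pop_and_genome
        arch = assign_trait(pop, g, seed=1)
        tbv = compute_tbv(pop.dosages(), arch)
        y = simulate_phenotype(tbv, arch.sigma_e2, seed=2)
        h2 = tbv.var() / y.var()
        assert abs(h2 - 0.25) < 0.03

    def test_gamma_effects_heavy_tailed(self, pop_and_genome):
        pop, g = pop_and_genome
        arch = assign_trait(pop, g, seed=3)
        a2 = np.sort(np.abs(arch.effects)) ** 2
        k = len(a2) // 10
        assert a2[-k:].sum() / a2[:k].sum() > 50  # top vs bottom decile

    def test_compute_tbv_hand_example(self):
        arch = popsim.TraitArchitecture(
            qtl_loci=np.array([0, 1]), effects=np.array([0.5, -2.0]),
            sigma_g2=1.0, sigma_e2=3.0, h2=0.25,
        )
        X = np.array([[0, 0], [2, 0], [1, 2]])
        np.testing.assert_allclose(compute_tbv(X, arch), [0.0, 1.0, -3.5])

    def test_compute_tbv_missing_columns_rejected(self):
        arch = popsim.TraitArchitecture(
            qtl_loci=np.array([0, 5]), effects=np.array([1.0, 1.0]),
            sigma_g2=1.0, sigma_e2=3.0, h2=0.25,
        )
        with pytest.raises(ValueError):
            compute_tbv(np.zeros((3, 4)), arch)

    def test_phenotype_no_noise_equals_tbv(self):
        tbv = np.array([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(simulate_phenotype(tbv, 0.0, seed=0), tbv)

    def test_phenotype_variance_additive(self):
        rng = np.random.default_rng(0)
        tbv = rng.normal(0, 1.0, 20000)
        y = simulate_phenotype(tbv, 3.0, seed=1)
        assert abs(y.var() - 4.0) < 0.15
        assert abs(np.corrcoef(y, tbv)[0, 1] ** 2 - 0.25) < 0.02


class TestPseudoEbv:
    def test_perfect_accuracy_preserves_ranking(self, rng):
        tbv = rng.normal(size=100)
        ebv = pseudo_ebv(tbv, 1.0, seed=0)
        assert np.array_equal(np.argsort(ebv), np.argsort(tbv))

    def test_zero_accuracy_uncorrelated(self, rng):
        tbv = rng.normal(size=5000)
        ebv = pseudo_ebv(tbv, 0.0, seed=1)
        assert abs(np.corrcoef(ebv, tbv)[0, 1]) < 0.05

    def test_stated_accuracy_realized(self, rng):
        tbv = rng.normal(size=5000)
        ebv = pseudo_ebv(tbv, 0.8, seed=2)
        assert abs(np.corrcoef(ebv, tbv)[0, 1] - 0.8) < 0.02

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            pseudo_ebv(np.zeros(3), 1.5)


def _mini_selection(accuracy, seed, n_generations=8):
    g = GenomeMap.random(2, 100.0, 30, 100, seed=seed)
    sched = PopulationSchedule(
        historic_anchors=((1, 100), (60, 100)), n_generations=n_generations,
        n_sires=5, n_dams=50, ebv_accuracy=accuracy,
    )
    pop0 = run_historic_phase(sched, g, seed=seed + 1)
    arch = assign_trait(pop0, g, seed=seed + 2)
    pop0.tbv = compute_tbv(pop0.dosages(), arch)
    pop0.phenotype = simulate_phenotype(pop0.tbv, arch.sigma_e2, seed=seed + 3)
    pop0.ebv = pseudo_ebv(pop0.tbv, accuracy, seed=seed + 4)
    pops = run_selection_phase(pop0, arch, g, sched, seed=seed + 5)
    return pop0, pops


class TestSelectionPhase:
    def test_offspring_counts_and_sexes(self):
        _, pops = _mini_selection(0.8, seed=20, n_generations=3)
        for g, pop in pops.items():
            assert pop.n == 50
            assert len(pop.males) == 25

    def test_positive_selection_response(self):
        # replicate-averaged genetic gain under accuracy-0.8 selection
        gains = []
        for seed in range(0, 50, 10):
            pop0, pops = _mini_selection(0.8, seed=seed)
            gains.append(pops[8].tbv.mean() - pop0.tbv.mean())
        assert np.mean(gains) > 0.5  # i ~ 2 sd at 5/50 sires alone

    def test_no_response_under_random_selection(self):
        gains = []
        for seed in range(0, 50, 10):
            pop0, pops = _mini_selection(0.0, seed=seed)
            gains.append(pops[8].tbv.mean() - pop0.tbv.mean())
        assert abs(np.mean(gains)) < 0.3

    def test_insufficient_candidates_rejected(self, tiny_genome):
        pop0 = init_founders(10, tiny_genome, seed=0)
        arch = assign_trait(pop0, tiny_genome, seed=1)
        pop0.tbv = compute_tbv(pop0.dosages(), arch)
        pop0.phenotype = simulate_phenotype(pop0.tbv, arch.sigma_e2, seed=2)
        pop0.ebv = pseudo_ebv(pop0.tbv, 0.8, seed=3)
        sched = PopulationSchedule(
            historic_anchors=((1, 10), (2, 10)), n_sires=20, n_dams=5
        )
        with pytest.raises(ValueError, match="male"):
            run_selection_phase(pop0, arch, tiny_genome, sched, seed=4)


class TestDatasets:
    @pytest.fixture(scope="class")
    def study(self):
        cfg = SimulationConfig(
            n_chromosomes=2, n_qtl_per_chromosome=30, n_snp_per_chromosome=100,
            schedule=PopulationSchedule(
                historic_anchors=((1, 80), (40, 80), (50, 200)),
                n_sires=5, n_dams=100,
            ),
            n_train_per_generation=40, n_test_per_generation=30,
        )
        return cfg, simulate_study(cfg, seed=31)

    def test_sizes_and_disjoint_ids(self, study):
        cfg, s = study
        assert s.datasets.train.n == 40 * 5
        assert all(t.n == 30 for t in s.datasets.tests.values())
        train_ids = set(s.datasets.train.ids)
        for t in s.datasets.tests.values():
            assert not train_ids & set(t.ids)

    def test_sampling_is_seeded_and_without_replacement(self, study):
        cfg, s = study
        s2 = simulate_study(cfg, seed=31)
        assert np.array_equal(s.datasets.train.ids, s2.datasets.train.ids)
        assert len(np.unique(s.datasets.train.ids)) == s.datasets.train.n

    def test_oversampling_rejected(self, study):
        cfg, s = study
        import dataclasses

        bad = dataclasses.replace(cfg, n_train_per_generation=101)
        with pytest.raises(ValueError, match="sample"):
            simulate_study(bad, seed=31)


class TestSegregatingLoci:
    def test_fixed_locus_excluded(self, tiny_genome):
        pop = init_founders(10, tiny_genome, seed=0)
        pop.haplotypes[:, :, 0] = 0  # fix locus 0
        pop.haplotypes[:, :, 1] = 1  # fix locus 1 at the other allele
        seg = segregating_loci(pop)
        assert 0 not in seg and 1 not in seg

    def test_class_filter(self, tiny_genome):
        pop = init_founders(50, tiny_genome, seed=1)
        snps = segregating_loci(pop, tiny_genome, "SNP")
        assert np.all(~tiny_genome.is_qtl[snps])
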