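"""Meiosis, pedigree, phenotype and pooled-sequencing simulator checks."""

import numpy as np
import pandas as pd
import pytest

from bsamap.genome import default_rice_genome
from bsamap.simulate import (DONOR, RECURRENT, PhredModel, QtlModel,
                             assign_phenotypes, breed_bc2f8, founder,
                             genotype_table, phenotype_table,
                             pooled_donor_frequency, simulate_bulk_pileup,
                             simulate_cohort_pileup, simulate_gamete,
                             uniform_haplotype, Individual)


def _assert_tiles(hap, length):
    segs = hap.segments()
    assert segs[0][0] == 1
    assert segs[-1][1] == length
    for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
        assert s2 == e1 + 1


class TestGamete:
    def test_homozygous_parent_gamete_is_uniform(self, small_genome, rng):
        donor = founder(small_genome, DONOR)
        for _ in range(5):
            g = simulate_gamete(donor, small_genome, rng)
            for c in small_genome.chromosomes:
                hap = g[c.name]
                assert (hap.origins == DONOR).all()
                _assert_tiles(hap, c.length_bp)

    def test_zero_genetic_length_returns_parental_haplotype(self, rng):
        from bsamap.genome import Chromosome, GenomeModel
        g = GenomeModel([Chromosome("c1", 1_000_000, 0.0)],
                        pd.DataFrame({"chrom": ["c1"], "pos": [500],
                                      "donor": ["A"], "recurrent": ["G"]}))
        f1 = Individual({"c1": (uniform_haplotype(1_000_000, DONOR),
                                uniform_haplotype(1_000_000, RECURRENT))})
        for _ in range(10):
            hap = simulate_gamete(f1, g, rng)["c1"]
            assert len(hap.ends) == 1  # one of the two unrecombined haplotypes

    def test_crossover_count_poisson_mean(self, rng):
        """F1 on a 100 cM chromosome: mean switches ~ Poisson(1) mean."""
        from bsamap.genome import Chromosome, GenomeModel
        g = GenomeModel([Chromosome("c1", 50_000_000, 100.0)],
                        pd.DataFrame({"chrom": ["c1"], "pos": [500],
                                      "donor": ["A"], "recurrent": ["G"]}))
        f1 = Individual({"c1": (uniform_haplotype(50_000_000, DONOR),
                                uniform_haplotype(50_000_000, RECURRENT))})
        switches = [len(simulate_gamete(f1, g, rng)["c1"].ends) - 1
                    for _ in range(10_000)]
        assert np.mean(switches) == pytest.approx(1.0, abs=0.03)

    def test_gamete_tiles_chromosome(self, small_genome, rng):
        donor = founder(small_genome, DONOR)
        recurrent = founder(small_genome, RECURRENT)
        f1 = Individual({c.name: (simulate_gamete(donor, small_genome, rng)[c.name],
                                  simulate_gamete(recurrent, small_genome, rng)[c.name])
                         for c in small_genome.chromosomes})
        for _ in range(50):
            g = simulate_gamete(f1, small_genome, rng)
            for c in small_genome.chromosomes:
                _assert_tiles(g[c.name], c.length_bp)


class TestPedigree:
    @pytest.fixture(scope="class")
    def population(self, ):
        genome = default_rice_genome(site_spacing=5_000_000)
        return genome, breed_bc2f8(genome, 600, rng_seed=99)

    def test_alleles_binary_and_tiling(self, population):
        genome, pop = population
        for ind in pop[:20]:
            for c in genome.chromosomes:
                pos = genome.site_positions(c.name)
                d = ind.dosage(c.name, pos)
                assert set(np.unique(d)) <= {0, 1, 2}
                for hap in ind.haplotypes[c.name]:
                    _assert_tiles(hap, c.length_bp)

    def test_donor_fraction_is_one_eighth(self, population):
        """Two backcrosses halve the donor genome twice: expect 12.5%."""
        genome, pop = population
        gt = genotype_table(pop, genome)
        frac = gt.drop(columns=["chrom", "pos"]).to_numpy().mean() / 2
        assert frac == pytest.approx(0.125, abs=0.01)

    def test_residual_heterozygosity(self, population):
        """Seven selfings from BC2F1: het = (1/4) * (1/2)^7 ~ 0.00195."""
        genome, pop = population
        gt = genotype_table(pop, genome).drop(columns=["chrom", "pos"])
        draws = gt.to_numpy().ravel()
        rng = np.random.default_rng(5)
        sample = rng.choice(draws, size=10_000, replace=False)
        p = 0.25 * 0.5 ** 7
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs((sample == 1).mean() - p) <= 3 * se

    def test_bit_reproducible(self, small_genome):
        a = breed_bc2f8(small_genome, 20, rng_seed=7)
        b = breed_bc2f8(small_genome, 20, rng_seed=7)
        ga = genotype_table(a, small_genome)
        gb = genotype_table(b, small_genome)
        pd.testing.assert_frame_equal(ga, gb)


class TestPhenotypes:
    def test_no_qtl_no_noise_gives_baseline(self, small_genome):
        pop = breed_bc2f8(small_genome, 10, rng_seed=3)
        qtl = QtlModel(baseline_ac=23.2, qtl_effects=[], env_sd=0.0)
        assign_phenotypes(pop, qtl, 0)
        assert all(ind.phenotype_ac == pytest.approx(23.2) for ind in pop)

    def test_single_qtl_homozygous_donor_reaches_donor_parent_value(self):
        """+2.5 on the 23.2 baseline puts a full donor at 25.7% amylose."""
        genome = default_rice_genome(site_spacing=10_000_000)
        donor = founder(genome, DONOR, id="donor")
        qtl = QtlModel(23.2, [("chr06", 1_769_686, 2.5)], env_sd=0.0)
        assign_phenotypes([donor], qtl, 0)
        assert donor.phenotype_ac == pytest.approx(25.7)

    def test_opposite_sign_minor_gives_transgressive_low(self):
        """A donor segment at the negative minor locus alone drops amylose
        below the recurrent parent (transgressive segregation)."""
        genome = default_rice_genome(site_spacing=10_000_000)
        low = founder(genome, RECURRENT)
        chrom_len = genome.chromosome("chr01").length_bp
        from bsamap.simulate import Haplotype
        hap = Haplotype(np.array([chrom_len]), np.array([DONOR], dtype=np.int8))
        low.haplotypes["chr01"] = (hap, hap)
        assign_phenotypes([low], QtlModel(env_sd=0.0), 0)
        assert low.phenotype_ac < 23.2

    def test_env0_variance_matches_additive_formula(self):
        """With env_sd 0, Var(AC) = sum effect^2 p(1-p) at unlinked QTLs
        (inbred lines: dosage is essentially 0/2 with p = 1/8)."""
        genome = default_rice_genome(site_spacing=10_000_000)
        pop = breed_bc2f8(genome, 600, rng_seed=11)
        qtl = QtlModel(env_sd=0.0)
        assign_phenotypes(pop, qtl, 0)
        ac = np.array([i.phenotype_ac for i in pop])
        p = 0.125
        expected = sum(e ** 2 * p * (1 - p) for _, _, e in qtl.qtl_effects)
        assert ac.var() == pytest.approx(expected, rel=0.25)

    def test_qtl_at_missing_site_rejected(self, small_genome):
        pop = breed_bc2f8(small_genome, 2, rng_seed=0)
        qtl = QtlModel(23.2, [("chrA", 123, 1.0)], 0.0)
        with pytest.raises(KeyError):
            qtl.validate_sites(small_genome)


class TestPileup:
    def test_fixed_donor_bulk_no_error_all_donor_reads(self, small_genome, rng):
        bulk = [founder(small_genome, DONOR) for _ in range(4)]
        pile = simulate_cohort_pileup(bulk, small_genome, 50, 0.0, rng)
        sites = small_genome.sites
        merged = pile.merge(sites, on=["chrom", "pos"])
        for b in "ACGT":
            wrong = merged[(merged["donor"] != b) & (merged[b] > 0)]
            assert wrong.empty

    def test_half_donor_pool_mean_fraction(self, small_genome):
        """Pooled frequency 0.5 at depth 50: binomial mean 0.50 +/- 0.01."""
        rng = np.random.default_rng(77)
        bulk = ([founder(small_genome, DONOR) for _ in range(2)]
                + [founder(small_genome, RECURRENT) for _ in range(2)])
        fracs = []
        for _ in range(1500):
            p = simulate_bulk_pileup(bulk, ("chrA", 1_000_000), small_genome,
                                     50, 0.0, rng, sample="b")
            if p.depth:
                fracs.append(p.counts.get("A", 0) / p.depth)
        assert np.mean(fracs) == pytest.approx(0.50, abs=0.01)

    def test_error_rate_recovered(self, small_genome):
        """1% per-read error on a fixed bulk: 1% +/- 0.1% non-donor reads."""
        rng = np.random.default_rng(123)
        bulk = [founder(small_genome, DONOR)]
        p = simulate_bulk_pileup(bulk, ("chrA", 1_000_000), small_genome,
                                 100_000, 0.01, rng, sample="b")
        non_donor = p.depth - p.counts.get("A", 0)
        assert non_donor / p.depth == pytest.approx(0.01, abs=0.001)

    def test_true_pool_frequency(self, small_genome):
        bulk = ([founder(small_genome, DONOR)]
                + [founder(small_genome, RECURRENT) for _ in range(3)])
        p = pooled_donor_frequency(bulk, "chrA",
                                   small_genome.site_positions("chrA"))
        assert np.allclose(p, 0.25)

    def test_degraded_phred_fraction(self, small_genome):
        rng = np.random.default_rng(9)
        bulk = [founder(small_genome, DONOR)]
        pm = PhredModel(40.0, degraded_fraction=0.5, degraded_value=20.0)
        pile = simulate_cohort_pileup(bulk, small_genome, 30, 0.0, rng, pm)
        assert set(pile["phred"]) <= {20.0, 40.0}
        assert (pile["phred"] == 20.0).any()

    def test_empty_bulk_rejected(self, small_genome, rng):
        with pytest.raises(ValueError):
            simulate_cohort_pileup([], small_genome, 50, 0.0, rng)

    def test_bad_error_rate_rejected(self, small_genome, rng):
        bulk = [founder(small_genome, DONOR)]
        with pytest.raises(ValueError):
            simulate_cohort_pileup(bulk, small_genome, 50, 0.3, rng)

    def test_pileup_reproducible(self, small_genome):
        bulk = [founder(small_genome, DONOR)]
        a = simulate_cohort_pileup(bulk, small_genome, 50, 0.01, 42)
        b = simulate_cohort_pileup(bulk, small_genome, 50, 0.01, 42)
        pd.testing.assert_frame_equal(a, b)
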