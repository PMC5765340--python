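"""Simulation engine: founders, meiosis, trait calibration, drift."""

import numpy as np
import pytest

from gsrefresh.synthpop import (
    SEX_FEMALE,
    SEX_MALE,
    ConfigurationError,
    GenomeSpec,
    TraitModel,
    assign_phenotypes,
    assign_trait,
    make_offspring,
    make_offspring_batch,
    random_union_offspring,
    sample_gamete,
    sample_gametes_batch,
    simulate_founders,
)


class TestGenomeSpec:
    def test_default_layout(self):
        g = GenomeSpec.default()
        assert g.n_markers == 2000
        assert g.n_qtl == 200
        assert g.n_loci == 2200
        # marker and QTL index sets partition the loci
        assert np.intersect1d(g.marker_index, g.qtl_index).size == 0

    def test_rejects_bad_configs(self):
        with pytest.raises(ConfigurationError):
            GenomeSpec(1, 100.0, [[10.0, 5.0]], [[50.0]])  # not increasing
        with pytest.raises(ConfigurationError):
            GenomeSpec(1, 100.0, [[10.0]], [[10.0]])  # overlap
        with pytest.raises(ConfigurationError):
            GenomeSpec.default(founder_allele_freq_range=(0.0, 0.9))


class TestTraitModel:
    def test_h2_consistent_with_components(self):
        t = TraitModel(np.ones(3))
        assert t.h2 == pytest.approx(
            t.sigma2_g / (t.sigma2_g + t.sigma2_e), abs=1e-12
        )
        assert t.h2 == pytest.approx(0.3, abs=0.001)

    def test_rejects_nonpositive_genetic_variance(self):
        with pytest.raises(ConfigurationError):
            TraitModel(np.ones(3), sigma2_g=0.0)


class TestFounders:
    def test_founders_have_unknown_parents(self, tiny_genome):
        pop = simulate_founders(tiny_genome, 10, 10, 5, seed=1, burnin_size=20)
        assert np.all(pop.sire == 0) and np.all(pop.dam == 0)
        assert np.all(pop.generation == 0)
        assert (pop.sex == SEX_MALE).sum() == 10

    def test_zero_burnin_matches_binomial_sampling(self):
        # with all initial frequencies 0.5 and no burn-in, each marker's
        # observed frequency is Binomial(2n, 0.5)/2n; check 4-SE bands
        g = GenomeSpec.default(
            n_chromosomes=2,
            n_markers_per_chrom=100,
            n_qtl_per_chrom=5,
            founder_allele_freq_range=(0.5, 0.5),
        )
        pop = simulate_founders(g, 500, 500, n_burnin_generations=0, seed=2)
        freqs = pop.marker_allele_freqs()
        se = np.sqrt(0.25 / (2 * 1000))
        assert np.all(np.abs(freqs - 0.5) < 4 * se)

    def test_seed_determinism(self, tiny_genome):
        a = simulate_founders(tiny_genome, 10, 10, 5, seed=3, burnin_size=20)
        b = simulate_founders(tiny_genome, 10, 10, 5, seed=3, burnin_size=20)
        c = simulate_founders(tiny_genome, 10, 10, 5, seed=4, burnin_size=20)
        assert np.array_equal(a.haps, b.haps)
        assert not np.array_equal(a.haps, c.haps)

    def test_rejects_zero_counts(self, tiny_genome):
        with pytest.raises(ConfigurationError):
            simulate_founders(tiny_genome, 0, 10, 5, seed=1)


class TestMeiosis:
    def test_gamete_alleles_come_from_parent(self, tiny_founders, rng):
        pop, _ = tiny_founders
        gam = sample_gametes_batch(pop.haps, np.arange(20), pop.genome, rng)
        for k in range(20):
            ok = (gam[k] == pop.haps[k, 0]) | (gam[k] == pop.haps[k, 1])
            assert ok.all()

    def test_homozygous_parent_transmits_identically(self, tiny_genome, rng):
        from gsrefresh.synthpop import Individual

        hap = rng.integers(0, 2, tiny_genome.n_loci).astype(np.uint8)
        parent = Individual(1, 0, 0, SEX_MALE, 0, np.stack([hap, hap]))
        gam = sample_gamete(parent, tiny_genome, rng)
        assert np.array_equal(gam, hap)

    def test_crossover_count_is_poisson_with_map_length_mean(self, rng):
        # 1 chromosome of 100 cM -> mean one crossover per meiosis; estimate
        # the rate from switch points of a maximally informative parent
        g = GenomeSpec(1, 100.0, [np.linspace(0.5, 99.5, 200)], [[]])
        haps = np.stack(
            [np.zeros((1, 200), np.uint8), np.ones((1, 200), np.uint8)], axis=1
        ).reshape(1, 2, 200)
        n = 10_000
        gam = sample_gametes_batch(haps, np.zeros(n, dtype=int), g, rng)
        switches = (np.diff(gam.astype(int), axis=1) != 0).sum(axis=1)
        # observed switches undercount crossovers (double crossovers between
        # adjacent markers cancel); with 200 markers the loss is ~0.25%
        se = np.sqrt(1.0 / n)
        assert switches.mean() == pytest.approx(1.0, abs=3 * se + 0.01)


class TestOffspring:
    def test_homozygous_identical_parents_fix_dosage(self, tiny_genome, rng):
        from gsrefresh.synthpop import Individual

        hap = np.ones(tiny_genome.n_loci, np.uint8)
        sire = Individual(1, 0, 0, SEX_MALE, 0, np.stack([hap, hap]))
        dam = Individual(2, 0, 0, SEX_FEMALE, 0, np.stack([hap, hap]))
        trait = TraitModel(np.zeros(tiny_genome.n_qtl))
        off = make_offspring(sire, dam, SEX_MALE, 1, tiny_genome, trait, rng)
        assert np.all(off.haplotypes.sum(axis=0) == 2)

    def test_zero_residual_variance_gives_phenotype_equal_tbv(
        self, tiny_genome, rng
    ):
        from gsrefresh.synthpop import Individual

        hap = rng.integers(0, 2, tiny_genome.n_loci).astype(np.uint8)
        sire = Individual(1, 0, 0, SEX_MALE, 0, np.stack([hap, hap]))
        dam = Individual(2, 0, 0, SEX_FEMALE, 0, np.stack([hap, 1 - hap]))
        trait = TraitModel(rng.standard_normal(tiny_genome.n_qtl), sigma2_e=0.0)
        off = make_offspring(
            sire, dam, SEX_FEMALE, 1, tiny_genome, trait, rng, with_phenotype=True
        )
        assert off.phenotype == pytest.approx(off.tbv, abs=1e-12)

    def test_sex_mismatch_raises(self, tiny_founders, rng):
        pop, trait = tiny_founders
        males = np.nonzero(pop.sex == SEX_MALE)[0][:2]
        with pytest.raises(ConfigurationError):
            make_offspring_batch(
                pop.copy(), males, males, [SEX_MALE, SEX_MALE], 1, trait, rng
            )

    def test_bernoulli_sex_draws_match_binomial_oracle(self, rng):
        # callers draw offspring sex; check the Bernoulli(0.5) recipe itself
        n = 10_000
        sexes = np.where(rng.random(n) < 0.5, SEX_MALE, SEX_FEMALE)
        male_frac = (sexes == SEX_MALE).mean()
        se = np.sqrt(0.25 / n)
        assert male_frac == pytest.approx(0.5, abs=3 * se)

    def test_mendelian_consistency_of_offspring(self, tiny_founders, rng):
        pop, trait = tiny_founders
        pop = pop.copy()
        sires = np.nonzero(pop.sex == SEX_MALE)[0][:10]
        dams = np.nonzero(pop.sex == SEX_FEMALE)[0][:10]
        new = make_offspring_batch(
            pop, sires, dams, [SEX_MALE] * 10, 1, trait, rng
        )
        for k, row in enumerate(new):
            for h, par in ((0, sires[k]), (1, dams[k])):
                hap = pop.haps[row, h]
                ok = (hap == pop.haps[par, 0]) | (hap == pop.haps[par, 1])
                assert ok.all()


class TestTraitCalibration:
    def test_rescale_hits_genetic_variance_exactly(self, tiny_founders):
        pop, _ = tiny_founders
        assert pop.tbv.var(ddof=1) == pytest.approx(423_390.0, rel=1e-9)

    def test_rescale_is_scale_invariant(self, tiny_founders):
        pop, _ = tiny_founders
        pop = pop.copy()
        base = TraitModel(np.random.default_rng(7).standard_normal(pop.genome.n_qtl))
        doubled = TraitModel(2.0 * base.qtl_effects)
        t1 = assign_trait(pop, base, rescale=True)
        t2 = assign_trait(pop, doubled, rescale=True)
        np.testing.assert_allclose(t1.qtl_effects, t2.qtl_effects, rtol=1e-12)

    def test_monomorphic_qtl_raise(self, tiny_genome):
        from gsrefresh.synthpop import Population

        pop = Population(tiny_genome)
        haps = np.zeros((5, 2, tiny_genome.n_loci), np.uint8)
        pop._append(np.arange(1, 6), np.zeros(5), np.zeros(5),
                    np.zeros(5), np.zeros(5), haps)
        with pytest.raises(ConfigurationError):
            assign_trait(pop, TraitModel(np.ones(tiny_genome.n_qtl)))

    def test_realized_heritability_near_target(self, rng):
        g = GenomeSpec.default(n_chromosomes=3, n_markers_per_chrom=60,
                               n_qtl_per_chrom=10)
        pop = simulate_founders(g, 1000, 1000, 10, seed=5, burnin_size=200)
        trait = assign_trait(pop, TraitModel.draw(g, rng), rescale=True)
        assign_phenotypes(pop, np.arange(pop.n), trait, rng)
        h2 = pop.tbv.var(ddof=1) / pop.phenotype.var(ddof=1)
        assert h2 == pytest.approx(0.30, abs=0.05)


class TestDrift:
    def test_heterozygosity_decays_at_drift_rate(self):
        # random mating at N = 100 (50 + 50): E[H_t] = H_0 (1 - 1/(2N))^t
        g = GenomeSpec(
            2, 100.0,
            [np.linspace(1, 99, 100), np.linspace(1, 99, 100)],
            [[], []],
            founder_allele_freq_range=(0.5, 0.5),
        )
        n_reps, t, N = 20, 20, 100
        h0, ht = [], []
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            haps = (rng.random((N, 2, g.n_loci)) < 0.5).astype(np.uint8)
            h0.append((haps.sum(axis=1) == 1).mean())
            males, females = np.arange(50), np.arange(50, 100)
            for _ in range(t):
                haps = random_union_offspring(haps, males, females, N, g, rng)
            ht.append((haps.sum(axis=1) == 1).mean())
        h0, ht = np.asarray(h0), np.asarray(ht)
        expected = h0.mean() * (1 - 1 / (2 * N)) ** t
        se = ht.std(ddof=1) / np.sqrt(n_reps)
        assert ht.mean() == pytest.approx(expected, abs=3 * se)

    def test_pedigree_is_generation_ordered_after_simulation(self, tiny_founders, rng):
        pop, trait = tiny_founders
        pop = pop.copy()
        sires = np.nonzero(pop.sex == SEX_MALE)[0][:5]
        dams = np.nonzero(pop.sex == SEX_FEMALE)[0][:5]
        make_offspring_batch(pop, sires, dams, [SEX_FEMALE] * 5, 1, trait, rng)
        ped = pop.pedigree()  # Pedigree.__post_init__ validates ordering
        sidx, didx = ped.parent_indices()
        nonfounder = sidx >= 0
        assert np.all(
            ped.generation[nonfounder]
            > ped.generation[sidx[nonfounder]]
        )
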