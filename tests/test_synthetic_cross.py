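"""Tests for the haploid F2 cross and pooled-sequencing generator."""

import numpy as np
import pandas as pd
import pytest

from segscan.synthetic_cross import (
    Chromosome,
    CrossConfig,
    GenomeMap,
    assign_phenotype,
    assign_phenotypes,
    default_genome,
    sample_pool_reads,
    select_pools,
    simulate_f2_population,
    simulate_meiosis,
    simulate_pool_counts,
)

from _oracles import f2_two_locus_haplotype_probs, haldane


def _one_chromosome(n_markers, morgans=1.0, length=1_000_000):
    spacing = length // n_markers
    pos = np.arange(1, n_markers + 1) * spacing - spacing // 2
    return GenomeMap(
        chromosomes=(Chromosome("1", length, morgans),),
        markers={"1": pos},
    )


class TestGenomeMap:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomeMap(chromosomes=(), markers={})
        with pytest.raises(ValueError, match="strictly increasing"):
            GenomeMap(chromosomes=(Chromosome("1", 100, 1.0),),
                      markers={"1": np.array([10, 10])})
        with pytest.raises(ValueError, match="outside"):
            GenomeMap(chromosomes=(Chromosome("1", 100, 1.0),),
                      markers={"1": np.array([101])})

    def test_marker_index(self, small_genome):
        assert small_genome.marker_index("1", 100_000) == 0
        assert small_genome.marker_index("2", 900_000) == 9
        with pytest.raises(KeyError):
            small_genome.marker_index("1", 123)


class TestMeiosis:
    def test_zero_genetic_length_copies_whole_parent_per_chromosome(self, rng):
        gmap = GenomeMap(
            chromosomes=(Chromosome("1", 1000, 0.0), Chromosome("2", 1000, 0.0)),
            markers={"1": np.arange(1, 11) * 90, "2": np.arange(1, 11) * 90},
        )
        a = np.ones(20, bool)
        b = np.zeros(20, bool)
        for _ in range(20):
            child = simulate_meiosis(a, b, gmap, rng)
            for sl in gmap.marker_slices().values():
                assert child[sl].all() or not child[sl].any()

    def test_identical_parents_identical_offspring(self, rng, small_genome):
        parent = rng.random(10) < 0.5
        child = simulate_meiosis(parent, parent, small_genome, rng)
        assert np.array_equal(child, parent)

    def test_mismatched_parents_rejected(self, rng, small_genome):
        with pytest.raises(ValueError):
            simulate_meiosis(np.ones(3, bool), np.ones(10, bool), small_genome, rng)

    def test_switch_frequency_matches_haldane(self, rng):
        """Fully distinct parents, one 1-Morgan chromosome: the pooled
        frequency of parental-origin switches between adjacent markers
        equals the Haldane recombination fraction within 3 SE."""
        gmap = _one_chromosome(20, morgans=1.0)
        a = np.ones(20, bool)
        b = np.zeros(20, bool)
        n = 10_000
        children = np.stack([simulate_meiosis(a, b, gmap, rng) for _ in range(n)])
        switches = children[:, 1:] != children[:, :-1]
        spacing_bp = np.diff(gmap.markers["1"])
        d = spacing_bp / 1_000_000 * 1.0  # Morgans between adjacent markers
        r_expected = haldane(d[0])  # equal spacing
        n_pairs = switches.size
        r_observed = switches.mean()
        se = np.sqrt(r_expected * (1 - r_expected) / n_pairs)
        assert abs(r_observed - r_expected) < 3 * se


class TestF2Population:
    def test_unlinked_marker_segregates_one_to_one(self):
        config = CrossConfig(genome=_one_chromosome(5), n_f2=10_000, seed=3)
        pop = simulate_f2_population(config)
        freq = pop.mean(axis=0)
        se = np.sqrt(0.25 * (1 / config.n_f2 + 1 / config.n_f1))
        assert np.all(np.abs(freq - 0.5) < 3 * se)

    def test_fixed_seed_reproducible(self, small_genome):
        config = CrossConfig(genome=small_genome, n_f2=50, seed=11)
        assert np.array_equal(simulate_f2_population(config), simulate_f2_population(config))
        other = CrossConfig(genome=small_genome, n_f2=50, seed=12)
        assert not np.array_equal(simulate_f2_population(config), simulate_f2_population(other))

    def test_two_locus_haplotypes_match_haldane_expectation(self):
        """Markers 1 cM apart: F2 haplotype frequencies follow the
        closed-form no-interference expectation.  The SE accounts for both
        the F2 draw and sampling through the finite F1 pool."""
        length = 1_000_000
        gmap = GenomeMap(
            chromosomes=(Chromosome("1", length, 1.0),),
            markers={"1": np.array([500_000, 510_000])},
        )
        n_f2, n_f1 = 100_000, 20_000
        config = CrossConfig(genome=gmap, n_f2=n_f2, n_f1=n_f1, seed=5)
        pop = simulate_f2_population(config)
        r = haldane(0.01)
        expected = f2_two_locus_haplotype_probs(r)
        observed = {
            "MM": (pop[:, 0] & pop[:, 1]).mean(),
            "UU": (~pop[:, 0] & ~pop[:, 1]).mean(),
            "MU": (pop[:, 0] & ~pop[:, 1]).mean(),
            "UM": (~pop[:, 0] & pop[:, 1]).mean(),
        }
        for hap, p in expected.items():
            se = np.sqrt(p * (1 - p) * (1 / n_f2 + 1 / n_f1))
            assert abs(observed[hap] - p) < 3 * se, hap


class TestPhenotypeAndPools:
    def _config(self, model="ALL"):
        gmap = _one_chromosome(5)
        loci = (("1", int(gmap.markers["1"][1])), ("1", int(gmap.markers["1"][3])))
        return CrossConfig(genome=gmap, causal_loci=loci, phenotype_model=model)

    def test_all_model_rules(self):
        config = self._config("ALL")
        g = np.zeros(5, bool)
        g[[1, 3]] = True
        assert assign_phenotype(g, config) == "multicellular"
        g[3] = False
        assert assign_phenotype(g, config) == "unicellular"

    def test_any_model_rules(self):
        config = self._config("ANY")
        g = np.zeros(5, bool)
        g[1] = True
        assert assign_phenotype(g, config) == "multicellular"

    def test_causal_locus_off_marker_rejected(self):
        with pytest.raises(KeyError):
            CrossConfig(genome=_one_chromosome(5), causal_loci=(("1", 123),))

    def test_perfect_sorting_partitions_by_phenotype(self, rng):
        phen = np.array(["unicellular", "multicellular"] * 50)
        pool_u, pool_m = select_pools(phen, 0.0, rng)
        assert np.array_equal(pool_u, np.arange(0, 100, 2))
        assert np.array_equal(pool_m, np.arange(1, 100, 2))

    def test_uninformative_sorting_mixes_pools(self, rng):
        """epsilon = 0.5: pool membership is independent of phenotype, so
        causal-allele frequencies agree between pools within 3 SE."""
        config = CrossConfig(
            genome=_one_chromosome(5),
            causal_loci=(("1", int(_one_chromosome(5).markers["1"][2])),),
            n_f2=10_000, seed=21,
        )
        pop = simulate_f2_population(config)
        phen = assign_phenotypes(pop, config)
        pool_u, pool_m = select_pools(phen, 0.5, rng)
        ci = config.causal_indices()[0]
        f_u = pop[pool_u, ci].mean()
        f_m = pop[pool_m, ci].mean()
        se = np.sqrt(0.25 * (1 / len(pool_u) + 1 / len(pool_m)))
        assert abs(f_u - f_m) < 3 * se

    def test_misclassified_pool_frequency_matches_conditional_formula(self, rng):
        """epsilon = 0.1, ALL model: the derived-allele frequency at a
        causal locus in pool M matches the mixture implied by the realised
        phenotype-class frequencies and epsilon, within 3 SE of the
        sorting randomness."""
        eps = 0.1
        config = self._config("ALL")
        config = CrossConfig(genome=config.genome, causal_loci=config.causal_loci,
                             phenotype_model="ALL", n_f2=10_000, seed=9)
        pop = simulate_f2_population(config)
        phen = assign_phenotypes(pop, config)
        ci = config.causal_indices()[0]
        is_multi = phen == "multicellular"
        n_multi, n_uni = is_multi.sum(), (~is_multi).sum()
        f_multi = pop[is_multi, ci].mean()     # = 1 under the ALL model
        f_uni = pop[~is_multi, ci].mean()
        # expected pool-M composition: (1-eps) of multis, eps of unis
        w_multi = (1 - eps) * n_multi
        w_uni = eps * n_uni
        f_expected = (w_multi * f_multi + w_uni * f_uni) / (w_multi + w_uni)
        pool_u, pool_m = select_pools(phen, eps, rng)
        f_observed = pop[pool_m, ci].mean()
        # dominant noise: which individuals land in pool M (Bernoulli eps)
        se = np.sqrt(f_expected * (1 - f_expected) / len(pool_m))
        assert abs(f_observed - f_expected) < 3 * se


class TestPoolReads:
    def test_monomorphic_pool_no_errors(self, rng):
        gmap = _one_chromosome(10)
        pop = np.ones((20, 10), bool)
        ref, alt = sample_pool_reads(np.arange(20), pop, gmap, 50.0, 0.0, rng)
        assert (ref == 0).all()
        depth = ref + alt
        assert np.array_equal(alt, depth)

    def test_saturated_error_rate_invalid(self):
        """Per-read error is capped at 5%; 0.5 is outside the model."""
        with pytest.raises(ValueError):
            CrossConfig(genome=_one_chromosome(5), seq_error_rate=0.5)

    def test_saturated_error_gives_half_alt_fraction(self, rng):
        """e = 0.5 (called directly): expected alt fraction 1/2 regardless
        of pool composition."""
        gmap = _one_chromosome(2000, length=2_000_000)
        pop = np.ones((10, 2000), bool)  # pool fixed for alt
        ref, alt = sample_pool_reads(np.arange(10), pop, gmap, 100.0, 0.5, rng)
        frac = alt.sum() / (ref + alt).sum()
        se = np.sqrt(0.25 / (ref + alt).sum())
        assert abs(frac - 0.5) < 3 * se

    def test_observed_alt_fraction_matches_closed_form(self, rng):
        """lambda = 150, e = 0.01: mean observed alt fraction over many
        SNPs is f(1-e) + (1-f)e within 3 SE."""
        n_snps, f, e = 10_000, 0.3, 0.01
        spacing = 100
        gmap = GenomeMap(
            chromosomes=(Chromosome("1", n_snps * spacing, 1.0),),
            markers={"1": np.arange(1, n_snps + 1) * spacing},
        )
        pool = np.arange(10)
        pop = np.zeros((10, n_snps), bool)
        pop[:3] = True  # pool frequency exactly 0.3 at every SNP
        ref, alt = sample_pool_reads(pool, pop, gmap, 150.0, e, rng)
        expected = f * (1 - e) + (1 - f) * e
        total = (ref + alt).sum()
        frac = alt.sum() / total
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(frac - expected) < 3 * se

    def test_empty_pool_rejected(self, rng):
        gmap = _one_chromosome(5)
        with pytest.raises(ValueError, match="empty pool"):
            sample_pool_reads(np.array([], dtype=int), np.zeros((5, 5), bool),
                              gmap, 10.0, 0.0, rng)


class TestEndToEndGeneration:
    def test_deterministic_output_tables(self):
        config = CrossConfig(genome=default_genome(3, 5), n_f2=200, seed=42,
                             causal_loci=(("2", 500_000),))
        c1, t1 = simulate_pool_counts(config)
        c2, t2 = simulate_pool_counts(config)
        pd.testing.assert_frame_equal(c1, c2)
        assert t1 == t2

    def test_truth_ledger_contents(self):
        config = CrossConfig(genome=default_genome(3, 5), n_f2=200, seed=1,
                             causal_loci=(("2", 500_000),))
        counts, truth = simulate_pool_counts(config)
        assert truth["causal_loci"] == [("2", 500_000)]
        assert truth["n_f2"] == 200 and truth["seed"] == 1
        assert len(truth["pool_U_ids"]) + len(truth["pool_M_ids"]) == 200
        assert len(truth["freq_U"]) == config.genome.n_markers
        assert list(counts.columns) == [
            "chrom", "pos", "ref", "alt", "refU", "altU", "refM", "altM", "alt_origin"
        ]

    def test_unlinked_markers_near_half_frequency_in_pool_union(self):
        """Mendelian sanity: pooled allele frequency at non-causal unlinked
        markers is ~0.5 in the union of pools."""
        config = CrossConfig(genome=default_genome(4, 10), n_f2=10_000, seed=13,
                             causal_loci=(("1", 450_000),), pool_depth=(150.0, 130.0))
        counts, _ = simulate_pool_counts(config)
        other = counts[counts["chrom"] != "1"]
        k = (other["altU"] + other["altM"]).to_numpy()
        n = k + (other["refU"] + other["refM"]).to_numpy()
        # pooled read frequency averaged over markers; noise dominated by
        # the finite F2/F1 population shared across markers
        f = (k / n).mean()
        se = np.sqrt(0.25 * (1 / config.n_f2 + 1 / config.n_f1))
        assert abs(f - 0.5) < 3 * se

    def test_growth_locus_biases_pool_frequencies(self):
        """With a strong growth advantage at a designated locus, carriers
        are over-sampled in both pools relative to the neutral run."""
        gmap = default_genome(2, 10)
        base = dict(genome=gmap, n_f2=4000, seed=77)
        neutral, _ = simulate_pool_counts(CrossConfig(**base))
        biased, _ = simulate_pool_counts(CrossConfig(
            **base, growth_locus=("1", 450_000), growth_advantage=5.0))
        i = gmap.marker_index("1", 450_000)
        f_neutral = (neutral["altU"] + neutral["altM"]) / (
            neutral[["refU", "altU", "refM", "altM"]].sum(axis=1))
        f_biased = (biased["altU"] + biased["altM"]) / (
            biased[["refU", "altU", "refM", "altM"]].sum(axis=1))
        assert f_biased[i] > f_neutral[i] + 0.1
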