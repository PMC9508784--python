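"""Unit and property tests for the F2 cross + pooled sequencing generator."""

import numpy as np
import pytest
from scipy import stats

from bulkscan.io import read_allele_depths, write_allele_depths
from bulkscan.simulate import (
    CrossConfig, DiagnosticIndel, F2Individual, GenomeModel, WEEPING, STANDARD,
    build_variant_sites, bulk_allele_frequencies, embed_diagnostic_indel,
    haldane_recombination_fraction, indel_dosages, indel_marker_codes,
    make_bulks, simulate_f2_population, simulate_parent_reads,
    simulate_pool_reads, _simulate_gametes,
)


# ---------------------------------------------------------------------------
# meiosis model
# ---------------------------------------------------------------------------

def test_zero_recombination_limit_gives_constant_chromosomes():
    """With vanishing map distance every chromosome is inherited whole."""
    genome = GenomeModel.default(n_chrom=1, length=1_000_000,
                                 marker_spacing=10_000, cm_per_mb=1e-12)
    config = CrossConfig(n_f2=50, bulk_size=5, causal_chrom="chr1",
                         causal_pos=500_000, seed=3)
    for ind in simulate_f2_population(genome, config):
        g = ind.genotype["chr1"]
        assert np.all(g == g[0])


def test_phenotype_is_recessive_at_causal_locus(toy_cross):
    genome, config, population = toy_cross
    for ind in population:
        causal = ind.causal_genotype(config.causal_chrom, config.causal_pos,
                                     genome)
        assert (ind.phenotype == WEEPING) == (causal == 2)


def test_segregation_close_to_3_to_1_across_seeds():
    """A 395-plant F2 passes the 1:3 chi-square check in >= 90% of seeds."""
    genome = GenomeModel.default(n_chrom=1, length=200_000,
                                 marker_spacing=100_000, cm_per_mb=4.0)
    ok = 0
    n_seeds = 30
    for seed in range(n_seeds):
        config = CrossConfig(n_f2=395, bulk_size=15, causal_chrom="chr1",
                             causal_pos=100_000, seed=seed)
        population = simulate_f2_population(genome, config)
        n_weep = sum(ind.phenotype == WEEPING for ind in population)
        _, p = stats.chisquare([n_weep, 395 - n_weep],
                               [395 * 0.25, 395 * 0.75])
        ok += p > 0.05
    assert ok >= 0.9 * n_seeds


def test_unlinked_marker_segregates_1_2_1():
    """Genotypes at a marker on another chromosome follow 1:2:1."""
    genome = GenomeModel(
        chromosomes=(("chr1", 200_000), ("chr2", 200_000)),
        marker_positions={"chr1": np.array([100_000]),
                          "chr2": np.array([100_000])},
        cm_per_mb=4.0,
    )
    config = CrossConfig(n_f2=10_000, bulk_size=10, causal_chrom="chr1",
                         causal_pos=100_000, seed=11)
    population = simulate_f2_population(genome, config)
    g = np.array([ind.genotype["chr2"][0] for ind in population])
    n = len(g)
    for dosage, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
        observed = np.mean(g == dosage)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se


def test_recombination_fraction_recovers_haldane_map():
    """Gamete phase switches between markers match r = (1-e^{-2d/100})/2."""
    rng = np.random.default_rng(5)
    positions = np.array([1, 2_000_001, 7_000_001])  # 8 cM and 20 cM gaps
    phases = _simulate_gametes(rng, positions, 10_000, cm_per_mb=4.0)
    for gap, d_cm in ((0, 8.0), (1, 20.0)):
        expected = haldane_recombination_fraction(d_cm)
        observed = np.mean(phases[:, gap] != phases[:, gap + 1])
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * se


def test_causal_position_must_be_a_marker(toy_genome):
    config = CrossConfig(n_f2=10, bulk_size=2, causal_chrom="chr1",
                         causal_pos=123_456, seed=0)
    with pytest.raises(ValueError, match="not a marker"):
        simulate_f2_population(toy_genome, config)


def test_invalid_population_size_rejected():
    with pytest.raises(ValueError):
        CrossConfig(n_f2=0, bulk_size=0)


# ---------------------------------------------------------------------------
# bulking
# ---------------------------------------------------------------------------

def _force_population(n_weep, n_std, genome):
    pop = []
    for _ in range(n_weep):
        pop.append(F2Individual(
            genotype={"chr1": np.full(len(genome.marker_positions["chr1"]), 2)},
            phenotype=WEEPING))
    for _ in range(n_std):
        pop.append(F2Individual(
            genotype={"chr1": np.zeros(len(genome.marker_positions["chr1"]),
                                       dtype=int)},
            phenotype=STANDARD))
    return pop


def test_bulk_is_forced_when_class_exactly_fits():
    genome = GenomeModel.default(n_chrom=1, length=100_000,
                                 marker_spacing=50_000)
    pop = _force_population(15, 40, genome)
    for seed in (0, 1, 99):
        weeping_bulk, _ = make_bulks(pop, 15, seed)
        assert set(map(id, weeping_bulk)) == set(map(id, pop[:15]))


def test_bulk_deficit_error_names_shortfall():
    genome = GenomeModel.default(n_chrom=1, length=100_000,
                                 marker_spacing=50_000)
    pop = _force_population(3, 40, genome)
    with pytest.raises(ValueError, match="short by 12"):
        make_bulks(pop, 15, seed=0)


def test_weeping_bulk_fixed_for_mutant_allele(toy_cross):
    genome, config, population = toy_cross
    weeping_bulk, _ = make_bulks(population, config.bulk_size, seed=1)
    freqs = bulk_allele_frequencies(weeping_bulk, genome)
    idx = np.searchsorted(genome.marker_positions["chr1"], config.causal_pos)
    assert freqs["chr1"][idx] == 1.0


def test_standard_bulk_causal_frequency_averages_one_third():
    """E[f] over the AA:Aa = 1:2 truncated F2 distribution is 1/3."""
    genome = GenomeModel.default(n_chrom=1, length=200_000,
                                 marker_spacing=100_000)
    rng = np.random.default_rng(123)
    freqs = []
    for _ in range(1000):
        # standard-class causal dosage: 0 w.p. 1/3, 1 w.p. 2/3
        dosages = rng.choice([0, 1], size=15, p=[1 / 3, 2 / 3])
        bulk = [F2Individual(genotype={"chr1": np.array([d, d])},
                             phenotype=STANDARD) for d in dosages]
        freqs.append(bulk_allele_frequencies(bulk, genome)["chr1"][0])
    freqs = np.asarray(freqs)
    se = freqs.std(ddof=1) / np.sqrt(len(freqs))
    assert abs(freqs.mean() - 1 / 3) < 3 * se


# ---------------------------------------------------------------------------
# pooled read sampling
# ---------------------------------------------------------------------------

def _uniform_bulk(genome, dosage, n=10):
    m = len(genome.marker_positions["chr1"])
    return [F2Individual(genotype={"chr1": np.full(m, dosage)},
                         phenotype=WEEPING if dosage == 2 else STANDARD)
            for _ in range(n)]


def test_pool_reads_all_mutant_when_fixed_and_error_free():
    genome = GenomeModel.default(n_chrom=1, length=1_000_000,
                                 marker_spacing=10_000)
    depth, mutant = simulate_pool_reads(_uniform_bulk(genome, 2), genome,
                                        depth_mean=50, error_rate=0.0,
                                        seed=0)["chr1"]
    assert np.array_equal(depth, mutant)


def test_pool_reads_no_mutant_when_absent_and_error_free():
    genome = GenomeModel.default(n_chrom=1, length=1_000_000,
                                 marker_spacing=10_000)
    _, mutant = simulate_pool_reads(_uniform_bulk(genome, 0), genome,
                                    depth_mean=50, error_rate=0.0,
                                    seed=0)["chr1"]
    assert np.all(mutant == 0)


def test_pool_reads_mean_index_matches_binomial_expectation():
    """Observed index over 10,000 sites at f = 1/3 averages 1/3."""
    genome = GenomeModel.default(n_chrom=1, length=100_000_000,
                                 marker_spacing=10_000)
    m = len(genome.marker_positions["chr1"])
    assert m == 10_000
    bulk = [F2Individual(genotype={"chr1": np.full(m, d)}, phenotype=STANDARD)
            for d in (0, 1, 1)]   # pool frequency exactly 1/3 everywhere
    depth, mutant = simulate_pool_reads(bulk, genome, depth_mean=100,
                                        error_rate=0.0, seed=2)["chr1"]
    covered = depth > 0
    index = mutant[covered] / depth[covered]
    se = index.std(ddof=1) / np.sqrt(covered.sum())
    assert abs(index.mean() - 1 / 3) < 3 * se


def test_pool_reads_depth_bounds_and_determinism(toy_cross):
    genome, config, population = toy_cross
    bulk, _ = make_bulks(population, config.bulk_size, seed=0)
    a = simulate_pool_reads(bulk, genome, 30, 0.001, seed=9)
    b = simulate_pool_reads(bulk, genome, 30, 0.001, seed=9)
    for chrom in a:
        depth, mutant = a[chrom]
        assert np.all((0 <= mutant) & (mutant <= depth))
        assert np.array_equal(depth, b[chrom][0])
        assert np.array_equal(mutant, b[chrom][1])


def test_same_seed_gives_byte_identical_tables(tmp_path, toy_cross):
    genome, config, population = toy_cross
    paths = []
    for run in ("a", "b"):
        pl_bulk, st_bulk = make_bulks(population, config.bulk_size, seed=4)
        parent = simulate_parent_reads(genome, 40, 0.001, seed=5)
        st = simulate_pool_reads(st_bulk, genome, 40, 0.001, seed=6)
        pl = simulate_pool_reads(pl_bulk, genome, 40, 0.001, seed=7)
        sites = build_variant_sites(genome, parent, st, pl, seed=8)
        path = tmp_path / f"{run}.tsv"
        write_allele_depths(sites, path, format="tsv")
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


# ---------------------------------------------------------------------------
# diagnostic indel embedding
# ---------------------------------------------------------------------------

def test_indel_dosage_maps_causal_genotypes_through_haplotype_rule():
    """On a 6-plant toy population the dosage is 2 - causal dosage."""
    genome = GenomeModel.default(n_chrom=1, length=100_000,
                                 marker_spacing=50_000)
    pop = [F2Individual(genotype={"chr1": np.array([d, d])},
                        phenotype=WEEPING if d == 2 else STANDARD)
           for d in (0, 0, 1, 1, 2, 2)]
    indel = DiagnosticIndel(chrom="chr1", pos=75_000, deleted_length=35)
    dosage = indel_dosages(pop, indel, "chr1", 50_000, genome)
    assert dosage.tolist() == [2, 2, 1, 1, 0, 0]


def test_weeping_individuals_homozygous_for_non_deleted_allele(toy_cross):
    genome, config, population = toy_cross
    indel = DiagnosticIndel(chrom="chr1", pos=1_005_000)
    codes = indel_marker_codes(population, indel, config.causal_chrom,
                               config.causal_pos, genome)
    for ind, code in zip(population, codes):
        if ind.phenotype == WEEPING:
            assert code == "B"   # hom for the long (non-deleted) allele


def test_embedded_indel_round_trips_and_rejects_collisions(tmp_path, toy_cross):
    genome, config, population = toy_cross
    pl_bulk, st_bulk = make_bulks(population, config.bulk_size, seed=1)
    parent = simulate_parent_reads(genome, 60, 0.0, seed=2)
    st = simulate_pool_reads(st_bulk, genome, 60, 0.0, seed=3)
    pl = simulate_pool_reads(pl_bulk, genome, 60, 0.0, seed=4)
    sites = build_variant_sites(genome, parent, st, pl, seed=5)
    indel = DiagnosticIndel(chrom="chr1", pos=1_005_000, deleted_length=35)
    embedded = embed_diagnostic_indel(sites, indel, pl_bulk, st_bulk,
                                      "chr1", config.causal_pos, genome,
                                      depth_mean=60, error_rate=0.0, seed=6)
    assert len(embedded) == len(sites) + 1

    for fmt in ("tsv", "vcf"):
        path = tmp_path / f"sites.{fmt}"
        write_allele_depths(embedded, path, format=fmt,
                            contig_lengths=genome.chrom_lengths)
        back = read_allele_depths(path)
        indels = [s for s in back if s.kind == "indel"]
        assert len(indels) == 1 and indels[0].length_difference == 35

    with pytest.raises(ValueError, match="collides"):
        embed_diagnostic_indel(sites, DiagnosticIndel(chrom="chr1", pos=50_000),
                               pl_bulk, st_bulk, "chr1", config.causal_pos,
                               genome, 60, 0.0, seed=6)


def test_population_phenotype_frequency_converges_to_quarter():
    genome = GenomeModel.default(n_chrom=1, length=200_000,
                                 marker_spacing=100_000)
    config = CrossConfig(n_f2=10_000, bulk_size=10, causal_chrom="chr1",
                         causal_pos=100_000, seed=21)
    population = simulate_f2_population(genome, config)
    n_weep = sum(ind.phenotype == WEEPING for ind in population)
    assert stats.binomtest(n_weep, 10_000, 0.25).pvalue > 0.001
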