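"""Synthetic F2 cross and pooled-sequencing generator.

Models the study design the scan assumes: an F2 population derived from
selfing a heterozygous F1, segregating 3:1 (standard : weeping) for a
single recessive locus; two phenotype-selected bulks of ~15 individuals
each; and pooled short-read sequencing of each bulk at ~100-fold depth
with a small symmetric allele-flip error.

Meiosis follows a Markov walk along ordered markers where the phase-switch
probability between adjacent markers is the Haldane recombination fraction

    r = (1/2) * (1 - exp(-2 d / 100)),   d = inter-marker distance in cM,

i.e. crossovers occur without interference.  All operations take an
explicit ``seed`` and build one :class:`numpy.random.Generator` per call,
so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import VariantSite

WEEPING = "weeping"
STANDARD = "standard"


@dataclass(frozen=True)
class GenomeModel:
    """Marker map of the synthetic genome.

    ``chromosomes``: list of (name, length in bp).
    ``marker_positions``: per-chromosome sorted 1-based bp positions of
    segregating SNPs.  ``cm_per_mb``: uniform recombination rate.
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_positions: dict[str, np.ndarray]
    cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")
        lengths = dict(self.chromosomes)
        if set(self.marker_positions) - set(lengths):
            raise ValueError("marker_positions name an unknown chromosome")
        converted = {}
        for name, pos in self.marker_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{name}: positions must be strictly increasing")
            if len(pos) and (pos[0] < 1 or pos[-1] > lengths[name]):
                raise ValueError(f"{name}: positions outside [1, {lengths[name]}]")
            converted[name] = pos
        object.__setattr__(self, "marker_positions", converted)
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @classmethod
    def default(cls, n_chrom: int = 2, length: int = 25_000_000,
                marker_spacing: int = 10_000, cm_per_mb: float = 4.0) -> "GenomeModel":
        """Desk-scale genome: 2 chromosomes of 25 Mb, markers every 10 kb.

        Large enough to exercise 1 Mb windowing, small enough for quick
        simulation; a full plant-genome scale is reachable by arguments.
        """
        chroms = tuple((f"chr{i + 1}", length) for i in range(n_chrom))
        positions = {
            name: np.arange(marker_spacing, length + 1, marker_spacing, dtype=np.int64)
            for name, _ in chroms
        }
        return cls(chromosomes=chroms, marker_positions=positions, cm_per_mb=cm_per_mb)


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross and pooled sequencing.

    Defaults mirror the study design: 395 F2 individuals, bulks of 15,
    ~100-fold pooled depth, sequencing error 1e-3, error-free phenotyping.
    """

    n_f2: int = 395
    bulk_size: int = 15
    causal_chrom: str = "chr1"
    causal_pos: int = 12_500_000
    depth_mean: float = 100.0
    error_rate: float = 0.001
    phenotype_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if 2 * self.bulk_size > self.n_f2:
            raise ValueError("2 * bulk_size must not exceed n_f2")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 <= self.phenotype_error <= 1):
            raise ValueError("phenotype_error must be in [0, 1]")


@dataclass(frozen=True)
class DiagnosticIndel:
    """A deletion that co-segregates perfectly with the causal locus.

    ``carrier_haplotype`` names the parental haplotype that LACKS the
    segment.  The default models the diagnostic marker of the weeping
    cross: a 35 bp deletion carried on the standard (non-weeping)
    haplotype, so weeping individuals are homozygous for the non-deleted
    allele.
    """

    chrom: str = "chr1"
    pos: int = 12_505_000
    deleted_length: int = 35
    carrier_haplotype: str = STANDARD

    def __post_init__(self) -> None:
        if self.deleted_length <= 0:
            raise ValueError("deleted_length must be > 0")
        if self.carrier_haplotype not in (STANDARD, WEEPING):
            raise ValueError("carrier_haplotype must be 'standard' or 'weeping'")


@dataclass
class F2Individual:
    """One F2 plant: per-marker mutant-allele dosage and its phenotype.

    ``genotype[chrom][i]`` counts copies (0/1/2) of the mutant
    (weeping-derived) allele at the i-th marker of ``chrom``.
    """

    genotype: dict[str, np.ndarray]
    phenotype: str

    def causal_genotype(self, chrom: str, pos: int, genome: GenomeModel) -> int:
        idx = _marker_index(genome, chrom, pos)
        return int(self.genotype[chrom][idx])


def _marker_index(genome: GenomeModel, chrom: str, pos: int) -> int:
    positions = genome.marker_positions.get(chrom)
    if positions is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    idx = int(np.searchsorted(positions, pos))
    if idx >= len(positions) or positions[idx] != pos:
        raise ValueError(f"position {chrom}:{pos} is not a marker")
    return idx


def haldane_recombination_fraction(d_cm) -> np.ndarray:
    """Map genetic distance (cM) to recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _simulate_gametes(rng, positions: np.ndarray, n_gametes: int,
                      cm_per_mb: float) -> np.ndarray:
    """(n_gametes, n_markers) 0/1 phases; 1 = mutant parental haplotype."""
    m = len(positions)
    start = rng.integers(0, 2, size=(n_gametes, 1))
    if m == 1:
        return start
    d_cm = np.diff(positions) / 1e6 * cm_per_mb
    r = haldane_recombination_fraction(d_cm)
    switches = rng.random((n_gametes, m - 1)) < r
    return (start + np.concatenate(
        [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switches, axis=1)],
        axis=1)) % 2


def simulate_f2_population(genome: GenomeModel, config: CrossConfig
                           ) -> list[F2Individual]:
    """Simulate the F2 offspring of a selfed heterozygous F1.

    Each individual is the fusion of two independent gametes; each gamete
    is a Haldane Markov walk along the marker map.  Phenotype is weeping
    iff the individual carries two mutant alleles at the causal locus
    (recessive rule), optionally misclassified at ``phenotype_error``.
    """
    causal_idx = _marker_index(genome, config.causal_chrom, config.causal_pos)
    rng = np.random.default_rng(config.seed)
    n = config.n_f2
    genotypes: dict[str, np.ndarray] = {}
    for name, _ in genome.chromosomes:
        positions = genome.marker_positions[name]
        if len(positions) == 0:
            genotypes[name] = np.zeros((n, 0), dtype=np.int64)
            continue
        phases = _simulate_gametes(rng, positions, 2 * n, genome.cm_per_mb)
        genotypes[name] = phases[0::2] + phases[1::2]

    causal = genotypes[config.causal_chrom][:, causal_idx]
    weeping = causal == 2
    if config.phenotype_error > 0:
        flip = rng.random(n) < config.phenotype_error
        weeping = weeping ^ flip
    return [
        F2Individual(
            genotype={name: genotypes[name][i] for name, _ in genome.chromosomes},
            phenotype=WEEPING if weeping[i] else STANDARD,
        )
        for i in range(n)
    ]


def make_bulks(population: Sequence[F2Individual], bulk_size: int, seed
               ) -> tuple[list[F2Individual], list[F2Individual]]:
    """Draw the two phenotype-selected bulks.

    Uniform random subsets without replacement of each phenotype class,
    mimicking the equal-amount pooling of selected plants.  Returns
    (weeping_bulk, standard_bulk).
    """
    rng = np.random.default_rng(seed)
    bulks = []
    for phenotype in (WEEPING, STANDARD):
        members = [ind for ind in population if ind.phenotype == phenotype]
        if len(members) < bulk_size:
            raise ValueError(
                f"need {bulk_size} {phenotype} individuals, found {len(members)} "
                f"(short by {bulk_size - len(members)})"
            )
        pick = rng.choice(len(members), size=bulk_size, replace=False)
        bulks.append([members[i] for i in sorted(pick)])
    return bulks[0], bulks[1]


def bulk_allele_frequencies(bulk: Sequence[F2Individual], genome: GenomeModel
                            ) -> dict[str, np.ndarray]:
    """True mutant-allele frequency of the pooled DNA, per marker."""
    freqs = {}
    for name, _ in genome.chromosomes:
        stacked = np.stack([ind.genotype[name] for ind in bulk])
        freqs[name] = stacked.sum(axis=0) / (2.0 * len(bulk))
    return freqs


def _sample_reads(freqs: dict[str, np.ndarray], depth_mean: float,
                  error_rate: float, rng) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (total_depth, mutant_read_count) arrays."""
    out = {}
    for name, f in freqs.items():
        depth = rng.poisson(depth_mean, size=len(f))
        f_obs = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        mutant = rng.binomial(depth, f_obs)
        out[name] = (depth, mutant)
    return out


def simulate_pool_reads(bulk: Sequence[F2Individual], genome: GenomeModel,
                        depth_mean: float, error_rate: float, seed
                        ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pooled sequencing of one bulk.

    Per site the total depth is Poisson(``depth_mean``) and the
    mutant-read count is Binomial(depth, f') with
    f' = f(1 - e) + (1 - f)e, where f is the bulk's true mutant-allele
    frequency and e the symmetric allele-flip error.  Returns per
    chromosome the (total_depth, mutant_count) arrays, ordered as the
    genome's markers.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = np.random.default_rng(seed)
    return _sample_reads(bulk_allele_frequencies(bulk, genome), depth_mean,
                         error_rate, rng)


def simulate_parent_reads(genome: GenomeModel, depth_mean: float,
                          error_rate: float, seed
                          ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sequencing of the heterozygous (Aa) parent: true frequency 1/2 everywhere."""
    rng = np.random.default_rng(seed)
    freqs = {name: np.full(len(p), 0.5) for name, p in genome.marker_positions.items()}
    return _sample_reads(freqs, depth_mean, error_rate, rng)


_BASES = np.array(list("ACGT"))


def build_variant_sites(genome: GenomeModel,
                        parent_reads, st_reads, pl_reads, seed) -> list[VariantSite]:
    """Assemble per-sample read counts into biallelic SNP records.

    The mutant allele is assigned to REF or ALT uniformly at random per
    site (seeded), so downstream orientation is actually exercised rather
    than trivially reading the ALT column.
    """
    rng = np.random.default_rng(seed)
    sites: list[VariantSite] = []
    for name, _ in genome.chromosomes:
        positions = genome.marker_positions[name]
        m = len(positions)
        if m == 0:
            continue
        base_idx = rng.integers(0, 4, size=m)
        alt_off = rng.integers(1, 4, size=m)
        mutant_is_alt = rng.random(m) < 0.5
        for i in range(m):
            ref = _BASES[base_idx[i]]
            alt = _BASES[(base_idx[i] + alt_off[i]) % 4]
            depths = {}
            for key, table in (("parent", parent_reads), ("st", st_reads),
                               ("pl", pl_reads)):
                depth, mutant = table[name]
                d, mut = int(depth[i]), int(mutant[i])
                if d == 0:
                    depths[key] = None
                elif mutant_is_alt[i]:
                    depths[key] = (d - mut, mut)
                else:
                    depths[key] = (mut, d - mut)
            sites.append(VariantSite(chrom=name, pos=int(positions[i]),
                                     ref=str(ref), alt=str(alt), **depths))
    return sites


def indel_dosages(population: Sequence[F2Individual], indel: DiagnosticIndel,
                  causal_chrom: str, causal_pos: int, genome: GenomeModel
                  ) -> np.ndarray:
    """Copies of the DELETED allele per individual.

    The deletion rides one parental haplotype, so the dosage is a direct
    map of the causal genotype: carried on the standard haplotype it is
    2 - (mutant copies), carried on the weeping haplotype it equals them.
    """
    causal = np.array([
        ind.causal_genotype(causal_chrom, causal_pos, genome) for ind in population
    ])
    return 2 - causal if indel.carrier_haplotype == STANDARD else causal


def indel_marker_codes(population: Sequence[F2Individual], indel: DiagnosticIndel,
                       causal_chrom: str, causal_pos: int, genome: GenomeModel
                       ) -> list[str]:
    """Genotype codes for the indel assay, B = hom for the weeping-linked allele.

    In gel terms: single short band = hom deleted, single long band = hom
    non-deleted, two bands = heterozygous.
    """
    dosage = indel_dosages(population, indel, causal_chrom, causal_pos, genome)
    weeping_linked_copies = (
        2 - dosage if indel.carrier_haplotype == STANDARD else dosage
    )
    return [{0: "A", 1: "H", 2: "B"}[int(c)] for c in weeping_linked_copies]


def embed_diagnostic_indel(sites: list[VariantSite], indel: DiagnosticIndel,
                           weeping_bulk: Sequence[F2Individual],
                           standard_bulk: Sequence[F2Individual],
                           causal_chrom: str, causal_pos: int,
                           genome: GenomeModel, depth_mean: float,
                           error_rate: float, seed) -> list[VariantSite]:
    """Insert a perfectly linked indel record into an allele-depth table.

    The REF allele carries the extra ``deleted_length`` bases, the ALT
    allele lacks them.  Pool read counts are drawn with the same
    Poisson/binomial model as SNP sites, from each bulk's true
    deleted-allele frequency; the parent is heterozygous.
    """
    if indel.chrom not in genome.chrom_lengths:
        raise ValueError(f"indel chromosome {indel.chrom!r} not in genome")
    if indel.pos > genome.chrom_lengths[indel.chrom]:
        raise ValueError("indel position beyond chromosome end")
    if any(s.chrom == indel.chrom and s.pos == indel.pos for s in sites):
        raise ValueError(
            f"indel position {indel.chrom}:{indel.pos} collides with an existing site"
        )
    rng = np.random.default_rng(seed)
    ref = "A" + "C" * indel.deleted_length   # long, non-deleted allele
    alt = "A"                                 # deleted allele

    depths = {}
    freq_del = {
        "pl": indel_dosages(weeping_bulk, indel, causal_chrom, causal_pos,
                            genome).sum() / (2.0 * len(weeping_bulk)),
        "st": indel_dosages(standard_bulk, indel, causal_chrom, causal_pos,
                            genome).sum() / (2.0 * len(standard_bulk)),
        "parent": 0.5,
    }
    for key in ("parent", "st", "pl"):
        depth = int(rng.poisson(depth_mean))
        f = freq_del[key] * (1 - error_rate) + (1 - freq_del[key]) * error_rate
        n_del = int(rng.binomial(depth, f))
        depths[key] = None if depth == 0 else (depth - n_del, n_del)

    record = VariantSite(chrom=indel.chrom, pos=indel.pos, ref=ref, alt=alt,
                         **depths)
    out = sites + [record]
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out
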