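"""End-to-end orchestration: simulate → index → scan → segtest → marker.

A run is fully described by a :class:`RunConfig`; every stage draws its
seed deterministically from the run seed, the configuration is echoed to
``manifest.yaml``, and all stage outputs land in the run directory, so a
run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .io import GenomicInterval, write_allele_depths, read_allele_depths, write_bed
from .simulate import (
    CrossConfig, DiagnosticIndel, GenomeModel, build_variant_sites,
    embed_diagnostic_indel, indel_marker_codes, make_bulks,
    simulate_f2_population, simulate_parent_reads, simulate_pool_reads,
    WEEPING,
)
from .index import FilterConfig, apply_filters, compute_indices, write_index_table
from .scan import (
    call_candidate_regions, default_depth_grid, interval_length_kb, plot_scan,
    simulate_null_thresholds, sliding_windows, write_windows_table,
)
from .segregation import chi_square_ratio
from .finemap import co_segregation_accuracy, find_diagnostic_indels

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Defaults reproduce the study's stated analysis settings: per-pool
    depth filter 7-fold, SNP-index cutoff 0.3, 1 Mb windows advanced by
    1 kb, 1000 null simulations at 95% confidence, an F2 of 395 with
    bulks of 15 sequenced at ~100-fold.
    """

    seed: int = 0
    outdir: Optional[str] = None

    # stage toggles
    simulate: bool = True
    run_scan: bool = True
    run_segtest: bool = True
    run_marker: bool = True
    make_plot: bool = False
    write_vcf: bool = False

    # synthetic genome
    n_chrom: int = 2
    chrom_length: int = 25_000_000
    marker_spacing: int = 10_000
    cm_per_mb: float = 4.0

    # cross + sequencing
    n_f2: int = 395
    bulk_size: int = 15
    causal_chrom: str = "chr1"
    causal_pos: int = 12_500_000
    depth_mean: float = 100.0
    error_rate: float = 0.001
    phenotype_error: float = 0.0
    indel_offset: int = 5_000
    null_bulks: bool = False    # ignore phenotype when pooling (null cross)

    # input when not simulating
    input_sites: Optional[str] = None

    # filtering
    min_depth: int = 7
    min_index: float = 0.3
    parent_band_low: float = 0.3
    parent_band_high: float = 0.7
    require_parent: bool = True
    index_filter_mode: str = "both"

    # scan
    window_bp: int = 1_000_000
    step_bp: int = 1_000
    n_sim: int = 1000
    confidence: float = 0.95
    max_gap: int = 1

    # segregation test
    expected_ratio: tuple[float, float] = (1, 3)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_depth=self.min_depth, min_index=self.min_index,
            parent_het_band=(self.parent_band_low, self.parent_band_high),
            require_parent=self.require_parent,
            index_filter_mode=self.index_filter_mode,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "expected_ratio" in data:
            data["expected_ratio"] = tuple(data["expected_ratio"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["expected_ratio"] = list(self.expected_ratio)
        return d


@dataclass
class RunSummary:
    """Counts and headline results of one run, stage by stage."""

    seed: int
    n_sites: int = 0
    filter_report: dict = field(default_factory=dict)
    n_passing: int = 0
    n_windows: int = 0
    n_regions: int = 0
    top_region: Optional[dict] = None
    segregation: Optional[dict] = None
    marker_accuracy: Optional[float] = None
    candidate_indels: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Deterministic child seeds (< 2^31), one per stage slot."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the enabled stages in order; see module docstring."""
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "bulkscan_version": __version__,
            "config": config.to_dict(),
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    summary = RunSummary(seed=config.seed)
    genome = None
    population = None
    indel = None

    # -- simulate -----------------------------------------------------------
    if config.simulate:
        genome = GenomeModel.default(
            n_chrom=config.n_chrom, length=config.chrom_length,
            marker_spacing=config.marker_spacing, cm_per_mb=config.cm_per_mb,
        )
        cross = CrossConfig(
            n_f2=config.n_f2, bulk_size=config.bulk_size,
            causal_chrom=config.causal_chrom, causal_pos=config.causal_pos,
            depth_mean=config.depth_mean, error_rate=config.error_rate,
            phenotype_error=config.phenotype_error, seed=seeds[0],
        )
        population = simulate_f2_population(genome, cross)
        if config.null_bulks:
            rng = np.random.default_rng(seeds[1])
            order = rng.permutation(len(population))
            pl_bulk = [population[i] for i in order[:config.bulk_size]]
            st_bulk = [population[i]
                       for i in order[config.bulk_size:2 * config.bulk_size]]
        else:
            pl_bulk, st_bulk = make_bulks(population, config.bulk_size, seeds[1])
        parent_reads = simulate_parent_reads(
            genome, config.depth_mean, config.error_rate, seeds[2])
        st_reads = simulate_pool_reads(
            st_bulk, genome, config.depth_mean, config.error_rate, seeds[3])
        pl_reads = simulate_pool_reads(
            pl_bulk, genome, config.depth_mean, config.error_rate, seeds[4])
        sites = build_variant_sites(genome, parent_reads, st_reads, pl_reads,
                                    seeds[5])
        indel = DiagnosticIndel(chrom=config.causal_chrom,
                                pos=config.causal_pos + config.indel_offset)
        sites = embed_diagnostic_indel(
            sites, indel, pl_bulk, st_bulk, config.causal_chrom,
            config.causal_pos, genome, config.depth_mean, config.error_rate,
            seeds[6])
        if outdir:
            write_allele_depths(sites, outdir / "sites.tsv", format="tsv",
                                header_comments=[f"seed={config.seed}"])
            if config.write_vcf:
                write_allele_depths(sites, outdir / "sites.vcf", format="vcf",
                                    contig_lengths=genome.chrom_lengths)
    else:
        if not config.input_sites:
            raise ValueError("stage simulate disabled and no input_sites given")
        sites = read_allele_depths(config.input_sites)
    summary.n_sites = len(sites)
    logger.info("stage simulate/load: %d sites", len(sites))

    # -- index --------------------------------------------------------------
    records = compute_indices(sites)
    passing, report = apply_filters(records, config.filter_config())
    summary.filter_report = report
    summary.n_passing = len(passing)
    if outdir:
        write_index_table(records, outdir / "index.tsv")
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("stage index: %d/%d passing", len(passing), len(records))

    # -- scan ---------------------------------------------------------------
    regions = []
    if config.run_scan:
        chrom_lengths = genome.chrom_lengths if genome else None
        windows = sliding_windows(passing, chrom_lengths,
                                  window_bp=config.window_bp,
                                  step_bp=config.step_bp)
        curve = simulate_null_thresholds(
            config.bulk_size, default_depth_grid(windows),
            n_sim=config.n_sim, confidence=config.confidence, seed=seeds[7])
        regions = call_candidate_regions(windows, curve,
                                         step_bp=config.step_bp,
                                         max_gap=config.max_gap)
        summary.n_windows = len(windows)
        summary.n_regions = len(regions)
        if regions:
            top = regions[0]
            summary.top_region = {
                "chrom": top.interval.chrom,
                "start": top.interval.start,
                "end": top.interval.end,
                "length_kb": interval_length_kb(top),
                "peak_delta": top.peak_delta,
                "n_windows": top.n_windows,
            }
        if outdir:
            write_windows_table(windows, outdir / "windows.tsv")
            write_bed([r.interval for r in regions], outdir / "regions.bed")
            if config.make_plot:
                plot_scan(passing, windows, regions, outdir / "scan.png",
                          chrom_lengths)
        logger.info("stage scan: %d windows, %d regions", len(windows),
                    len(regions))

    # -- segregation test ---------------------------------------------------
    if config.run_segtest and population is not None:
        n_weep = sum(ind.phenotype == WEEPING for ind in population)
        n_std = len(population) - n_weep
        test = chi_square_ratio((n_weep, n_std), config.expected_ratio)
        summary.segregation = {
            "weeping": n_weep, "standard": n_std,
            "chi2": test.chi2, "p_value": test.p_value, "df": test.df,
        }
        logger.info("stage segtest: %d:%d chi2=%.3f p=%.3f", n_std, n_weep,
                    test.chi2, test.p_value)

    # -- diagnostic marker --------------------------------------------------
    if config.run_marker and population is not None and indel is not None:
        codes = indel_marker_codes(population, indel, config.causal_chrom,
                                   config.causal_pos, genome)
        phenotypes = [ind.phenotype for ind in population]
        result = co_segregation_accuracy(codes, phenotypes,
                                         marker=f"indel@{indel.chrom}:{indel.pos}")
        summary.marker_accuracy = result.accuracy
        search_region = (regions[0].interval if regions
                         else GenomicInterval(config.causal_chrom, 0,
                                              config.chrom_length))
        summary.candidate_indels = find_diagnostic_indels(sites, search_region)
        logger.info("stage marker: accuracy %.1f%%, %d candidate indel(s)",
                    result.accuracy, len(summary.candidate_indels))

    if outdir:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    return summary
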