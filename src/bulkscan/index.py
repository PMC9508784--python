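"""Per-site SNP-index computation and site filtering.

The SNP-index of a pool at one site is the fraction of its reads carrying
the mutant (weeping-derived) allele; Δ(SNP-index) is the weeping-bulk
index minus the standard-bulk index.  Under the recessive F2 two-bulk
design the expected values at the causal locus are 1 and 1/3, so Δ → 2/3.

Because the shared parent is heterozygous, the mutant allele cannot be
phased from the parent sample alone; orientation instead uses the bulk
contrast (the allele enriched in the weeping bulk), and the parent serves
as a heterozygosity filter to eliminate spurious sites.

Filter semantics follow the standard QTL-seq reading of the discard
rules: a site needs depth >= min_depth in BOTH pools, must be observed in
both pools, and is dropped for low index only when BOTH pools fall below
the cutoff — an either-pool rule would erase true linked sites, whose
expected standard-bulk index (1/3) sits at the cutoff.  The literal
either-pool reading remains available via ``index_filter_mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .io import VariantSite

logger = logging.getLogger(__name__)

#: flag precedence for the single-count filter report
FILTER_PRECEDENCE = ("low_depth", "one_pool_missing", "parent_not_het", "low_index")


@dataclass(frozen=True)
class FilterConfig:
    """Site-filter thresholds.

    ``min_depth``: minimum per-pool total reads (default 7-fold).
    ``min_index``: SNP-index cutoff (default 0.3).
    ``parent_het_band``: allowed parent mutant-allele fraction for a
    credibly heterozygous site (default 0.3–0.7).  ``require_parent``
    turns the parent check off entirely when False.
    """

    min_depth: int = 7
    min_index: float = 0.3
    parent_het_band: tuple[float, float] = (0.3, 0.7)
    require_parent: bool = True
    index_filter_mode: Literal["both", "either"] = "both"

    def __post_init__(self) -> None:
        if not (0 <= self.min_index < 0.5):
            raise ValueError("min_index must be in [0, 0.5)")
        low, high = self.parent_het_band
        if not (0 <= low < high <= 1):
            raise ValueError("parent_het_band must satisfy 0 <= low < high <= 1")
        if self.index_filter_mode not in ("both", "either"):
            raise ValueError("index_filter_mode must be 'both' or 'either'")


@dataclass
class SNPIndexRecord:
    """Per-site indices for both bulks, oriented to the mutant allele.

    ``index_pl`` / ``index_st`` are mutant-read fractions in the weeping
    and standard pools (None when the pool is unobserved or has zero
    depth — absence is not index 0).  ``delta`` = index_pl - index_st
    when both are defined.  ``filter_status`` holds every failed filter,
    or {"pass"}.
    """

    site: VariantSite
    mutant_allele: Literal["ref", "alt"]
    index_pl: Optional[float]
    index_st: Optional[float]
    depth_pl: int
    depth_st: int
    parent_index: Optional[float]
    delta: Optional[float]
    filter_status: frozenset[str] = frozenset()

    @property
    def passes(self) -> bool:
        return self.filter_status == frozenset({"pass"})


def orient_mutant_allele(site: VariantSite) -> Literal["ref", "alt"]:
    """Decide which allele is the mutant (weeping-derived) one.

    The mutant allele is the one enriched in the weeping bulk relative to
    the standard bulk; ties (including both pools missing) resolve to the
    alt allele, deterministically.  With a single observed pool the
    orientation falls back to that pool's majority allele (weeping) or
    minority allele (standard); such records are flagged downstream
    anyway.
    """
    def alt_fraction(d):
        if d is None or d[0] + d[1] == 0:
            return None
        return d[1] / (d[0] + d[1])

    fpl, fst = alt_fraction(site.pl), alt_fraction(site.st)
    if fpl is None and fst is None:
        return "alt"
    if fst is None:
        return "alt" if fpl >= 0.5 else "ref"
    if fpl is None:
        return "alt" if fst <= 0.5 else "ref"
    return "alt" if fpl - fst >= 0 else "ref"


def _mutant_fraction(depths, mutant_allele) -> tuple[Optional[float], int]:
    if depths is None:
        return None, 0
    total = depths[0] + depths[1]
    if total == 0:
        return None, 0
    mutant = depths[1] if mutant_allele == "alt" else depths[0]
    return mutant / total, total


def compute_indices(sites: Sequence[VariantSite]) -> list[SNPIndexRecord]:
    """Orient each site and compute both pool indices and Δ.

    Zero-depth or absent pools yield a None index; Δ is only defined when
    both pools are observed.
    """
    records = []
    for site in sites:
        mutant = orient_mutant_allele(site)
        index_pl, depth_pl = _mutant_fraction(site.pl, mutant)
        index_st, depth_st = _mutant_fraction(site.st, mutant)
        parent_index, _ = _mutant_fraction(site.parent, mutant)
        delta = (
            index_pl - index_st
            if index_pl is not None and index_st is not None
            else None
        )
        records.append(SNPIndexRecord(
            site=site, mutant_allele=mutant, index_pl=index_pl,
            index_st=index_st, depth_pl=depth_pl, depth_st=depth_st,
            parent_index=parent_index, delta=delta,
        ))
    return records


def _failed_flags(rec: SNPIndexRecord, config: FilterConfig) -> set[str]:
    flags: set[str] = set()
    missing = rec.index_pl is None or rec.index_st is None
    if missing:
        flags.add("one_pool_missing")
    observed_depths = [d for d, idx in ((rec.depth_pl, rec.index_pl),
                                        (rec.depth_st, rec.index_st))
                       if idx is not None]
    if any(d < config.min_depth for d in observed_depths):
        flags.add("low_depth")
    if config.require_parent and (
        rec.parent_index is None
        or not (config.parent_het_band[0] <= rec.parent_index
                <= config.parent_het_band[1])
    ):
        flags.add("parent_not_het")
    if not missing:
        below = [rec.index_pl < config.min_index, rec.index_st < config.min_index]
        low = all(below) if config.index_filter_mode == "both" else any(below)
        if low:
            flags.add("low_index")
    return flags


def apply_filters(records: Iterable[SNPIndexRecord],
                  config: Optional[FilterConfig] = None
                  ) -> tuple[list[SNPIndexRecord], dict[str, int]]:
    """Annotate records with filter flags and split off the passing set.

    Returns (passing records, report).  The report counts each failing
    record exactly once, attributed to its highest-precedence flag
    (low_depth > one_pool_missing > parent_not_het > low_index), so the
    per-reason counts sum to total - passing.
    """
    config = config or FilterConfig()
    passing: list[SNPIndexRecord] = []
    report = {flag: 0 for flag in FILTER_PRECEDENCE}
    report["pass"] = 0
    report["total"] = 0
    for rec in records:
        report["total"] += 1
        flags = _failed_flags(rec, config)
        if not flags:
            rec.filter_status = frozenset({"pass"})
            report["pass"] += 1
            passing.append(rec)
        else:
            rec.filter_status = frozenset(flags)
            for flag in FILTER_PRECEDENCE:
                if flag in flags:
                    report[flag] += 1
                    break
    logger.info(
        "site filters: %d/%d passing (%s)", report["pass"], report["total"],
        ", ".join(f"{k}={report[k]}" for k in FILTER_PRECEDENCE if report[k]),
    )
    return passing, report


_INDEX_COLUMNS = ("chrom", "pos", "index_st", "index_pl", "delta",
                  "depth_st", "depth_pl", "filter_status")


def write_index_table(records: Iterable[SNPIndexRecord], path) -> None:
    """Write the per-site index table as TSV (missing values as '.')."""
    def fmt(x):
        return "." if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))

    with open(path, "w") as fh:
        fh.write("\t".join(_INDEX_COLUMNS) + "\n")
        for r in records:
            status = ",".join(sorted(r.filter_status)) if r.filter_status else "."
            fh.write("\t".join([
                r.site.chrom, str(r.site.pos), fmt(r.index_st), fmt(r.index_pl),
                fmt(r.delta), str(r.depth_st), str(r.depth_pl), status,
            ]) + "\n")
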