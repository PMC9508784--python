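"""Recombinant-based fine mapping and diagnostic-marker validation.

Under a single-locus recessive model, an individual is *recombinant* at a
marker when its marker genotype contradicts its phenotype: a weeping
(mutant) plant that is not homozygous for the mutant-linked allele, or a
standard plant that is.  Markers free of recombinants delimit the region
that still co-segregates with the trait; the nearest recombinant-bearing
markers on each side bound the localized interval (closed, i.e. the
flanking markers themselves are the printed endpoints).

Diagnostic indel selection looks for indels where the two bulks are
near-fixed for opposite alleles — weeping-bulk index ~1, standard-bulk
index near the 1/3 expected of an AA:Aa = 1:2 mixture — and
co-segregation accuracy scores a marker's recessive phenotype prediction
(weeping iff homozygous for the mutant-linked allele) across a panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .io import GENOTYPE_CODES, GenomicInterval, VariantSite
from .index import compute_indices


class Marker(NamedTuple):
    name: str
    chrom: str
    pos: int


@dataclass
class MarkerGenotypeMatrix:
    """Markers × individuals genotype codes with per-individual phenotypes.

    Codes: ``A`` hom wild, ``H`` het, ``B`` hom mutant-linked, ``-``
    missing.  Markers must be unique and sorted by (chrom, pos).
    """

    markers: list[Marker]
    genotypes: list[list[str]]
    individuals: list[str]
    phenotypes: list[str]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.genotypes):
            raise ValueError("one genotype row per marker required")
        n = len(self.individuals)
        if len(self.phenotypes) != n:
            raise ValueError("one phenotype per individual required")
        for marker, row in zip(self.markers, self.genotypes):
            if len(row) != n:
                raise ValueError(f"marker {marker.name}: row width != {n}")
            bad = set(row) - GENOTYPE_CODES
            if bad:
                raise ValueError(f"marker {marker.name}: unknown codes {bad}")
        seen = {}
        for marker in self.markers:
            key = (marker.chrom, marker.pos)
            if key in seen:
                raise ValueError(
                    f"duplicate marker position {key}: {seen[key]} and {marker.name}"
                )
            seen[key] = marker.name
        keys = [(m.chrom, m.pos) for m in self.markers]
        if keys != sorted(keys):
            raise ValueError("markers must be sorted by (chrom, pos)")

    def marker_row(self, name: str) -> tuple[Marker, list[str]]:
        for marker, row in zip(self.markers, self.genotypes):
            if marker.name == name:
                return marker, row
        raise KeyError(f"marker {name!r} not in matrix")

    def drop_markers(self, names: set[str]) -> "MarkerGenotypeMatrix":
        keep = [i for i, m in enumerate(self.markers) if m.name not in names]
        return MarkerGenotypeMatrix(
            markers=[self.markers[i] for i in keep],
            genotypes=[self.genotypes[i] for i in keep],
            individuals=list(self.individuals),
            phenotypes=list(self.phenotypes),
        )


@dataclass(frozen=True)
class RecombinantReport:
    """Per-marker recombinant tallies and the localized interval.

    ``per_marker`` maps name -> (n_recombinant, n_informative, ids).
    ``interval`` is None when no zero-recombinant anchor exists;
    ``open_left``/``open_right`` flag sides with no recombinant-bearing
    flanking marker.
    """

    per_marker: dict[str, tuple[int, int, tuple[str, ...]]]
    interval: Optional[GenomicInterval]
    open_left: bool = False
    open_right: bool = False


@dataclass(frozen=True)
class DiagnosticMarkerResult:
    marker: str
    concordant: int
    informative: int

    @property
    def accuracy(self) -> float:
        """Percent of informative individuals predicted correctly."""
        return 100.0 * self.concordant / self.informative


def _is_recombinant(code: str, phenotype: str) -> Optional[bool]:
    """None = uninformative (missing genotype)."""
    if code == "-":
        return None
    if phenotype == "weeping":
        return code != "B"
    return code == "B"


def count_recombinants(matrix: MarkerGenotypeMatrix, marker: str
                       ) -> tuple[int, list[str]]:
    """Recombinant individuals at one marker under the recessive rule."""
    _, row = matrix.marker_row(marker)
    ids = [
        ind
        for ind, code, phe in zip(matrix.individuals, row, matrix.phenotypes)
        if _is_recombinant(code, phe)
    ]
    return len(ids), ids


def localize_interval(matrix: MarkerGenotypeMatrix) -> RecombinantReport:
    """Bound the causal locus by the recombinant-bearing flanking markers.

    The anchor is the longest run of zero-recombinant markers (first run
    on ties); the interval spans from the nearest marker with >= 1
    recombinant on its left to the nearest such marker on its right,
    closed at those markers' positions.  A side with no recombinant
    marker leaves the interval open (clamped to the anchor's outermost
    marker) and flagged.
    """
    per_marker: dict[str, tuple[int, int, tuple[str, ...]]] = {}
    counts = []
    for marker, row in zip(matrix.markers, matrix.genotypes):
        flags = [_is_recombinant(c, p) for c, p in zip(row, matrix.phenotypes)]
        ids = tuple(i for i, f in zip(matrix.individuals, flags) if f)
        informative = sum(f is not None for f in flags)
        per_marker[marker.name] = (len(ids), informative, ids)
        # a marker with no informative individual cannot anchor the interval
        counts.append(len(ids) if informative > 0 else -1)

    # longest zero-recombinant run
    best: Optional[tuple[int, int]] = None  # (start, stop) indices, half-open
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            j = i
            while j < len(counts) and counts[j] == 0 \
                    and matrix.markers[j].chrom == matrix.markers[i].chrom:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    if best is None:
        return RecombinantReport(per_marker=per_marker, interval=None)

    lo, hi = best
    chrom = matrix.markers[lo].chrom
    left = next(
        (matrix.markers[k] for k in range(lo - 1, -1, -1)
         if matrix.markers[k].chrom == chrom and counts[k] > 0),
        None,
    )
    right = next(
        (matrix.markers[k] for k in range(hi, len(counts))
         if matrix.markers[k].chrom == chrom and counts[k] > 0),
        None,
    )
    start_marker = left if left is not None else matrix.markers[lo]
    end_marker = right if right is not None else matrix.markers[hi - 1]
    interval = GenomicInterval.from_1based(chrom, start_marker.pos, end_marker.pos) \
        if start_marker.pos < end_marker.pos else \
        GenomicInterval.from_1based(chrom, start_marker.pos, start_marker.pos + 1)
    return RecombinantReport(
        per_marker=per_marker,
        interval=interval,
        open_left=left is None,
        open_right=right is None,
    )


def find_diagnostic_indels(sites: Sequence[VariantSite],
                           region: GenomicInterval,
                           min_mutant_index: float = 0.95,
                           other_band: tuple[float, float] = (0.15, 0.55)
                           ) -> list[dict]:
    """Indels inside ``region`` whose bulks show the linked fixation pattern.

    A candidate has weeping-bulk (mutant) index >= ``min_mutant_index``
    and standard-bulk index inside ``other_band`` — the band around the
    1/3 expected of the AA:Aa = 1:2 standard-bulk mixture, widened for
    sampling slack.  SNPs are never returned.  Each candidate reports the
    allele length difference in bp.
    """
    candidates = []
    indels = [s for s in sites
              if s.kind == "indel" and region.contains(s.chrom, s.pos)]
    for rec in compute_indices(indels):
        if rec.index_pl is None or rec.index_st is None:
            continue
        if rec.index_pl >= min_mutant_index and \
                other_band[0] <= rec.index_st <= other_band[1]:
            candidates.append({
                "chrom": rec.site.chrom,
                "pos": rec.site.pos,
                "length_difference": rec.site.length_difference,
                "index_pl": rec.index_pl,
                "index_st": rec.index_st,
                "delta": rec.delta,
            })
    return candidates


def co_segregation_accuracy(genotypes: Sequence[str], phenotypes: Sequence[str],
                            marker: str = "indel") -> DiagnosticMarkerResult:
    """Score a marker's recessive phenotype prediction across a panel.

    Predicted weeping iff the genotype is ``B`` (homozygous for the
    weeping-linked allele).  Individuals with missing genotype are
    excluded from numerator and denominator alike.
    """
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotypes and phenotypes must be aligned")
    informative = concordant = 0
    for code, phe in zip(genotypes, phenotypes):
        if code == "-":
            continue
        if code not in GENOTYPE_CODES:
            raise ValueError(f"unknown genotype code {code!r}")
        informative += 1
        predicted = "weeping" if code == "B" else "standard"
        concordant += predicted == phe
    if informative == 0:
        raise ValueError("no informative individuals")
    return DiagnosticMarkerResult(marker=marker, concordant=concordant,
                                  informative=informative)
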