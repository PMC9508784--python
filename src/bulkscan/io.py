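"""Readers and writers for the tabular formats the pipeline touches.

Coordinate conventions, used consistently across the package:

* variant sites are 1-based inclusive (VCF convention);
* genomic intervals are 0-based half-open (BED convention).

Every public structure documents which frame it uses; conversions between
the two happen only at construction (:meth:`GenomicInterval.from_1based`)
and at serialisation boundaries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: per-sample (ref_count, alt_count) read depths
Depths = tuple[int, int]

VCF_SAMPLES = ("PARENT", "ST_POOL", "PL_POOL")

GENOTYPE_CODES = frozenset({"A", "H", "B", "-"})


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with per-sample ref/alt read depths.

    ``pos`` is 1-based.  ``parent``, ``st`` and ``pl`` hold
    (ref_count, alt_count) pairs for the heterozygous parent, the
    standard-phenotype bulk and the mutant-phenotype (weeping) bulk;
    any of them may be ``None`` when the sample was not observed at the
    site — absence is never represented as zero depth.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    parent: Optional[Depths] = None
    st: Optional[Depths] = None
    pl: Optional[Depths] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("parent", "st", "pl"):
            d = getattr(self, name)
            if d is not None and (d[0] < 0 or d[1] < 0):
                raise ValueError(f"negative depth in {name}: {d}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def kind(self) -> str:
        """``"indel"`` iff the alleles differ in length, else ``"snp"``."""
        return "indel" if len(self.ref) != len(self.alt) else "snp"

    @property
    def length_difference(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic interval, 0-based half-open (BED frame)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @classmethod
    def from_1based(cls, chrom: str, first: int, last: int) -> "GenomicInterval":
        """Build from 1-based inclusive endpoints (e.g. marker positions)."""
        return cls(chrom, first - 1, last)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end


# ---------------------------------------------------------------------------
# allele-depth tables: TSV dialect and VCF 4.2
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "chrom pos ref alt parent_ref parent_alt st_ref st_alt pl_ref pl_alt".split()
)


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".vcf":
        return "vcf"
    return "tsv"


def read_allele_depths(path, format: Optional[str] = None) -> list[VariantSite]:
    """Read an allele-depth table from VCF (FORMAT AD) or the TSV dialect.

    Output is sorted by (chrom, pos); unsorted input is sorted with a
    logged warning.  Multi-allelic VCF rows are skipped with a logged
    count, matching the biallelic-only contract of the pipeline.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        sites = _read_vcf(path)
    elif fmt == "tsv":
        sites = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        logger.warning("%s was not coordinate-sorted; sorting output", path)
        sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def _parse_depth_pair(ref_s: str, alt_s: str, lineno: int) -> Optional[Depths]:
    if ref_s == "." and alt_s == ".":
        return None
    try:
        return (int(ref_s), int(alt_s))
    except ValueError:
        raise ValueError(f"line {lineno}: malformed depth pair ({ref_s}, {alt_s})")


def _read_tsv(path: Path) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields != _TSV_COLUMNS:
                    raise ValueError(
                        f"line {lineno}: expected header {_TSV_COLUMNS}, got {fields}"
                    )
                header = fields
                continue
            if len(fields) != len(_TSV_COLUMNS):
                raise ValueError(
                    f"line {lineno}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise ValueError(f"line {lineno}: bad position {fields[1]!r}")
            sites.append(
                VariantSite(
                    chrom=fields[0],
                    pos=pos,
                    ref=fields[2],
                    alt=fields[3],
                    parent=_parse_depth_pair(fields[4], fields[5], lineno),
                    st=_parse_depth_pair(fields[6], fields[7], lineno),
                    pl=_parse_depth_pair(fields[8], fields[9], lineno),
                )
            )
    return sites


def write_allele_depths(
    sites: Iterable[VariantSite],
    path,
    format: Optional[str] = None,
    contig_lengths: Optional[dict[str, int]] = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write sites as the TSV dialect or as minimal VCF 4.2 with AD fields."""
    path = Path(path)
    fmt = format or _infer_format(path)
    sites = list(sites)
    if fmt == "tsv":
        _write_tsv(sites, path, header_comments)
    elif fmt == "vcf":
        _write_vcf(sites, path, contig_lengths)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _fmt_pair(d: Optional[Depths]) -> tuple[str, str]:
    return (".", ".") if d is None else (str(d[0]), str(d[1]))


def _write_tsv(sites, path: Path, header_comments: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in sites:
            row = [s.chrom, str(s.pos), s.ref, s.alt]
            for d in (s.parent, s.st, s.pl):
                row.extend(_fmt_pair(d))
            fh.write("\t".join(row) + "\n")


def _write_vcf(sites, path: Path, contig_lengths) -> None:
    if contig_lengths is None:
        contig_lengths = {}
        for s in sites:
            contig_lengths[s.chrom] = max(
                contig_lengths.get(s.chrom, 0), s.pos + len(s.ref)
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bulkscan\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth for each allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(VCF_SAMPLES)
            + "\n"
        )
        for s in sites:
            calls = []
            for d in (s.parent, s.st, s.pl):
                calls.append("./." if d is None else f"./.:{d[0]},{d[1]}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(calls)
                + "\n"
            )


def _read_vcf(path: Path) -> list[VariantSite]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        sample_idx = {name: i for i, name in enumerate(vcf.samples)}
        missing = [s for s in VCF_SAMPLES if s not in sample_idx]
        if missing:
            raise ValueError(
                f"{path}: VCF lacks required samples {missing}; "
                f"found {vcf.samples}"
            )
        sites: list[VariantSite] = []
        n_multi = 0
        for v in vcf:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            ad = v.format("AD")
            depths: dict[str, Optional[Depths]] = {}
            for name in VCF_SAMPLES:
                row = ad[sample_idx[name]] if ad is not None else None
                if row is None or len(row) < 2 or row[0] < 0 or row[1] < 0:
                    depths[name] = None
                else:
                    depths[name] = (int(row[0]), int(row[1]))
            sites.append(
                VariantSite(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=v.ALT[0],
                    parent=depths["PARENT"],
                    st=depths["ST_POOL"],
                    pl=depths["PL_POOL"],
                )
            )
        if n_multi:
            logger.warning("%s: skipped %d multi-allelic records", path, n_multi)
        return sites
    finally:
        vcf.close()


# ---------------------------------------------------------------------------
# BED3 intervals
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write standard 3-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED columns")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return intervals


# ---------------------------------------------------------------------------
# marker-genotype tables for fine mapping
# ---------------------------------------------------------------------------

_MARKER_POS_RE = re.compile(r"-(\d+)$")


def parse_marker_position(name: str) -> int:
    """Extract the bp position encoded as a ``NAME-<pos>`` suffix.

    Mapping primers are conventionally named after their target
    coordinate (e.g. ``CZ2-40F-20839173`` sits at bp 20,839,173).
    """
    m = _MARKER_POS_RE.search(name)
    if not m:
        raise ValueError(f"cannot parse a position from marker name {name!r}")
    return int(m.group(1))


def read_marker_genotypes(path, default_chrom: str = "."):
    """Read a marker × individual genotype TSV into a matrix.

    Layout: a header row ``marker [chrom] [pos] <id> <id> ...``, then a
    ``phenotype`` row giving each individual's class (``weeping`` /
    ``standard``), then one row per marker with genotype codes
    ``A`` (hom wild), ``H`` (het), ``B`` (hom mutant), ``-`` (missing).
    When the ``pos`` column is absent, positions are parsed from the
    ``NAME-<pos>`` marker-name suffix.

    Returns a :class:`bulkscan.finemap.MarkerGenotypeMatrix` with markers
    sorted by (chrom, position).
    """
    from .finemap import Marker, MarkerGenotypeMatrix

    with open(path) as fh:
        lines = [
            ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")
        ]
    if len(lines) < 3:
        raise ValueError(f"{path}: need a header, a phenotype row and >= 1 marker")
    header = lines[0].split("\t")
    if header[0] != "marker":
        raise ValueError(f"{path}: first header column must be 'marker'")
    has_chrom = len(header) > 1 and header[1] == "chrom"
    has_pos = len(header) > (2 if has_chrom else 1) and header[
        2 if has_chrom else 1
    ] == "pos"
    n_meta = 1 + has_chrom + has_pos
    individuals = header[n_meta:]
    if not individuals:
        raise ValueError(f"{path}: no individual columns")

    pheno_fields = lines[1].split("\t")
    if pheno_fields[0] != "phenotype":
        raise ValueError(f"{path}: second row must be the 'phenotype' row")
    phenotypes = pheno_fields[n_meta:]
    if len(phenotypes) != len(individuals):
        raise ValueError(f"{path}: phenotype row width mismatch")

    markers: list[Marker] = []
    rows: list[list[str]] = []
    for line in lines[2:]:
        fields = line.split("\t")
        if len(fields) != n_meta + len(individuals):
            raise ValueError(
                f"{path}: marker row {fields[0]!r} has {len(fields)} columns, "
                f"expected {n_meta + len(individuals)}"
            )
        name = fields[0]
        chrom = fields[1] if has_chrom else default_chrom
        pos = int(fields[n_meta - 1]) if has_pos else parse_marker_position(name)
        for ind, code in zip(individuals, fields[n_meta:]):
            if code not in GENOTYPE_CODES:
                raise ValueError(
                    f"{path}: unknown genotype code {code!r} at marker "
                    f"{name!r}, individual {ind!r}"
                )
        markers.append(Marker(name=name, chrom=chrom, pos=pos))
        rows.append(fields[n_meta:])

    order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos))
    markers = [markers[i] for i in order]
    rows = [rows[i] for i in order]
    return MarkerGenotypeMatrix(
        markers=markers,
        genotypes=[list(r) for r in rows],
        individuals=list(individuals),
        phenotypes=list(phenotypes),
    )


def write_marker_genotypes(matrix, path) -> None:
    """Inverse of :func:`read_marker_genotypes` (always writes chrom + pos)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["marker", "chrom", "pos"] + list(matrix.individuals)) + "\n")
        fh.write("\t".join(["phenotype", ".", "."] + list(matrix.phenotypes)) + "\n")
        for marker, row in zip(matrix.markers, matrix.genotypes):
            fh.write(
                "\t".join([marker.name, marker.chrom, str(marker.pos)] + list(row))
                + "\n"
            )
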