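"""Genetic-model arithmetic for the single-locus recessive F2 design.

Two things live here: the Pearson chi-square goodness-of-fit test used to
check a phenotypic segregation ratio (3:1 standard : weeping for a
monogenic recessive trait), and the expected SNP-index values of the two
phenotype-selected bulks, which anchor the Δ(SNP-index) scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class SegregationTest:
    observed: tuple[int, int]
    expected_ratio: tuple[float, float]
    chi2: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class BulkModel:
    """Expected bulk indices for a two-bulk design."""

    design: str
    expected_index_mutant_bulk: float
    expected_index_other_bulk: float
    expected_delta: float


def chi_square_ratio(observed: tuple[int, int],
                     ratio: tuple[float, float] = (1, 3),
                     yates: bool = False) -> SegregationTest:
    """Pearson chi-square test of a two-class segregation ratio.

    No continuity correction by default (``yates=True`` applies one).
    E.g. 56 weeping vs 210 standard against 1:3 gives chi2 ≈ 2.21
    (reported as 2.2), consistent with monogenic recessive inheritance.
    """
    n1, n2 = observed
    r1, r2 = ratio
    total = n1 + n2
    if total <= 0:
        raise ValueError("need at least one observation")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ratio terms must be positive")
    e1 = total * r1 / (r1 + r2)
    e2 = total * r2 / (r1 + r2)
    correction = 0.5 if yates else 0.0
    chi2 = sum(
        (max(abs(o - e) - correction, 0.0)) ** 2 / e
        for o, e in ((n1, e1), (n2, e2))
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(observed=(n1, n2), expected_ratio=(r1, r2),
                           chi2=float(chi2), p_value=p, df=1)


def expected_indices(design: str = "f2_recessive") -> BulkModel:
    """Expected bulk SNP-indices under a named design.

    For ``f2_recessive``: the mutant bulk contains only aa individuals,
    so its index is aa/aa = 1; the other bulk is a 1:2 mixture of AA and
    Aa, giving AA/(AA + 2Aa) = 1/3 mutant alleles; Δ = 1 - 1/3 = 2/3.
    """
    if design != "f2_recessive":
        raise ValueError(f"unknown design {design!r}")
    mutant = 1.0
    other = 1.0 / 3.0
    return BulkModel(design=design, expected_index_mutant_bulk=mutant,
                     expected_index_other_bulk=other,
                     expected_delta=mutant - other)
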