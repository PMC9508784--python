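"""Sliding-window Δ(SNP-index) scan with simulation-based thresholds.

The genome is tiled with large windows advanced by a small step (defaults
1 Mb / 1 kb); each window's statistic is the unweighted mean of the
per-site Δ(SNP-index) values inside it.  Significance is judged against
depth-dependent quantiles of Δ under the null of no linkage, obtained by
simulating bulk composition and read sampling: with no linkage,
phenotype selection does not constrain a site, so both pools draw their
``bulk_size`` genotypes from the 1:2:1 F2 distribution, form the pool
allele frequency, and sequence it binomially at the given depth.
Windows above the upper quantile are merged into candidate regions.

Calling is one-sided on the upper tail — the two-bulk design makes Δ
positive at linked sites by construction — but the lower quantile is
computed and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import GenomicInterval
from .index import SNPIndexRecord


@dataclass
class Window:
    """One sliding window: interval (0-based half-open), site summary, call."""

    interval: GenomicInterval
    n_sites: int
    mean_delta: float
    mean_depth: float
    threshold: Optional[float] = None
    significant: bool = False


@dataclass(frozen=True)
class ThresholdCurve:
    """Null |Δ| quantiles as a function of read depth.

    ``depths`` is the simulated grid; ``lower``/``upper`` the empirical
    (1-confidence)/2 and 1-(1-confidence)/2 quantiles of null Δ at each
    grid depth.  Lookup is by nearest grid point.
    """

    bulk_size: int
    confidence: float
    depths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if np.any(self.upper < self.lower):
            raise ValueError("upper quantile below lower quantile")

    def lookup(self, depth: float) -> tuple[float, float]:
        """(lower, upper) at the grid depth nearest to ``depth``."""
        i = int(np.argmin(np.abs(self.depths - depth)))
        return float(self.lower[i]), float(self.upper[i])


@dataclass(frozen=True)
class CandidateRegion:
    """A run of consecutive significant windows, merged."""

    interval: GenomicInterval
    peak_delta: float
    n_windows: int


def sliding_windows(records: Sequence[SNPIndexRecord],
                    chrom_lengths: Optional[dict[str, int]] = None,
                    window_bp: int = 1_000_000,
                    step_bp: int = 1_000) -> list[Window]:
    """Tile each chromosome and average Δ per window.

    ``records`` should be filter-passing, coordinate-sorted index
    records.  Windows start at 0, step, 2*step, ... up to the chromosome
    end (taken from ``chrom_lengths`` or the last observed site);
    ``mean_delta`` is the unweighted mean of per-site Δ in
    [start, start + window_bp), ``mean_depth`` the mean per-site
    min(depth_st, depth_pl).  Windows containing no site are omitted.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    by_chrom: dict[str, list[SNPIndexRecord]] = {}
    for r in records:
        if r.delta is None:
            continue
        by_chrom.setdefault(r.site.chrom, []).append(r)

    windows: list[Window] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.site.pos)
        pos = np.array([r.site.pos for r in recs], dtype=np.int64)
        delta = np.array([r.delta for r in recs])
        depth = np.array([min(r.depth_st, r.depth_pl) for r in recs], dtype=float)
        csum_delta = np.concatenate([[0.0], np.cumsum(delta)])
        csum_depth = np.concatenate([[0.0], np.cumsum(depth)])

        limit = (chrom_lengths or {}).get(chrom)
        length = limit if limit is not None else int(pos[-1])
        starts = np.arange(0, length, step_bp, dtype=np.int64)
        # interval [start, start+window) in the 0-based frame holds the
        # 1-based site positions p with start < p <= start+window
        lo = np.searchsorted(pos, starts, side="right")
        hi = np.searchsorted(pos, starts + window_bp, side="right")
        n = hi - lo
        keep = np.nonzero(n > 0)[0]
        for i in keep:
            a, b = int(lo[i]), int(hi[i])
            count = b - a
            end = int(starts[i]) + window_bp
            if limit is not None:
                end = min(end, limit)   # clamp at the chromosome boundary
            windows.append(Window(
                interval=GenomicInterval(chrom, int(starts[i]), end),
                n_sites=count,
                mean_delta=float((csum_delta[b] - csum_delta[a]) / count),
                mean_depth=float((csum_depth[b] - csum_depth[a]) / count),
            ))
    return windows


def simulate_null_thresholds(bulk_size: int,
                             depth_grid: Sequence[int],
                             n_sim: int = 1000,
                             confidence: float = 0.95,
                             seed=None) -> ThresholdCurve:
    """Depth-wise null quantiles of Δ(SNP-index) by Monte-Carlo simulation.

    For each depth d, ``n_sim`` replicates draw both pools' genotype
    compositions from the unconstrained F2 law (1:2:1 — equivalently the
    pool's mutant-allele count is Binomial(2*bulk_size, 1/2)), then d
    reads per pool binomially at the pool frequency, and record the
    difference of observed indices.  Deterministic given ``seed``.
    """
    depth_grid = np.asarray(sorted(set(int(d) for d in depth_grid)), dtype=np.int64)
    if depth_grid.size == 0:
        raise ValueError("depth grid is empty")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not (0 <= confidence < 1):
        raise ValueError("confidence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    q_lo, q_hi = (1 - confidence) / 2, 1 - (1 - confidence) / 2
    lower = np.empty(depth_grid.size)
    upper = np.empty(depth_grid.size)
    two_n = 2 * bulk_size
    for i, d in enumerate(depth_grid):
        f_pl = rng.binomial(two_n, 0.5, size=n_sim) / two_n
        f_st = rng.binomial(two_n, 0.5, size=n_sim) / two_n
        idx_pl = rng.binomial(d, f_pl) / d
        idx_st = rng.binomial(d, f_st) / d
        delta = idx_pl - idx_st
        lower[i], upper[i] = np.quantile(delta, [q_lo, q_hi])
    return ThresholdCurve(bulk_size=bulk_size, confidence=confidence,
                          depths=depth_grid, lower=lower, upper=upper)


def default_depth_grid(windows: Sequence[Window]) -> list[int]:
    """Deciles of the observed window depths, deduplicated."""
    depths = np.array([w.mean_depth for w in windows])
    if depths.size == 0:
        raise ValueError("no windows to build a depth grid from")
    qs = np.quantile(depths, np.linspace(0, 1, 11))
    return sorted({max(1, int(round(q))) for q in qs})


def assign_thresholds(windows: Iterable[Window], curve: ThresholdCurve) -> None:
    """Attach the nearest-depth upper threshold and the significance call."""
    for w in windows:
        _, upper = curve.lookup(w.mean_depth)
        w.threshold = upper
        w.significant = w.mean_delta > upper


def call_candidate_regions(windows: Sequence[Window], curve: ThresholdCurve,
                           step_bp: int = 1_000,
                           max_gap: int = 1) -> list[CandidateRegion]:
    """Merge runs of consecutive significant windows into regions.

    Windows must come from :func:`sliding_windows` (sorted per
    chromosome).  Runs tolerate up to ``max_gap`` omitted (zero-site)
    windows between consecutive significant ones.  Regions are returned
    sorted by peak mean Δ, descending.
    """
    assign_thresholds(windows, curve)
    regions: list[CandidateRegion] = []
    run: list[Window] = []

    def flush():
        if run:
            regions.append(CandidateRegion(
                interval=GenomicInterval(run[0].interval.chrom,
                                         run[0].interval.start,
                                         run[-1].interval.end),
                peak_delta=max(w.mean_delta for w in run),
                n_windows=len(run),
            ))
            run.clear()

    max_jump = (max_gap + 1) * step_bp
    for w in windows:
        if not w.significant:
            continue
        if run and (w.interval.chrom != run[-1].interval.chrom
                    or w.interval.start - run[-1].interval.start > max_jump):
            flush()
        run.append(w)
    flush()
    regions.sort(key=lambda r: r.peak_delta, reverse=True)
    return regions


def interval_length_kb(region) -> int:
    """Interval span in kb, rounded to the nearest integer.

    Accepts a :class:`CandidateRegion` or a bare interval; e.g. the
    closed marker interval 20,839,173–20,998,220 bp spans 159 kb.
    """
    iv = region.interval if isinstance(region, CandidateRegion) else region
    return int(round(iv.length_bp / 1000.0))


_WINDOW_COLUMNS = ("chrom", "start", "end", "n_sites", "mean_delta",
                   "mean_depth", "threshold", "significant")


def write_windows_table(windows: Iterable[Window], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
        for w in windows:
            th = "." if w.threshold is None else f"{w.threshold:.6g}"
            fh.write("\t".join([
                w.interval.chrom, str(w.interval.start), str(w.interval.end),
                str(w.n_sites), f"{w.mean_delta:.6g}", f"{w.mean_depth:.6g}",
                th, "1" if w.significant else "0",
            ]) + "\n")


def plot_scan(records: Sequence[SNPIndexRecord], windows: Sequence[Window],
              regions: Sequence[CandidateRegion], path,
              chrom_lengths: Optional[dict[str, int]] = None) -> None:
    """Per-chromosome Δ scan plot: site points, window mean, threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.interval.chrom for w in windows}
                    | {r.site.chrom for r in records if r.delta is not None})
    if not chroms:
        raise ValueError("nothing to plot")
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.8 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        pts = [(r.site.pos, r.delta) for r in records
               if r.site.chrom == chrom and r.delta is not None]
        if pts:
            x, y = zip(*pts)
            ax.plot(np.array(x) / 1e6, y, ".", ms=1.5, color="steelblue",
                    alpha=0.4, label="site Δ")
        ws = [w for w in windows if w.interval.chrom == chrom]
        if ws:
            mid = np.array([(w.interval.start + w.interval.end) / 2 for w in ws]) / 1e6
            ax.plot(mid, [w.mean_delta for w in ws], color="red", lw=1.2,
                    label="window mean")
            if ws[0].threshold is not None:
                ax.plot(mid, [w.threshold for w in ws], color="green", lw=1.0,
                        label="confidence threshold")
        for reg in regions:
            if reg.interval.chrom == chrom:
                ax.axvspan(reg.interval.start / 1e6, reg.interval.end / 1e6,
                           color="orange", alpha=0.2)
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel("Δ(SNP-index)")
        ax.set_ylim(-1, 1)
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
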