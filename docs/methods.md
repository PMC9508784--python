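# Methods

## The genetic model

The pipeline assumes a single-locus, fully penetrant recessive trait in
an F2 population obtained by selfing a heterozygous F1 (*Aa*).
Genotypes segregate 1 *AA* : 2 *Aa* : 1 *aa* and phenotypes 3:1; the
mutant class is exactly the *aa* genotype. Two bulks are formed by
phenotype: the mutant bulk is all *aa*; the wild-type bulk is a 1:2
mixture of *AA* and *Aa*, whose expected mutant-allele frequency is
(0·1 + 1·2)/(2·3) = 1/3. These two constants — mutant-bulk SNP-index 1
and wild-type-bulk SNP-index 1/3 — and their difference Δ = 2/3 are the
anchors of the scan (`segregation.expected_indices`).

## SNP-index computation and orientation

The F1 parent is heterozygous at every informative site, so the phase of
the mutant allele cannot be read off the parent sample; the parent is
used only as a heterozygosity filter. The mutant allele at a site is
instead defined operationally as the allele enriched in the mutant bulk
relative to the wild-type bulk (ties, and both-pools-missing, resolve to
ALT deterministically; a single observed pool orients to its majority
allele). Consequence: the per-site Δ is non-negative by construction —
it is |Δ| of a fixed-allele convention. The null-threshold machinery and
the one-sided calling rule are interpreted accordingly (see "Null
thresholds" and "Limitations").

A pool with zero reads at a site is *missing*, not index 0: absence of
evidence is never converted into an allele-frequency estimate.

## Site filters

Defaults follow the analysis settings of the motivating study:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 7 | each pool needs ≥ 7 reads |
| `min_index` | 0.3 | low-index discard cutoff |
| `parent_het_band` | 0.3–0.7 | parent mutant-read fraction accepted as heterozygous |
| `index_filter_mode` | `both` | low-index discard only when **both** pools are below the cutoff |

The `both` reading of the low-index rule is deliberate: truly linked
sites have an expected wild-type-bulk index of 1/3, essentially at the
0.3 cutoff, so an either-pool rule would discard half of the real signal
along with noise. The literal either-pool reading remains available via
`index_filter_mode="either"`. Filter flags are all recorded per site;
the summary report attributes each failing site to one reason under the
precedence low_depth > one_pool_missing > parent_not_het > low_index.

## Sliding windows

Windows of `window_bp` = 1 Mb advanced by `step_bp` = 1 kb ("1 Mb
intervals, 1 kb sliding window" in the QTL-seq convention of large
window / small step). The window statistic is the unweighted mean of
per-site Δ; per-site depth enters as min(depth of the two pools), and
windows with no passing site are omitted rather than imputed. Intervals
are 0-based half-open internally (BED frame); sites are 1-based (VCF
frame); conversion happens only at construction/serialisation.

## Null thresholds

Under no linkage, phenotype selection does not constrain a site, so both
pools draw their 15 genotypes from the 1:2:1 F2 law — equivalently the
pool's mutant-allele count is Binomial(2·15, ½) — and reads are
Binomial(d, f) at depth d. One thousand replicates per grid depth give
the empirical (1−c)/2 and 1−(1−c)/2 quantiles of Δ at confidence
c = 0.95; the depth grid defaults to the deciles of the observed window
depths and lookup is by nearest grid point. Region calling is one-sided
against the upper quantile (the bulk design makes Δ positive at linked
sites); the lower quantile is computed and reported for completeness.
Runs of consecutive significant windows merge into candidate regions,
tolerating up to `max_gap` = 1 omitted window; regions are ranked by
peak window Δ.

## Recombinant fine mapping

An individual is recombinant at a marker iff its genotype contradicts
its phenotype under the recessive model: mutant-phenotype plants must be
homozygous for the trait-linked allele (code B), wild-type plants must
not be. Missing genotypes are uninformative and excluded everywhere.
The localized interval runs from the nearest recombinant-bearing marker
left of the (longest) zero-recombinant block to the nearest such marker
on the right, *closed* at those markers — this matches the field's
convention of naming the flanking markers as the interval bounds. A side
with no recombinant-bearing marker leaves the interval open on that side
and flagged. Markers with zero informative individuals cannot anchor the
block.

Diagnostic indel candidates inside a region must show the linked
fixation pattern: mutant-bulk index ≥ 0.95 and wild-type-bulk index in
[0.15, 0.55] — a band centred on the theoretical 1/3 with slack for
binomial sampling at ~100× over 30 haplotypes. Co-segregation accuracy
scores the recessive prediction (mutant phenotype iff genotype B) over
informative individuals.

## The synthetic generator

`simulate` emulates the study design: 395 F2 plants, bulks of 15,
~100-fold pooled depth (the study reports 93.9–104.2×), symmetric
allele-flip sequencing error 10⁻³, error-free phenotyping (a
misclassification rate parameter exists, default 0). The default genome
is deliberately desk-scale: 2 chromosomes × 25 Mb, markers every 10 kb,
4 cM/Mb — large enough to exercise 1 Mb windowing and give ~100 cM per
chromosome, small enough that a full pipeline run takes under a second;
a real plant-genome scale is reachable through configuration. The bulk
size follows the bulk-construction description (15 per phenotype; an
adjacent DNA-preparation passage mentions 20 — the generator makes it
configurable and defaults to 15).

Meiosis is a Markov phase walk along each chromosome's ordered markers
with switch probability r = ½(1 − e^(−2d/100)) per inter-marker gap
(Haldane, i.e. no crossover interference — the simplest model consistent
with single-crossover fine mapping). Each individual fuses two
independent gametes. Pooled sequencing draws total depth
Poisson(depth_mean) and mutant reads Binomial(depth, f′) with
f′ = f(1−e) + (1−f)e. The mutant allele is assigned to REF or ALT
uniformly at random per site so that downstream orientation is actually
exercised. The embedded diagnostic indel (35 bp deletion, carried on the
wild-type haplotype so mutant plants are homozygous for the non-deleted
allele) co-segregates perfectly with the causal genotype by
construction; its co-segregation accuracy of 100% on error-free panels
is therefore a consistency check of the scoring rule, not a discovery
claim.

What the generator does **not** model: read-level errors with quality
scores, alignment and calling artifacts, multi-allelic sites,
segregation distortion, crossover interference, polygenic or epistatic
trait architecture, and phenotyping structure beyond a uniform
misclassification rate. Passing tests therefore certify the statistical
machinery under the stated design, not robustness to real-data artifact
classes.

## Determinism and numerics

Every stochastic operation takes an explicit seed and builds one
`numpy.random.Generator`; the pipeline derives per-stage seeds
deterministically from the run seed, echoes the full configuration to
`manifest.yaml`, and reruns are byte-identical. Quantiles use numpy's
default (linear) interpolation; the chi-square test uses the uncorrected
Pearson statistic by default (a Yates flag exists) because the
uncorrected form reproduces the field's standard worked values; window
means use exact cumulative sums; nearest-depth threshold lookup breaks
ties toward the lower grid index via argmin.

## Known limitations

- **Genome-wide null exceedances.** With bulks of 15, the pool allele
  frequency at a site is an average over only 30 haplotypes (drift sd
  ≈ 0.13), and these deviations are long-range correlated along a
  chromosome (phase correlation e^(−2d/100) decays over tens of cM).
  The per-site 95% null quantile is honored — measured per-window
  exceedance under phenotype-ignoring null crosses is ~2%, well within
  2× nominal — but because a chromosome contains only a handful of
  effectively independent drift excursions, a null genome still shows
  ≥ 1 spurious above-threshold window run in a substantial fraction of
  runs. Identification of the causal region therefore rests on ranking
  by peak Δ (the causal peak sits near 2/3, far above any drift
  excursion), not on the scan being empty elsewhere; single small
  regions far from the top peak should be read as drift.
- The folded (non-negative) per-site Δ that orientation induces raises
  the null window mean slightly above 0; the threshold quantile absorbs
  this because the same upper tail applies, but two-sided inference on
  signed Δ is not available without parental phase.
- Candidate regions are wide (several Mb) by design at this bulk size
  and depth; narrowing to sub-Mb scale is the job of the recombinant
  fine-mapping stage, not the scan.
- Only two-class segregation ratios (df = 1) and the recessive F2
  two-bulk design are implemented.
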