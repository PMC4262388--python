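# Methods

## Scope and data model

`batchlens` analyzes probe × sample matrices of log2-scale intensities.
All exchange between modules happens on log2 scale; linear (raw)
intensities exist only inside preprocessing.  A *batch factor* is a
named partition of the samples (experiment, sampling date, RNA date,
RNA person, scan date in the motivating ovary compendium of 511 fathead
minnow and 80 zebrafish arrays); one sample belongs to exactly one
batch per factor, and factors may be nested or crossed.

## Preprocessing

Order of operations: background correction → within-array MA-loess (two-
color arrays only) → log2 → quantile normalization across samples or
channels.

* **Background correction.** Default `subtract-floor`:
  `max(signal − background, 0) + offset` with offset 1.0, which keeps
  log2 defined.  Alternative `normexp-moment`: the spot intensity is
  modeled as exponential signal plus Gaussian noise; (α, μ₀, σ) are
  estimated by matching the first three moments of signal − background
  (third central moment = 2α³ identifies the exponential mean), and the
  corrected value is the strictly positive posterior mean of the signal.
* **Quantile normalization** forces every column to the row-wise mean of
  the column order statistics.  Ties receive a common value through
  average ranks; the operation is idempotent and conserves the grand
  mean exactly.
* **MA-loess** regresses M = log2(R/G) on A = (log2 R + log2 G)/2 with
  robust locally weighted regression (span 0.3, degree 1, 3 robustness
  iterations — conventional settings for dye-bias removal) and subtracts
  the fit; A is unchanged.  At least 50 probes are required.
* **Channel splitting.** The two dye channels of each array become
  separate single-channel columns (log R = A + M/2, log G = A − M/2),
  quantile-normalized across all channels.  Channels of one array share
  spot effects and are therefore correlated; rather than a generalized
  least-squares consensus-correlation fit, the decoupling here is
  loess-within-array + quantile-across-channels, with the channel
  provenance (array id, dye) recorded per column so downstream models
  can add an array blocking covariate.  This preserves the intent —
  decoupling correlated channels — through a transparent, testable
  mechanism.

## Gene-wise linear models with moderated statistics

Each probe is fitted by OLS against one shared, treatment-coded design
(intercept, batch indicators, optional case/control class, optional
blocking terms).  Collinear nuisance columns are dropped with a warning;
a class indicator aliased with the blocked structure is an error, since
silently dropping it would void the test of interest.

The residual variances s²_g (df d = n − rank) feed a scaled-inverse-
chi-square hierarchy.  The prior (d₀, s₀²) is estimated by method of
moments on z_g = log s²_g: the excess of Var(z) over the sampling
variance trigamma(d/2) equals trigamma(d₀/2), solved by monotone root
finding on d₀ ∈ [0.01, 10⁶] (tolerance 1e-8); when no excess dispersion
is observed, d₀ = ∞ and s₀² is the arithmetic mean of the s²_g.  Probes
with s²_g = 0 participate through the floor max(s²_g, 1e-12).  The
posterior variance s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) replaces s²_g in
the t (or F) statistic with d₀ + d degrees of freedom (normal/χ²
reference when d₀ = ∞).  Setting d₀ = 0 recovers the ordinary t
exactly; the test suite verifies bit-level agreement of the finite-d₀
path with limma's `lmFit`/`eBayes` as an independent oracle.

DEGs are probes with Benjamini–Hochberg adjusted p ≤ α; default
α = 0.05, no fold-change filter.  The threshold and correction are
configurable (`alpha`, `adjust_method`) because no single convention is
universal; all DEG counts in this package carry that convention.

## Between-batch variation

* **Simulated reference**: the reference group holds one pseudo-sample
  per batch — the per-gene batch mean — and each batch's replicates are
  tested against it with a two-group moderated t.  The k pseudo-samples
  carry the between-batch spread, which inflates the pooled variance:
  the scheme is deliberately the more conservative of the two, and the
  test suite checks that ordering on matched data.
* **Designated reference**: one batch (default: the largest, ties
  lexicographic, for maximal reference precision) is the common
  reference; the N−1 remaining batches are contrasted against it inside
  a single batch-blocked model.
* **Pooling**: per-factor DEG sets are united (non-redundant) and
  reported as a fraction of the transcriptome.
* **Permutation null**: sample labels are globally shuffled with batch
  sizes preserved; permutation r uses batch (r mod k) as reference
  (a reproducible rotation); the mean DEG count over the N−1 pairs is
  recorded, and critical values are empirical (1−α) quantiles at
  α ∈ {5%, 1%, 0.1%}.  At least 100 permutations are required for the
  0.1% tail.  Each permutation draws from a counter-derived RNG stream
  ([seed, stream-id, r]), so results are independent of execution,
  probe and sample order.  Observed real-label statistics are compared
  by non-exceedance (observed ≤ critical value counts as covered): DEG
  counts are discrete and the null mass often sits at zero.

A matrix with no variation at all (every probe constant) carries no
evidence of differential expression and returns zero counts directly;
inside the linear-model layer, an all-zero variance vector remains an
error, since no variance hierarchy can be fitted there.

## Within-batch variation

* **Case/control scan**: per permutation, every eligible batch
  (≥ `min_batch_size` samples; defaults 12 single-color / 10 two-color,
  the floors that keep the number of distinct splits comfortably above
  the permutation count) is split into case = ⌊n/2⌋ and control
  samples.  One *global* case/control factor, batch-blocked, is fitted —
  a single simulated two-level factor, not per-batch relabeling.  The
  maximal DEG count over permutations (also as % of the transcriptome)
  measures heterogeneity among individuals.  Permutation streams are
  nested in the seed, so the maximum is non-decreasing in the number of
  permutations.
* **Split combinatorics**: Σ_{k=min}^{max} C(n,k) counts labeled
  case/control configurations; for a batch of 22 with classes of 4–11
  this is 2,448,074 (≈2.4×10⁶) — the reason the scan samples rather
  than enumerates.
* **CV profile**: per probe and batch with ≥ `min_reps` replicates
  (default 2), CV = s/m of the log2 intensities with the sample (n−1)
  standard deviation; the per-probe profile is the *unweighted* mean
  over qualifying batches (batches are the unit of replication, so
  size-weighting would let one large batch dominate).  Under-sized
  batches are excluded, never zero-filled.  A non-positive within-batch
  mean is an error — CV on log2 scale presumes positive means, and the
  log2 convention is pinned by test (values [8,9,10] → CV = 1/9).
  Histogram bins follow the conventional grid <0.01, 0.01–0.049, …,
  ≥0.2; top-k variable-gene tables sort by CV descending with
  lexicographic tie-break and carry each probe's intensity.

## Cross-species conservation

Probes are consolidated to genes (unweighted probe means) through an
ortholog table joining the two platforms by shared gene ids.  Pathway
summaries average member genes per species and record the member-gene
Pearson correlation across species for CV and intensity; pathways need
≥ 5 shared orthologs to be included, and pathway-level correlations
additionally require member-correlation p ≤ 0.1 (configurable).
Zero-variance member sets leave the correlation undefined (NaN) and are
excluded from correlation-based lists, never coerced to 0.  Simple OLS
regressions accompany each correlation with Shapiro–Wilk residual
normality p-values.  Outliers are removed by one pass of externally
studentized residuals |r| > 3 — a reproducible, conventional rule chosen
because outlier handling in this kind of analysis is rarely specified;
excluded ids are always reported.  Pearson is the default association
measure (the regressions are linear); Spearman is available by flag.
Enrichment of a DEG set in pathways uses the one-sided hypergeometric
upper tail with BH correction across pathways — an in-package
replacement for external annotation web services.

## Synthetic data generator

The generator emulates the structure of a multi-year, two-species
compendium of untreated ovary arrays.  Defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| baseline intensity | N(8.5, 1.5²) clipped to [6, 14] log2 | observed transcriptome mean ≈ 8.5 and pathway-level range ≈ 6–14 |
| CV model | cv_g = a·μ_g^(−1)·lognormal(σ=0.35), a calibrated so mean CV = 0.05 | transcriptome-average within-batch CV ≈ 0.05 with inverse CV–intensity trend |
| batch effects | per factor and batch: 20% of genes hit, shifts N(0, 0.3²) log2 | nonsystematic subsets per batch; shift scale produces DEG counts far above the permutation null but far below saturation |
| duplicate probes | 30% of genes carry a second probe, affinity offsets N(0, 0.25²) | ortholog tables map ~1.3–1.4 probes per gene |
| orthologs | 70% of the smaller gene set, ρ_intensity = ρ_cv = 0.5 | mid-range conservation at gene level |
| pathways | 40 disjoint sets of 5–30 ortholog genes; shared offsets N(0, 1) on intensity (log2), N(0, 0.25) on log CV | several-fold pathway spread; conserved pathway structure |
| factors | Experiment 8 × 12, RNA_Person 48/48 | a primary factor with many batches plus a coarse nested factor |
| two-color | dye bias 0.3·sin(A), spot noise sd 0.6 with channel correlation 0.9 | strong shared spot effects are what makes channels correlated |

Noise is Gaussian on log2 scale with sd cv_g·μ_g, so the estimated
within-batch CV recovers cv_g directly.  Cross-species correlations are
achieved *by construction*: the shared pathway offsets and the
correlated idiosyncratic components are combined with an analytically
solved residual correlation so the total gene-level correlation matches
the configured ρ (clipped to [−1, 1] if the shared component alone
exceeds the target).  Batch hit sets are independent draws, so their
pairwise Jaccard index concentrates at f/(2−f) — the "nonsystematic"
structure that survives quantile normalization.  Every draw derives
from the mandatory seed; identical configurations are bit-identical.

What the generator does **not** emulate: probe-sequence effects,
scanner/spatial artifacts, non-Gaussian heavy-tailed biological
variation, correlated (co-regulated) gene modules beyond pathway mean
offsets, and missing values.  Passing tests therefore demonstrate that
the machinery recovers planted structure under a clean additive model,
not that real arrays meet these assumptions.

## Reporting

PCA uses SVD of the gene-centered DEG submatrix, no scaling (columns
are already on a common scale after quantile normalization); units are
samples or per-batch means, and batch-mean scores equal the mean of the
member samples' scores when projected on shared axes.  Hierarchical
clustering uses correlation distance (1 − Pearson) with average linkage;
node support is the ordinary bootstrap proportion ("BP") over
gene-resampled matrices — the multiscale approximately-unbiased variant
is intentionally not reimplemented, as its resampling machinery is out
of proportion to its role here.  Dendrograms export to Newick with
supports as internal labels.  `build_report` assembles the standard
table- and plot-data TSVs plus a JSON manifest with seeds and a
configuration digest.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical behavior under test is stable:
2 000–10 000 probes, 4–10 batches of 6–12 samples, 200 permutations for
null distributions (50 replicate generations for coverage), 250
permutations for scans, 20 replicates for scheme comparisons.  The
moment-matching root find uses bracket [0.01, 10⁶] with tolerance 1e-8;
d₀ above the bracket is reported as ∞.  Quantile normalization breaks
ties by average rank; top-gene tables break CV ties lexicographically;
the designated reference defaults to the largest batch with
lexicographic tie-break.

## Known limitations

* The DEG convention (BH at 0.05) is one of several defensible choices;
  absolute DEG counts shift with it, though scheme orderings and
  calibration properties do not.
* The simulated-reference scheme tests each batch against a reference
  that includes its own mean; with few batches this further dampens
  contrast estimates.
* CV on log2 intensities is not shift-invariant; comparisons across
  platforms require a common normalization target.
* The channel-splitting simplification ignores residual within-array
  correlation beyond what the array blocking term captures.
* Pathway sets are treated as disjoint in the generator, while real
  pathway catalogs overlap.
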