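# Methods

This note records the models, conventions and numerical choices behind
`coexpipe`, and what the synthetic-compendium experiments do and do not
establish about real data.

## Pipeline model

The pipeline treats a compendium as a set of *submissions* (one
repository deposit = one batch of arrays with a free-text description)
over a single expression matrix with rows = probes/probe-sets/genes and
columns = arrays. Stages run in a fixed order: duplicate removal → array
QC → summarization → scaling → log2 + mean centering → quantile
normalization → IQR filtering → annotation collapse → (optionally per
category) network construction. Per-category runs restart from the
post-QC raw gene matrix and re-estimate normalization and the filter
threshold independently, because a gene's dynamic range must be judged
against its own category's arrays.

### Duplicates

Exact duplicates are byte-identical array columns, detected by MD5
digests; within a digest group the array from the earliest-sorted
submission id is kept. Near-duplicate submissions are flagged when
descriptions match exactly or when their token-set Jaccard similarity
reaches 0.8 (default); flags are advisory — removal is a curation
decision replayed through an override/exclusion file, since visual or
editorial judgment cannot be automated.

### Array QC

* Scale factor: `target / trimmed_mean(column)` with a 2% two-sided trim
  and target intensity 1000. An array fails when its factor exceeds 3x
  its submission's mean factor; a single-array submission is its own mean
  and cannot fail this rule.
* Spike-ins: control probe-sets (ids prefixed `AFFX`) must have mean
  log2 intensity above 6; otherwise hybridization is considered failed.
* Probe-level model: within each submission, each probe-set's probes ×
  arrays table of log2 intensities is decomposed as
  `overall + probe effect + array effect` by median polish (alternating
  row/column median sweeps, tolerance 1e-8). RLE(g,a) is the fitted
  array-level expression minus its median over the submission's arrays;
  NUSE(g,a) is the residual-based unscaled standard error of the array
  effect divided by the probe-set's median SE, with the 0/0 case (perfect
  fit) defined as 1. An array fails when |median RLE| > 0.075,
  |median NUSE − 1| > 0.075, or either IQR exceeds 0.75; the comparisons
  are strict (>). The model is fit to unscaled log2 intensities, so a
  global brightness shift of an array shows up directly as its RLE
  median.

### Normalization

Probe-set summarization is a Tukey biweight location estimate of the
log2 probe intensities (c = 5, epsilon = 1e-4), iterated to its fixed
point with the scale held at the initial MAD. The iteration matters: the
one-step estimate inherits the sample median's discontinuity, and with
few probes per set that discontinuity contributes jitter comparable to a
quiet gene's biological spread. Stage order after summarization is
scale → log2 (non-positive values floored at 1e-6 × target) → per-gene
mean centering → quantile normalization; a `quantile_first` switch
restores the more conventional quantile-before-centering order. Quantile
normalization maps every column's sorted values onto the across-column
mean of sorted values; tied entries receive the mean of the reference
values at their tied ranks, which makes the transform deterministic and
idempotent to machine precision.

### IQR filtering

Per-gene IQR uses linear-interpolation quantiles (the convention is
pinned because IQR values are convention-sensitive). The survivor
profile is evaluated on a grid of step 0.01 starting at 0; its
derivative is taken by central differences, and the derivative selector
returns the grid point of the most negative derivative, ties broken
toward the smallest threshold. The histogram selector bins IQR values in
bins of width 0.025 anchored at 0 (a value on a bin edge, within float
tolerance 1e-9, belongs to the upper bin) and returns the center of the
fullest bin, ties broken toward the lowest bin. Filtering keeps genes
with IQR ≥ q. On compendia with many low-variance category-specific
genes, the derivative selector latches onto their sharp low-IQR pile-up
while the histogram mode is dragged no lower than that bin's center, so
the histogram threshold is at least the derivative threshold — the
ordering holds on every default synthetic compendium and is exercised
over 20 seeds.

### Annotation

Probe-sets annotated `no_match` or mapping to more than three gene ids
are dropped. Remaining probe-sets are clustered by shared gene ids
(connected components of the sharing graph); each cluster keeps the
member with the fewest gene ids (ties: lexicographically smallest
probe-set id) and is relabeled with the representative's
lexicographically smallest gene id. Both tie-breaks exist only to make
output deterministic.

### Classification

Keyword matching is case-insensitive whole-word matching after light
plural stripping ("roots" → "root", "leaves" → "leaf"), with multi-word
phrases matched as consecutive token runs. The default keyword lists are
a plain-vocabulary reconstruction for a plant compendium and are
configuration, not ground truth; assignments are multi-label and an
override file (add/remove, last wins, audited) replays manual curation.

### Networks

*PCC:* all-pairs Pearson correlation (zero-variance genes excluded). The
significance threshold is empirical-FDR: each of 100 permutations
shuffles every gene's values independently, |r| values pool into a null,
and the threshold is the smallest t with
`(null pairs ≥ t)/permutations / (observed pairs ≥ t) ≤ fdr_level`
(default 0.01); if no t qualifies the network is empty.

*MI:* the fractional B-spline binning estimator. Each sample is
rank-scaled to [0, 1] (average ranks for ties) and assigned fractional
memberships over `n_bins = 10` bins via the B-spline basis of order 3 on
a clamped uniform knot vector; marginal and joint weighted histograms
give the plug-in MI in nats, clamped at 0. Rank scaling makes the
estimate exactly invariant under strictly monotone transforms of either
argument, which also means the estimator can be applied to raw or log2
data with identical results. The network threshold is the
(1 − significance_level) quantile (default 0.01) of MI values from
`permutations = 1000` randomly chosen, independently permuted gene
pairs; edges above it are kept and DPI then removes, in one pass judged
against the original scores, every edge that is the strict minimum of
some triangle and below `(1 − tolerance)` times the smaller of the other
two edges (tolerance 0 by default). Unions of networks with the same
score type take the vertex and edge set union, keeping the larger score
on duplicate edges; "genes in a network" means non-isolated vertices.

**Known estimator bias.** Any estimator built on a 10-bin discretization
estimates the MI of the coarsened distribution, not of the continuous
one. For a bivariate normal with rho = 0.9 the exact MI is 0.830 nats,
the exact MI of its copula discretized to 10 equal-probability bins is
0.728 nats, and the fractional spline weights (a further stochastic
coarsening, by the data-processing inequality) bring the order-3
estimate to ≈ 0.64 at n = 5000. Hard binning (order 1) reaches ≈ 0.73,
and ≈ 0.83 requires ≥ 20 bins. The default settings therefore
systematically underestimate strong dependencies in absolute terms;
network construction is unaffected because the permutation threshold is
relative, but the estimate should not be read as an absolute MI for
highly dependent pairs.

**Threshold semantics and precision.** The pooled null gives per-pair
significance: on a G-gene network roughly
`significance_level × G(G−1)/2` false edges are expected. On a sparse
planted network (5 true edges among 190 pairs) that bounds expected
precision near 0.73 at the default 0.01 level; a user wanting
high-precision sparse networks should lower `significance_level` rather
than expect the default to deliver it.

## The synthetic compendium

The generator emulates, in log2 space: bulk genes with gene-specific
means (N(7, 1)) and spreads calibrated so across-array IQRs are
log-normal around 0.45; category-specific genes (11% of genes, spread
over six categories of 8 submissions × 20 arrays) at a low baseline
(mean 5, sd 0.0278) that switch to a high variable regime (+3, sd 0.7)
inside their own category; per-array residual gains (sd 0.015 log2);
probe expansion with zero-sum affinity offsets (sd 0.15) and residual
probe noise (sd 0.02); spike-in control probe-sets absent in designated
arrays; exact-duplicate columns re-emitted under a new submission;
near-duplicate submissions with copied descriptions and ±0.05 log2
perturbations; outlier arrays with a +1 log2 global shift; decoy
probe-sets exercising annotation cleanup; and planted pairwise
dependencies (linear, quadratic, sinusoidal) of configurable strength,
imposed within the arrays where both genes are active. Genes carrying
planted dependencies receive a generous dynamic range (≥ 1.5× the bulk
median IQR) so that a dependency is not erased by variance filtering —
co-regulated genes vary coordinately by construction.

Several magnitudes are deliberately gentler than real arrays: probe
affinities and residual probe noise are small so that summarization
preserves the calibrated IQR geometry of quiet genes, and per-array
gains are small because the QC probe-level model is fit to unscaled
intensities. Six-plus categories keep a category-specific gene's active
regime under a quartile of the aggregate arrays, which is what collapses
its aggregate IQR. Real compendia have messier probe effects, broader
brightness variation, intensity-dependent (not additive) array
distortions, and correlated — not independent — background genes;
passing tests here show the pipeline's logic and statistics behave as
designed under the stated model, not that real-compendium QC rates or
network sizes are reproduced.

Study-condition fixtures: the default configuration (4500 genes × 960
arrays + duplicates/outliers) drives the filtering phenomena; a 20-gene
× 300-array configuration with five strong planted edges drives
structure recovery; a 400-gene × 300-array five-category configuration
with in-category planted edges drives the partition-vs-aggregate network
comparison at all-pairs-feasible scale. The threshold-selector ordering
is exercised on the generator's direct probe-set-level output
(summarization-free path); the partition comparison runs the full
probe-level pipeline. Structure-recovery fixtures feed the estimators
log2 data without quantile normalization: forcing each array's 20 values
onto a common multiset induces compositional dependence that has nothing
to do with the planted structure (at thousands of genes the constraint
is negligible).

## Degenerate inputs and edge rules

Empty probe-sets, all-zero arrays, constant genes and vectors, single
probe-sets (no residual df: SE defined 0, flagged by convention
NUSE = 1), flat IQR profiles (first grid point, with a warning),
thresholds above every IQR (empty matrix, with a warning), and
fdr/significance levels of 1.0 (everything passes) are all defined
explicitly and tested. All stochastic operations require an explicit
seed; unseeded estimator configurations are rejected.
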