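# Methods

## Scope and data model

The pipeline operates on sparse gene × cell UMI count matrices
(Matrix Market triplet + gene/barcode TSVs, the 10x convention) with
per-gene species tags parsed from concatenated-genome id prefixes
(`GRCh38_` → human, `mm10_` → mouse, untagged → none), per-cell annotation
tables keyed by barcode, and per-axon / per-ROI morphometry tables in μm².
It does not touch reads: alignment, anchor-based integration and UMAP
visualisation are out of scope, and the split matrices produced by
demultiplexing stand in for per-species realignment.

## Synthetic data

All inputs can be generated with known ground truth; the generators are pure
functions of their configuration (seed included).

**Counts.** Gene/cell counts are gamma-Poisson (negative binomial with size
parameter `dispersion`, variance μ + μ²/φ) around class-specific means:
every class owns a disjoint block of `markers_per_class` genes whose mean is
`base_mean × marker_fold`, all other genes sit at `base_mean`. Each entry is
then zeroed with probability 1 − σ(`dropout_slope` · (ln μ −
`dropout_midpoint`)) — logistic dropout on the log mean, the minimal
mechanism that produces the detect/non-detect structure the binarized
classifier exploits. Defaults (8 classes, 500 genes, 200 cells/class, 10
markers/class, base mean 0.5, fold 8, dispersion 2, dropout midpoint
ln 0.1 ≈ −2.3, slope 1) give marker detection rates near 0.9 inside the
owning class and ~0.3 elsewhere, in the range droplet data shows for good
markers.

**Domain shift.** The unlabelled target shares the source's classes and
genes, but every gene's mean is multiplied by a log-normal(0,
`domain_shift_sd`) factor fixed per gene (default sd 0.3). This is the
simplest shift that breaks naive nearest-centroid transfer while preserving
marker detection ranks. The label set is closed: target cells always receive
some source label, mirroring a classifier with no reject option — novel
target classes would be forced into source labels, which the simulator
documents rather than hides.

**Chimera.** Each cell draws counts over its own species' genes from a flat
profile; a binomial `contamination_fraction` of every count is removed and
reassigned uniformly over the other species' genes (ambient cross-mapping).
Fractions ≥ 0.3 are rejected — beyond that the 70 % allocation rule is not
meaningful.

**Two-group expression.** Two equal groups; a leading fraction
`frac_de_genes` of genes has its group-B mean scaled by 2^±`effect_log2fc`
(alternating signs); `effect_log2fc = 0` or `frac_de_genes = 0` yield exact
nulls for type-I calibration.

**Morphometry.** Axon diameters are log-normal (median ≈ 0.82 μm, log-sd
0.35, spanning the sub-0.4 μm exclusion zone); a per-axon g-ratio is drawn
normal(`g_mean`, `g_sd`) and areas are derived assuming circular
cross-sections, so √(axon/outer area) recovers the drawn g exactly.
Mitochondrial area fractions are gamma with mean `mito_fraction`
(shape 20), split into 1–3 puncta. A companion puncta generator emulates
RNAscope ROI tables (Bernoulli OLIG2 status, Poisson puncta).

**What the simulators do not emulate:** ambient-RNA profiles or doublets,
spliced/unspliced layers, batch structure beyond the multiplicative shift,
library-size gradients within a class, spatial structure, or non-circular
axon geometry. Passing tests therefore demonstrate correctness of the
implementations and recoverability under the stated statistical model, not
performance on real tissue data.

## Preprocessing

- **Gene QC** removes genes detected in ≤ `min_cells_per_gene_exclusive`
  cells (default 10; a gene must be seen in strictly more than 10 cells).
- **Cell QC** flags cells outside median ± 3 scaled MADs (×1.4826, so 3 MADs
  ≈ 3 σ for normal metrics) on log total UMIs and log detected genes
  (two-sided) or above a mitochondrial-fraction ceiling (one-sided); a zero
  MAD (most cells identical on a metric) leaves that bound open. Removing
  more than 90 % of cells aborts unless forced. The numeric thresholds are
  this package's choice; only the criteria themselves are inherited.
- **Normalisation** divides counts by per-cell size factors rescaled to
  geometric mean 1 and stores ln(count/sf + 1). The default `median_ratio`
  basis computes DESeq-style median ratios against a geometric-mean
  reference over genes detected in every cell, and falls back to
  library-size factors when fewer than 20 such genes exist (the usual case
  for sparse droplet data). Downstream methods depend only on a monotone
  per-cell scaling, so the two bases are interchangeable in practice.
- **Variable genes** are ranked by standardized variance computed on
  depth-corrected counts against the one-parameter quasi-NB trend
  var = μ + φμ² with φ the median of per-gene moment estimates. A flexible
  (polynomial or loess) trend was rejected deliberately: with discrete mean
  structure — markers being the only genes at their mean — a mean-local fit
  tracks the marker cluster and flattens exactly the excess variance being
  sought. The parametric trend is anchored by the null-gene majority.
- **PCA** centers (and by default unit-scales) the selected genes and takes
  an exact SVD; each component's sign is fixed so its largest-magnitude
  loading is positive, making embeddings bit-reproducible.
- **Elbow selection** walks the variance spectrum and returns the first
  component at which the successive drop falls below `drop_fraction`
  (default 0.10) of total variance *after* at least one large drop has been
  seen; a spectrum with no large drop has no elbow and yields the cap. A
  floor (default 5) guards against overly aggressive truncation.
- **Clustering** builds a k-nearest-neighbour graph (Euclidean in PC space,
  default k = 20) with shared-neighbour Jaccard edge weights and maximises
  modularity with seeded Louvain (resolution 1.0). Labels are contiguous
  integers ordered by cluster size.

## Species demultiplexing

The per-cell human fraction is computed over species-tagged genes only, on
UMI counts by default or detected genes as an alternative basis (the
phrase "gene mapping" is ambiguous between the two; both are implemented
and the choice is logged). A cell is called human iff the fraction is
≥ `min_fraction` (default 0.70, boundary inclusive), mouse iff the
complement is, and ambiguous otherwise; `min_fraction` > 0.5 makes the
calls mutually exclusive, and cells with zero species-assignable signal are
flagged. Ambiguous cells are dropped from both split matrices but retained
in an audit list.

## ANN identity transfer

The feature space is the sorted union of source and target variable genes;
its size F is always data-derived. Expression is binarized to detection
(UMI > 0). Each ensemble member is

    p = softmax(relu(relu(X·W1 + b1)·W2 + b2)·W3 + b3)

with hidden sizes 64 and 32 and an L1 penalty (λ = 0.001) on W1 and W2 only
— biases and the output layer are unpenalised. Training minimises mean
cross-entropy (+ penalty) by RMSprop (η = 0.001, ρ = 0.9, ε = 1e-7) on
class-balanced minibatches: every gradient step samples 16 examples per
class with replacement, so the effective class prior is uniform regardless
of composition. Labels are split into stratified folds (5 by default, 3
supported); model i trains on all folds but i and records validation
balanced accuracy per epoch on fold i. "Step size 256" is read as 256
gradient steps per epoch (the batch size is already fixed by the generator
at 16 × K); the schedule is fully configurable, with 100 epochs as the
desk-run default and 1000 available by config. Weights are Glorot-uniform
initialised from the seeded generator; training is plain NumPy and
bit-reproducible. Probabilities are clipped at 1e-12 inside the log so the
loss stays finite.

Target cells are labelled by plurality vote over the ensemble's per-model
argmax labels; ties are broken by the highest mean softmax probability and
flagged. There is no reject option (a confidence threshold exists in the
configuration but defaults off). Evaluation reports balanced accuracy
(mean per-class recall), macro precision/recall (classes absent from the
predictions contribute precision 0), and the confusion matrix.

## Cluster comparison

Cluster profiles are per-cluster mean log-normalised expression restricted
to the shared ANN feature space (a detection-frequency profile is available
by configuration; the choice is logged since published heatmaps do not pin
the profile space). Similarity is the plain cosine; zero-norm profiles
yield flagged NaNs. Composition comparison computes cluster × condition
fractions and a per-cluster two-proportion z-test, BH-adjusted across
clusters.

## Hurdle differential expression

For each gene, detection (value > 0) is regressed logistically on the group
indicator plus optional covariates (sample identity by default; per-cell
detection rate supported), and log-normalised expression among detected
cells is regressed by ordinary least squares on the same design. The
likelihood-ratio statistics for the group term are summed across parts and
referred to χ² with the summed degrees of freedom. A part contributes 0 df
when it carries no information: detection constant, fewer than 3 detected
cells, or a rank-deficient continuous design. The logistic fits use
Newton-Raphson with a 1e-8 ridge; suspected separation (diverging
coefficients) triggers a 1e-4 ridge refit and a flag. Testing is performed
at the cell level with a sample covariate rather than on pseudo-bulk
aggregates — the two readings coexist in the source material and the
cell-level hurdle is the one matching the stated model class.

log2 fold changes are computed on back-transformed (expm1) normalised group
means with pseudocount 1, the dominant single-cell convention. The marker
screen pre-filters genes (log2FC > 0.25, detection ≥ 20 % inside the
cluster, < 60 % outside — the 60 % bound strict) before testing
cluster-vs-rest, with BH applied within each cluster's tested set. The
condition contrast uses the symmetric pre-filter |log2FC| > 0.25 with
max(pct) ≥ 20 % — the one-sided "outside" bound is meaningless for a
two-sided contrast and would break the exact up/down swap under recoded
conditions — then applies |log2FC| ≥ 0.5 and BH-adjusted p < 0.05 to the
survivors. BH is a hand-rolled step-up with enforced monotonicity, verified
against an independent oracle.

## Morphometry

Diameters come from areas via d = 2√(A/π) (circularity); the g-ratio is
√(axon area / outer area) ∈ (0, 1]. Axons with diameter < 0.4 μm are
excluded as unmyelinated small-calibre fibres — the exclusion is strict, so
a 0.40 μm axon is kept. Myelinated-axon percentages are computed per animal
(axons with uncompacted membranes count as unmyelinated) and summarised as
mean ± SEM *across animals* — the animal, not the axon, is the unit of
inference; per-object tables are emitted alongside to show the spread.
Mitochondrial load is reported three ways (count, total area, area
fraction) since an area increase cannot distinguish number from size. The
RNAscope composite score is (fraction OLIG2⁺ cells) × (mean puncta over all
cells) per ROI, summarised per animal then per condition.

Group comparisons check normality per group with a Kolmogorov–Smirnov
statistic using estimated parameters, with the p-value from a seeded
Monte-Carlo null (default 1000 simulations) of the same statistic —
the Lilliefors correction done by simulation because the closed forms are
approximate. Both groups normal at α = 0.05 → two-sided unpaired t-test;
otherwise two-sided Mann–Whitney U; the chosen path is recorded. Groups of
fewer than 4 animals skip the normality check (treated as normal) since the
statistic carries no power there.

## Reproducibility and numerics

A single run seed is expanded into per-stage substreams by hashing the
stage name into a `SeedSequence` spawn key, so reordering stages cannot
change any stage's stream; derived seeds stay below 2³¹. Fixed seed implies
byte-identical output files, which the test suite verifies by hashing two
complete pipeline runs. Tolerances: PCA is checked against a dense
eigendecomposition at 1e-8; the backprop gradient against central finite
differences at 1e-5; the hurdle statistic against direct ML optimisation at
1e-6.

## Validation experiment sizes

The standing validation experiments (see `oligomap.benchmarks`) use an
8-class, 500-gene, 200-cells-per-class transfer fixture with a 100-epoch ×
64-step 5-fold schedule; a 2000-gene, 100-cells-per-group null for hurdle
calibration; a 1000-cell chimera at 5 % contamination for demultiplexing;
120-cell planted blobs for clustering; and a 2000-cell chimera pipeline run
executed twice for hash stability. The `run-all` pipeline defaults to a
light smoke schedule (3 folds, 30 epochs × 64 steps) since its purpose is
end-to-end integrity rather than peak accuracy. These sizes are the
package's chosen desk-scale study conditions; the generators accept larger
values.

## Known limitations

- The hurdle test treats cells as exchangeable given covariates; it does
  not model per-sample random effects, so heavy pseudo-replication across
  few samples can inflate significance on real data.
- The classifier has no reject option: out-of-reference cell states will be
  assigned the nearest reference label with possibly high confidence.
- Louvain clustering quality depends on k and resolution; the defaults are
  tuned for a few hundred to a few thousand cells.
- Median-ratio size factors fall back to library-size scaling on sparse
  data, which is biased when a large fraction of counts is differentially
  expressed between cell populations.
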