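# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the open design choices behind `styletax`.

## Search pipeline

Trials are cleaned in two steps, in this order:

1. **Fast-guess exclusion.** Trials with RT < 150 ms are dropped (they
   reflect accidental double-clicks, not discrimination). The threshold is
   inclusive: RT = 150 ms is retained.
2. **Winsorization.** The mean and SD of the retained RTs are computed once
   (population SD, ddof = 0 — the convention is stated here because either
   choice is defensible and they differ at small n); every RT outside
   mean ± 3.5 SD is projected onto the nearer bound. Values inside the band
   are untouched, so re-projection with the original moments is idempotent.
   With fewer than 2 trials or zero SD the step is a flagged pass-through.

Exclusion precedes winsorization so that artifact trials do not contaminate
the moment estimates. Winsorization is global over the dataset rather than
per subject or per cell: it is the simplest defensible scope, and the run
report records the moments and clamp counts so the choice is auditable.

Per ordered (target, distractor) pair: accuracy is the fraction of trials
whose response location equals the target location; mean RT by default uses
all retained trials (correct and incorrect), with a `correct_only` flag.
Effective RT is the cell-wise quotient RT/accuracy; a cell with accuracy 0
receives the +inf sentinel, whose inverse is distance 0 (the continuous
limit: a pair never discriminated is maximally similar). The symmetric
distance is the arithmetic mean of the two ordered inverses, diagonal 0.
Cells with no trials stay NaN and block clustering with an error naming the
pair — silently imputing a distance would corrupt the tree.

The asymmetry matrix is eff(i,j) − eff(j,i) (antisymmetric by construction);
a directed relation i→j is emitted when the difference exceeds a
configurable threshold (default 0, sign only), pointing from the style that
is harder to find as a target toward the easier one.

## Gaze pipeline

Fixations for each (motif, style) stimulus — pooled over the subjects who saw
it — are binned into a G×G grid (default 10) over the image rectangle
(824 px square centered on a 1280×1024 screen; both are configuration, not
constants). Bins are half-open with the last row/column closed, exactly
`numpy.histogram2d`'s convention; fixations outside the image are discarded
and counted, not clipped into edge cells (clipping would inflate the border).
Maps are normalized to unit mass; the grand bias is the *unweighted* mean of
all normalized maps (every map counts equally regardless of its fixation
count), and bias-subtracted maps therefore sum to 0 to within accumulated
rounding (~1e-15, tested at 1e-9).

Maps carry an explicit state tag (`raw_counts → normalized →
bias_subtracted`) and every stage enforces its input state, so the pipeline
cannot, e.g., correlate maps that still contain the center bias.

Per motif, bias-subtracted maps are flattened row-major and correlated
pairwise (`scipy.stats.pearsonr`, two-sided p). Zero-variance maps produce a
NaN cell with a warning instead of a fabricated 0. Per-image p-values are
retained but never meta-combined; the dataset-level matrix is the cell-wise
mean of r over the motifs where the cell is defined, with the count
recorded. Clustering uses d = 1 − r̄ (an `arccos` rule is available); 1 − r
is the standard monotone conversion, and only the ordering matters for the
tree topology.

## Average linkage and tree comparison

UPGMA is implemented directly: at each step the two clusters with the
smallest unweighted mean pairwise inter-cluster distance merge at that mean.
Ties break toward the lexicographically smallest pair of (sorted) cluster
label tuples, making the merge sequence a pure function of the input — a
requirement for reproducible pipelines, where scipy's internal ordering
would be an implementation detail. scipy's `linkage(method="average")`
serves as an independent cross-check in the test suite, alongside a
brute-force oracle that recomputes every cluster-pair average each step. A
weighted (WPGMA) variant sits behind a flag. Average linkage cannot invert
heights, so trees are ultrametric.

Tree comparison reports (a) the Robinson–Foulds symmetric difference over
non-trivial bipartitions, which is invariant to any monotone rescaling of
heights, and (b) the Pearson correlation of cophenetic upper triangles,
which is not scale-free and is only meaningful when both trees carry real
heights. The art-historical reference tree ships with ordinal placeholder
heights (the source figure specifies topology only), so against it only the
topology distance is interpretable; the code and the comparison script both
say so.

Newick import requires an ultrametric tree: leaf-pair patristic distances
are halved to cophenetic heights and UPGMA on that matrix rebuilds the merge
list exactly. Round-trips preserve topology and heights to 1e-9.

## Synthetic-data generator

The generator emulates the two experimental designs exactly:

* **Search design:** every ordered style pair once per block (56 pairs for 8
  styles), blocks shuffled per seed, 4 blocks = 224 trials per subject,
  motifs assigned without repetition within a subject from a pool whose
  required size is checked.
* **Gaze design:** each subject sees |S|·motifs-per-style stimuli
  (240 = 8×30 by default), each motif exactly once in exactly one style,
  one stimulus of each style per consecutive block; styles rotate across
  subjects in a Latin design so each (motif, style) stimulus is seen by
  n_subjects/|S| subjects (8 of 64), reproducing ~128 fixations per image at
  16 per subject.

**Planted taxonomy.** Ground truth is an ultrametric tree; planted distances
are cophenetic heights divided by the tree height, so D ∈ [0, 1]. The
default 8-style tree mirrors the art-historical shape with well-separated
merge heights {0.25, 0.5, 0.75, 1.0}.

**Search behavior.** Accuracy follows the saturating psychometric family
p(D) = chance + (1 − chance)(1 − e^(−λD)) with chance = 1/4 (four response
locations) and gain λ = 3, spanning ~25 % to ~96 % over D ∈ [0, 1] — the
simplest monotone family that couples accuracy to similarity. RTs are
lognormal with median e^(0.7 − 0.6·D) seconds and shape σ = 0.8; the
location/shape were set from the observed scale of such experiments
(pair-averaged mean ≈ 2.2 s, median ≈ 1.6 s), and the negative slope makes
similar pairs slower, matching the empirical RT–accuracy coupling. Fast
guesses occur at rate 2 % with RT uniform on [0.05, 0.15) s — deliberately
inside the excluded band so the exclusion rule's effect is observable — and
5 % of trials get a heavy-tailed RT inflation (×(1 + Exp(2))) emulating
lapses, which the winsorization step absorbs. An optional lognormal
per-subject intercept (off by default) models inter-subject heterogeneity.

**Gaze behavior.** The fixation density for a stimulus is a convex mixture
(weights 0.35/0.35/0.30) of: a motif content field shared across styles; a
style field; and a central Gaussian (σ = 0.22 of the image side) emulating
center bias. Style fields come from Brownian diffusion along the planted
tree — each edge contributes an independent Gaussian increment with variance
proportional to its normalized length — so two styles share exactly the
increments above their lowest common ancestor and
corr(field_s, field_t) = 1 − D(s,t), the generator's stated similarity rule
(Monte-Carlo verified). Fields are smoothed (Gaussian, σ = 1 cell on a 20×20
fine grid) and exponentiated (softmax with gain 8) into densities; fixation
counts are Poisson(16) per subject per stimulus and positions are i.i.d.
cell-then-uniform draws, always inside the image.

The field gain matters: it sets the density contrast, and with ~128
fixations per map the multinomial sampling noise is substantial. The default
gain makes the per-map style signal comparable to that noise; far lower
gains leave densities near-uniform and the taxonomy unrecoverable at any
fixation count the design provides, which would defeat the generator's
purpose as a recovery benchmark.

**Seeding.** One integer seed per model/design call feeds named
`numpy.random.SeedSequence` substreams (design, trials, gaze design,
per-motif fields, sampling), so identical seeds give bit-identical outputs
and the stages can be re-run independently.

**What the generator does not emulate.** No saccades, scanpaths, or fixation
durations; no oculomotor main sequence; no image content (content fields are
abstract smooth random fields, not salience maps); no inter-subject strategy
differences beyond the optional RT intercept; independence of fixations
within a viewing (real fixations are autocorrelated). Passing recovery tests
therefore show the *pipelines* are correct and adequately powered at the
experiment's scale — they do not show that real art styles satisfy the
generative assumptions.

## Problem sizes used in tests and the acceptance script

Search recovery uses 20 replicates at 500 trials per ordered pair (28 000
trials per replicate); gaze recovery uses the full design scale (64
subjects, 240 motifs, ~246 000 fixations); chance calibration uses 10⁵
trials per cell on 8 cells; linkage oracle equivalence uses 100 random
matrices of 3–7 leaves; conservation checks use a 240-motif dataset at 8
subjects. These sizes make every stochastic check decisive (3-SE bands,
permutation nulls) while the whole suite stays fast.

## Known limitations

* Effective RT conflates speed and accuracy in a fixed ratio; no
  speed–accuracy tradeoff modeling is attempted.
* The per-image Pearson correlations are computed over 100 grid cells that
  are spatially autocorrelated; the reported per-image p-values inherit that
  and should be read descriptively, which is one reason the dataset-level
  matrix averages r only.
* Cophenetic correlation against a tree with arbitrary heights (the
  reference taxonomy) is not meaningful; use the topology distance.
* The winsorization scope (global) and the RT matrix population (all
  retained trials) are conventions; both are configurable and recorded in
  the run manifest, and the run report exposes both the clamped and the
  excluded fractions since "outlier rate" can reasonably mean either.
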