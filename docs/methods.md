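# Methods

This note records the models and conventions the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical corner cases. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Normalization

Size factors use the median-of-ratios estimator: reference genes are those
with strictly positive counts in every sample; the pseudo-reference is the
per-gene geometric mean; the factor of sample *j* is the median over
reference genes of count/reference ratios. Medians over an even number of
ratios resolve to the arithmetic midpoint of the two central *linear-scale*
ratios (not the geometric midpoint a log-space median would give). Factors
are not rescaled to unit geometric mean, matching the conventional
estimator; consequently the meaningful invariants live on factor *ratios* —
scaling one sample's counts by c scales its factor relative to every other
factor by exactly c, and re-estimating factors on normalized counts yields a
common constant (near, but not exactly, 1) for every sample. The literal
forms "the other factors are unchanged" and "second-round factors are 1"
do not hold for this estimator, because scaling any sample also moves every
per-gene geometric mean; the tests assert the ratio forms.

A practical caveat surfaced by the simulations: median-of-ratios assumes the
median gene is stable across samples. When a large majority of the
transcriptome moves (as in a dedifferentiation course where most genes
reverse), the factors absorb part of the trend unless the up- and
down-moving mass is balanced. The synthetic designs used for parameter
recovery are therefore constructed log2-symmetric (see below); on real data
this caveat is inherent to the estimator, not to this implementation.

Replicate averaging is the arithmetic mean per (condition, time). All log
transforms are log2(x+1) on normalized counts (log10(x+1) in the
single-cell module, which scores cells on that scale); the pseudocount of 1
keeps zero counts at zero and is configurable everywhere.

## Trajectory PCA and gene selection

PCA input is replicate-averaged, size-factor-normalized, log2(x+1) data,
filtered to genes with mean normalized count strictly above 10, gene-centered
and *not* unit-scaled: variance weighting by expression level is intended,
since the selection step interprets squared loadings as variance shares.
Samples are observations; the decomposition is the SVD of the centered
matrix. Each loading column is sign-fixed so its largest-magnitude entry is
positive; every downstream statistic is invariant to this choice. Requesting
more components than the data's numerical rank reduces to the rank with a
warning.

A gene's contribution to component *k* is its squared loading (unit-norm
columns make these sum to one). Selection ranks genes by contribution and
takes the shortest prefix whose cumulative contribution reaches the target
fraction — 0.10 by default for the clustering gene set, 0.25 for broader
sample characterisation. The prefix is minimal by construction: dropping its
last gene falls below the target. Projection of new samples (e.g. mutant
time courses) subtracts the training centers and applies the training
loadings; it refuses to run when model genes are missing rather than
imputing.

## Gene panels, symmetry and the overlap null

All threshold rules operate on linear-scale normalized counts with
pseudocounted fold changes:

- changing genes: normalized count > 100 at some timepoint AND
  |log2((v_t+1)/(v_0+1))| > 1 for some t ≠ 0;
- direction over a window (t0, t1): up/down when the pseudocounted fold
  change across the window exceeds 2 (or its inverse), else flat; window
  endpoints must be sampled timepoints — no interpolation;
- aggregation-specific: mean(4,6,8 hr) > 2 × mean(0,2 hr) and
  > 2 × mean(10,12,14 hr) of the development course;
- early-induced: the global maximum of the dedifferentiation profile occurs
  at t ≤ 2 hr (ties resolve to the earliest timepoint) and exceeds the 0 hr
  level by more than 50%. The alternative reading — any > 1.5-fold rise
  within the horizon regardless of where the global maximum lies — is
  implemented as `mode="any_rise"`; the global-max reading is the default
  because "maximally induced" most naturally refers to the profile's
  maximum;
- transient induction: some interior timepoint exceeds 2 × the 0 hr level
  (pseudocounted) and the final timepoint has fallen back below that
  threshold.

The symmetry statistic is |A ∩ B| / |A| for A = genes up (down) in both
dedifferentiation media over their steep windows and B = genes down (up)
during development; "both media" means passing the direction rule in liquid
AND bacteria.

The overlap permutation test draws |panel| genes uniformly without
replacement from the supplied universe (by default every annotated gene, not
the expression-filtered subset) and records the overlap with the induced
set. The sampled-mode empirical p is the add-one estimator (1+k)/(N+1),
which never returns zero — an observed overlap larger than all 10,000 draws
reports p = 1/10001. When C(|universe|, |panel|) ≤ 10⁶ the test can
enumerate every panel (`method="auto"`/`"exhaustive"`, via true subset
enumeration, not the hypergeometric closed form — the hypergeometric stays
an independent oracle in the tests); exhaustive mode reports the exact tail
fraction instead of the add-one estimate.

## Temporal clustering

Profiles are z-scored per gene with the sample (n−1) standard deviation;
constant rows are dropped and listed rather than propagating NaNs.
Clustering is agglomerative with distance 1 − Pearson correlation and
average linkage — correlation distance groups temporal *shapes* regardless
of amplitude, which is what temporal classes mean; Euclidean/Ward is
available by argument. k is user-chosen; no automatic model selection is
attempted. Two-way (gene × sample) clustering is reduced to gene-side
clustering with samples kept in time order, since the time ordering carries
the interpretation.

## Single-cell module

Cells are scored per marker panel as the mean of log10(count+1) over panel
genes; no per-cell depth normalization is applied to scores (the quantity
visualised is mean log counts), though the PCA accepts a depth option.
Marker selection from a differential table applies |log2FC| > 1, FDR < 0.1
and maximum normalized count > 100; when the table carries raw p-values the
Benjamini–Hochberg step-up procedure computes the q-values. Single-cell PCA
runs on log10(count+1) of genes detected in at least 1% of cells (an
unstated-but-necessary filter, configurable).

The convergence statistic operationalises trajectory merging: per sampling
hour, cells above the 80th percentile of the prestalk score (the same split
used for reporter intensity in the imaging arm) form the prestalk-high
group, and the curve is the Euclidean distance between that group's centroid
and the remainder's in (prestalk score, prespore score) space. Hours with
fewer than two cells in either group are reported missing, not raised. The
merge hour is the first hour the curve falls below 25% of its initial
value. Note the curve has a selection-bias floor: even in fully converged
data the top-quantile split produces a small positive distance of order the
score noise, so the curve plateaus at the noise floor rather than at zero.

## Cell-track module

Frame speeds are consecutive-frame displacements over Δt (µm/min); the
rolling speed is a centered box average over a 10 min window on interval
midpoints; persistence is net displacement over path length and is reported
absent (None) for a stationary window (0/0). Speed-profile clustering is
Ward/Euclidean on the rolling-speed vectors of tracks sharing one time grid
(unequal grids are an error instructing resampling); labels are renumbered
so cluster 1 is slowest, and an all-identical input is flagged degenerate
instead of raising. The division association is the Pearson chi-square
without continuity correction on the cluster × divided 2×2 table, with p
from the 1-df chi-square distribution. Censored tracks shorter than the
capture horizon are the caller's responsibility to exclude.

Reporter onset fitting minimises least squares over the continuous
two-segment model y = c + r·max(0, t − t0), with candidate breakpoints
restricted to observed sample times (avoiding sub-sample interpolation
ambiguity) that leave at least two baseline and two ramp samples. A trace is
inducing when the fitted slope is positive and the ramp's total rise
r·(t_end − t0) exceeds 3× the baseline-segment residual sd; thresholding the
*rise* rather than the slope makes detection depend on how far the ramp
clears the noise floor, not on its steepness, so shallow-but-long planted
ramps at 5% noise are detected while flat noisy traces are rejected. Onset
resolution is therefore the sampling step. Coupling statistics use Pearson r
for onset vs division time over inducing dividers (a rank option exists),
the two-sided Wilcoxon rank-sum for induction rates of dividers vs
non-dividers, and the fraction of inducing dividers whose onset precedes
division; missing pieces are flagged in the report rather than raised.

## Synthetic data

The generators emulate the study design, not its measured data: two
replicates of a 0–14 hr development course, 0–24 hr dedifferentiation
courses in two media, a buffer control stuck at the 0 hr state, and an
undifferentiated reference; hourly single-cell samples 0–6 hr from two
fates (20% prestalk / 80% prespore); 120 tracks at 30 s frames from a slow,
frequently dividing and a fast, rarely dividing cluster (1 vs 8 µm/min,
division probabilities 0.9 vs 0.1); and 100 flat-then-ramp reporter traces.
Bulk counts are negative binomial with variance m + α·m² around piecewise-
linear log2 mean profiles drawn from a small archetype library (reversing
up/down, dediff-specific, dediff-repressed, dev-specific, aggregation-
transient, biphasic cell-cycle, unchanged); α defaults to 0.1 (a moderate
biological CV of ~32%), per-library depth factors are log-uniform on
(0.7, 1.4), and α = 0 degenerates to exact rounded means for tests. Each
generator consumes its own RNG stream derived from (seed, generator offset),
so fixed seeds give bit-identical output and consuming one generator never
perturbs another.

Archetype assignment uses deterministic largest-remainder counts, so planted
fractions are exact. The recovery design for the symmetry statistic
(80% reversing genes) pairs every moving block with its log2 mirror —
reversal-up with reversal-down, dediff-specific with dediff-repressed — so
that the count distribution is symmetric at every sample and the
median-of-ratios reference stays pinned; without that symmetry the size
factors drift with the moving expression blocks and flat genes acquire
spurious fold changes (a genuine property of the estimator under
composition shift, not a bug).

Single-cell marker means are placed on the log10 score scale so that the
planted fate-score separation decays by 2^(−hour/half-life); the default
half-life of 1.25 hr puts the planted merge (separation below 25%) at the
3 hr sample. Background genes ramp monotonically with hour to give the data
a time axis. Counts are Poisson; the convergence-off and instant-convergence
limits are obtained by setting the half-life to None or near zero.

What the generators do *not* emulate: mapping artefacts, batch effects,
gene–gene correlation beyond the archetype structure, zero-inflation or
ambient RNA in the single-cell counts, realistic persistence/turning
statistics, or any coupling between the reporter traces and the track
divisions. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise models, not robustness to artefacts real
data may carry.

## Problem sizes and determinism

The shipped analyses use 2,000 genes, 76 libraries, 924 cells, 120 tracks
and 100 traces — sizes chosen so every driver and the full test suite run in
seconds while keeping each statistic's sampling error well inside its test
tolerance. Every randomised operation takes an explicit seed; the pipeline
driver writes a manifest (inputs, parameters, seed, package version) and
re-running an identical configuration reproduces every output byte for
byte.

## Known limitations

Real-data headline figures depend on unstated upstream choices (whether the
published PCA used log-transformed counts, the exact clustering linkage,
the universe used for random sampling); the defaults here are logged,
configurable conventions, and gene counts obtained on other datasets should
be expected to shift with those choices. The convergence statistic and the
onset-detection rule are this package's operationalisations of analyses the
source material describes qualitatively; both are documented above and
exposed with their parameters.
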