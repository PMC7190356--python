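# dediff

Analysis pipeline for *Dictyostelium discoideum* dedifferentiation: when
multicellular aggregates are disaggregated into nutrient media, partially
differentiated cells reverse development and return to growth within hours.
This package implements the quantitative procedures such a study needs — bulk
time-course trajectory analysis, threshold-based gene classification,
permutation nulls for gene-set overlap, single-cell fate convergence, and
cell-track event statistics — as a tested library (`src/dediff`) driven by
numbered analysis scripts (`analysis/`), exercised end to end on a synthetic
data generator that plants known ground truth.

It is written for computational biologists who want the individual statistics
as reusable functions and for reviewers who want every threshold, seed and
null model explicit and replayable.

## What it computes

**Trajectory PCA with loading-contribution selection.** Libraries are
normalized by median-of-ratios size factors
(s_j = median_g [ c_gj / (∏_j' c_gj')^{1/m} ] over genes with nonzero counts
in all samples), replicate-averaged, filtered to genes with mean normalized
count > 10, log2(x+1)-transformed and gene-centered; PCA treats samples as
observations. Because each loading column **w**_k has unit norm, w²_gk
partitions PC k's variance over genes; ranking genes by w²_gk and taking the
shortest prefix whose cumulative contribution reaches a target share (10% for
clustering, 25% for sample characterisation) gives the "genes carrying the
component".

**Gene panels and symmetry.** A gene changes during dedifferentiation when
its normalized count exceeds 100 at some timepoint and |log2FC| vs 0 hr
exceeds 1. Direction over the steep trajectory windows (development 2–6 hr;
dedifferentiation 0.5–4 hr in liquid, 0.5–5 hr on bacteria) uses a two-fold
threshold; the symmetry statistic is the fraction of genes up in both media
that are down in forward development (and vice versa). Aggregation-specific
genes have mean expression over 4–8 hr of development more than twice both
the 0–2 hr and the 10–14 hr means; early-induced genes reach their global
dedifferentiation maximum within 2 hr at more than 1.5× the 0 hr level. The
overlap of two panels is tested against panels of the same size drawn
uniformly from the genome (10,000 draws; empirical p = (1+k)/(N+1), exact
enumeration on small universes).

**Temporal classes.** Z-scored log2 profiles are clustered agglomeratively
with 1 − Pearson correlation and average linkage; transient inductions rise
more than two-fold above 0 hr at an interior timepoint and fall back by the
end.

**Single-cell convergence.** Cells sampled hourly (0–6 hr) are scored by the
mean log10 count over prestalk (48) and prespore (42) marker panels (markers:
|log2FC| > 1, FDR < 0.1, > 100 molecular counts in ≥ 1 cell). Per hour, the
Euclidean distance between the prestalk-high (top 20% by prestalk score)
subpopulation centroid and the remainder in (prestalk, prespore)-score space
measures fate separation; the merge hour is where it first drops below 25%
of its initial value.

**Cell tracks.** Frame speeds at 30 s intervals, 10 min rolling averages,
persistence (net displacement / path length), Ward clustering of speed
profiles into slow/fast populations, a 2×2 chi-square (no continuity
correction) linking cluster to division, a flat-then-ramp least-squares
changepoint fit for reporter onset time and rate, and Pearson/rank-sum
statistics coupling onset and rate to the first division.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_bulk_trajectory.py
python analysis/03_gene_panels.py
```

prints (seed 0):

```
bulk: 2000 genes x 76 libraries
...
PC1: 81.0% of variance
104 genes carry 10.0% of PC1 variance (target 10%)
...
of 701 genes up in both media, 77% are down during development
of 737 genes down in both media, 74% are up during development
aggregation panel (160 genes) vs early-induced: observed overlap 98%, null median 9%, p = 0.0001
```

PC1 separates undifferentiated from developed states and carries most of the
variance because the planted design reverses the majority of genes; the
symmetry fractions say that roughly three quarters of genes induced during
dedifferentiation in both media are exactly the genes switched off during
forward development. The aggregation panel recovers the planted transient
archetype, and its overlap with early-induced genes is far outside the
random-panel null (no null draw reached the observed overlap, hence
p = 1/10001). Scripts 04–06 add temporal classes, the single-cell
convergence curve (fates merge at 3 hr, matching the planted schedule), and
the track statistics (slow cells divide more; chi-square ≈ 80).

The same steps run from the command line via the `dediff` umbrella
(`dediff simulate|normalize|pca|panels|permtest|cluster|sc|tracks|run`).

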