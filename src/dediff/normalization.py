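"""Size-factor normalization, replicate averaging and log transforms.

Per-sample depth is estimated with the median-of-ratios estimator: the
reference profile is the per-gene geometric mean over samples (restricted to
genes with nonzero counts in every sample), and a sample's size factor is the
median of its count ratios to that reference.  Dividing by the factors makes
samples comparable without letting a handful of highly expressed genes drive
the scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, EstimationError, InputError, NormalizedMatrix


def compute_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with strictly positive counts in all samples;
    their per-gene geometric mean forms the pseudo-reference profile.
    Raises :class:`EstimationError` when no gene is positive everywhere.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "size factors undefined: no gene has nonzero counts in every sample"
        )
    ref = mat[positive]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geo_mean[:, None]
    # even-n medians resolve to the arithmetic midpoint of the central ratios
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def normalize(counts: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in counts.counts.columns if s not in factors.index]
    if missing:
        raise InputError(f"size factor missing for samples: {missing}")
    if (factors.loc[counts.counts.columns] <= 0).any():
        raise InputError("size factors must be positive")
    norm = counts.counts / factors.loc[counts.counts.columns]
    return NormalizedMatrix(
        norm, counts.samples.copy(), size_factors=factors.loc[counts.counts.columns]
    )


def average_replicates(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Arithmetic mean over replicates: one column per (condition, time).

    Single-replicate groups pass through unchanged.  Averaged sample ids are
    ``{condition}_t{time}``.
    """
    groups = norm.samples.groupby(["condition", "time_hr"], sort=False).groups
    cols = {}
    rows = []
    for (condition, time_hr), sample_ids in groups.items():
        new_id = f"{condition}_t{time_hr:g}"
        cols[new_id] = norm.values[list(sample_ids)].mean(axis=1)
        rows.append((new_id, condition, float(time_hr), 1))
    values = pd.DataFrame(cols, index=norm.values.index)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_hr", "replicate"]
    ).set_index("sample_id")
    return NormalizedMatrix(values, samples, size_factors=None, log2=norm.log2)


def log_transform(norm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(value + pseudocount), elementwise."""
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    values = np.log2(norm.values + pseudocount)
    return NormalizedMatrix(
        values, norm.samples.copy(), size_factors=norm.size_factors, log2=True
    )
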