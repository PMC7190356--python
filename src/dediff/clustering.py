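"""Temporal-class clustering of z-scored log2 expression profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import GenePanel, InputError, NormalizedMatrix


@dataclass
class ProfileMatrix:
    """Per-gene z-scored (sample sd) log2 profiles; constant genes dropped."""

    values: pd.DataFrame
    dropped_constant: list


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster id, dense 1..k
    linkage: np.ndarray  # scipy merge table, sufficient to re-cut
    k: int
    distance: str
    method: str
    degenerate: bool = False


def zscore_profiles(log2_tc: NormalizedMatrix) -> ProfileMatrix:
    """Standardise each gene row to mean 0, sample sd 1; drop constant rows."""
    if log2_tc.values.shape[1] < 2:
        raise InputError("z-scoring needs at least two columns")
    vals = log2_tc.values
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    kept = vals.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[~constant], axis=0)
    return ProfileMatrix(values=z, dropped_constant=vals.index[constant].tolist())


def hier_cluster(
    profiles: ProfileMatrix,
    k: int,
    distance: str = "correlation",
    method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of gene profiles, tree cut to k clusters.

    Default distance is 1 - Pearson correlation with average linkage, which
    groups genes by temporal shape regardless of amplitude; a Euclidean/Ward
    alternative is available.
    """
    X = profiles.values.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise InputError("k must be >= 1")
    if k > n:
        raise InputError(f"k={k} exceeds the {n} retained genes")
    if distance == "correlation":
        d = pdist(X, metric="correlation")
    elif distance == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise InputError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(d, method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # dense relabel 1..k' in order of first appearance
    labels = pd.Series(raw, index=profiles.values.index, name="cluster")
    dense = {c: i + 1 for i, c in enumerate(pd.unique(labels))}
    labels = labels.map(dense)
    return ClusterAssignment(
        labels=labels,
        linkage=Z,
        k=int(labels.max()),
        distance=distance,
        method=method,
        degenerate=labels.nunique() < k,
    )


def detect_transient_induction(
    tc: NormalizedMatrix,
    condition: str,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> GenePanel:
    """Genes with a transient rise of more than ``fold`` during a time course.

    Included when some interior timepoint exceeds ``fold`` times the 0 hr level
    (pseudocounted ratio) and the final timepoint has fallen back below that
    threshold.
    """
    if tc.log2:
        raise InputError("transient-induction rule expects linear-scale counts")
    table = tc.condition_timecourse(condition)
    if table.shape[1] < 3:
        raise InputError("transient detection needs at least three timepoints")
    vals = table.to_numpy(dtype=float)
    ratio = (vals + pseudocount) / (vals[:, [0]] + pseudocount)
    interior_peak = (ratio[:, 1:-1] > fold).any(axis=1)
    returns = ratio[:, -1] < fold
    selected = interior_peak & returns
    return GenePanel(
        name=f"transient_{condition}",
        genes=frozenset(table.index[selected]),
        definition={
            "rule": "transient",
            "condition": condition,
            "fold": fold,
            "pseudocount": pseudocount,
        },
    )
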