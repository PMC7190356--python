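"""Trajectory PCA with loading-contribution gene selection.

Samples are the observations and genes the variables: a time course traces a
curve through gene-expression space and the leading components capture the
major transcriptional programmes along it.  Because loading vectors have unit
norm, the squared loading of a gene partitions that component's variance, so
"the genes carrying the first component" can be made precise: rank genes by
squared loading and keep the shortest prefix reaching a target share (e.g.
10%) of the component's variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EstimationError, InputError, NormalizedMatrix


@dataclass
class TrajectoryModel:
    """Fitted PCA over a gene x sample matrix.

    loadings: gene x component, unit-norm columns, sign-fixed so each
    column's largest-magnitude entry is positive.
    scores: sample x component; ``scores = (X - center)^T @ loadings``.
    variance_fraction: share of total variance per component.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray
    center: pd.Series
    gene_universe: pd.Index

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ContributionSelection:
    """Shortest gene prefix reaching a target share of one component's variance."""

    component: int
    fraction: float
    genes: list = field(default_factory=list)
    achieved_fraction: float = 0.0


def filter_by_mean_count(norm: NormalizedMatrix, threshold: float = 10.0) -> NormalizedMatrix:
    """Keep genes whose mean over all samples is strictly greater than threshold."""
    means = norm.values.mean(axis=1)
    keep = means > threshold
    if not keep.any():
        raise InputError(
            f"mean-count filter at {threshold} removed every gene; review the threshold"
        )
    dropped = dict(norm.dropped_genes)
    dropped["mean_count_filter"] = norm.values.index[~keep].tolist()
    return NormalizedMatrix(
        norm.values.loc[keep].copy(),
        norm.samples.copy(),
        size_factors=norm.size_factors,
        log2=norm.log2,
        dropped_genes=dropped,
    )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]


def fit_pca(norm: NormalizedMatrix, n_components: int = 3) -> TrajectoryModel:
    """Fit PCA by SVD of the gene-centered matrix (samples = observations)."""
    if norm.values.shape[1] < 2:
        raise EstimationError("PCA requires at least two samples")
    X = norm.values.to_numpy(dtype=float).T  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0:
        raise EstimationError("zero total variance: all samples identical")
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds data rank {rank}; reduced to rank",
            stacklevel=2,
        )
        n_components = rank
    loadings = Vt[:n_components].T.copy()
    scores = Xc @ loadings
    _fix_signs(loadings, scores)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return TrajectoryModel(
        loadings=pd.DataFrame(loadings, index=norm.values.index, columns=comp_names),
        scores=pd.DataFrame(scores, index=norm.values.columns, columns=comp_names),
        variance_fraction=(s[:n_components] ** 2) / total_var,
        center=pd.Series(center, index=norm.values.index, name="center"),
        gene_universe=norm.values.index.copy(),
    )


def gene_contribution(model: TrajectoryModel, component: int = 1) -> pd.Series:
    """Squared loading per gene for one component (1-based); sums to 1."""
    if not 1 <= component <= model.n_components:
        raise InputError(f"component {component} not fitted (have {model.n_components})")
    col = model.loadings.iloc[:, component - 1]
    return (col**2).rename(f"contribution_PC{component}")


def select_top_contributors(
    model: TrajectoryModel, component: int = 1, fraction: float = 0.10
) -> ContributionSelection:
    """Shortest contribution-ranked gene prefix whose cumulative share >= fraction."""
    if not 0 < fraction <= 1:
        raise InputError("fraction must lie in (0, 1]")
    contrib = gene_contribution(model, component)
    order = np.argsort(-contrib.to_numpy(), kind="stable")
    cum = np.cumsum(contrib.to_numpy()[order])
    n_sel = int(np.searchsorted(cum, fraction) + 1)
    n_sel = min(n_sel, len(cum))
    genes = contrib.index[order[:n_sel]].tolist()
    return ContributionSelection(
        component=component,
        fraction=fraction,
        genes=genes,
        achieved_fraction=float(cum[n_sel - 1]),
    )


def project_samples(model: TrajectoryModel, norm: NormalizedMatrix) -> pd.DataFrame:
    """Project new samples into the fitted component space."""
    missing = [g for g in model.gene_universe if g not in norm.values.index]
    if missing:
        raise InputError(
            f"{len(missing)} model genes missing from new data, e.g. {missing[:5]}"
        )
    X = norm.values.loc[model.gene_universe].to_numpy(dtype=float).T
    scores = (X - model.center.to_numpy()) @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=norm.values.columns, columns=model.loadings.columns)
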