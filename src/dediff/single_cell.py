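"""Fate-marker selection, per-cell panel scoring and fate convergence.

Cells sampled hourly during dedifferentiation carry residual prestalk or
prespore expression from their life in the aggregate.  Scoring each cell by
the mean log10 count over a fate-marker panel gives a two-dimensional
(prestalk score, prespore score) fate plane; the distance between the
prestalk-high subpopulation and the rest, tracked per sampling hour, measures
how quickly the two fates converge onto a common dedifferentiation trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GenePanel, InputError, NormalizedMatrix
from .pca import TrajectoryModel, filter_by_mean_count, fit_pca


@dataclass
class SCCountMatrix:
    """Cell x gene molecular counts with per-cell metadata.

    ``meta`` is indexed by cell barcode with column ``hour`` (sampling hour)
    and, for synthetic data, an optional ``fate`` column.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if "hour" not in self.meta.columns:
            raise InputError("cell metadata needs an 'hour' column")
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.index]
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise InputError(
                f"{int((totals == 0).sum())} all-zero cells; remove them before analysis"
            )


def select_fate_markers(
    table: pd.DataFrame,
    min_abs_l2fc: float = 1.0,
    max_fdr: float = 0.1,
    min_max_count: float = 100.0,
) -> tuple[GenePanel, GenePanel]:
    """Split a differential-expression table into prestalk/prespore marker panels.

    ``table`` is indexed by gene with columns ``log2fc`` (positive toward
    prestalk), ``q`` (FDR-adjusted) or ``p`` (raw; adjusted here by
    Benjamini-Hochberg), and ``max_count``.  Returns (prestalk, prespore).
    """
    if table.empty:
        raise InputError("empty marker table")
    if "q" in table.columns:
        q = table["q"].to_numpy(dtype=float)
    elif "p" in table.columns:
        q = multipletests(table["p"].to_numpy(dtype=float), method="fdr_bh")[1]
    else:
        raise InputError("marker table needs a 'q' or 'p' column")
    l2fc = table["log2fc"].to_numpy(dtype=float)
    passing = (q < max_fdr) & (table["max_count"].to_numpy(dtype=float) > min_max_count)
    params = {
        "min_abs_l2fc": min_abs_l2fc,
        "max_fdr": max_fdr,
        "min_max_count": min_max_count,
    }
    prestalk = GenePanel(
        "prestalk_markers",
        frozenset(table.index[passing & (l2fc > min_abs_l2fc)]),
        definition={"rule": "fate_markers", "fate": "prestalk", **params},
    )
    prespore = GenePanel(
        "prespore_markers",
        frozenset(table.index[passing & (l2fc < -min_abs_l2fc)]),
        definition={"rule": "fate_markers", "fate": "prespore", **params},
    )
    return prestalk, prespore


def panel_score(sc: SCCountMatrix, panel: GenePanel) -> pd.Series:
    """Per-cell mean of log10(count + 1) over the panel genes."""
    genes = [g for g in sc.counts.columns if g in panel.genes]
    if not genes:
        raise InputError(f"panel {panel.name!r} shares no genes with the count matrix")
    return np.log10(sc.counts[genes] + 1).mean(axis=1).rename(panel.name)


def sc_pca(
    sc: SCCountMatrix, n_components: int = 3, min_cell_fraction: float = 0.01
) -> TrajectoryModel:
    """PCA of cells on log10(count+1) values of detectably expressed genes.

    A gene enters the model when detected (count > 0) in at least
    ``min_cell_fraction`` of cells.  Cells are the observations.
    """
    if sc.counts.shape[0] < 2:
        raise InputError("single-cell PCA needs at least two cells")
    detected = (sc.counts > 0).mean(axis=0) >= min_cell_fraction
    values = np.log10(sc.counts.loc[:, detected] + 1).T  # gene x cell
    sheet = pd.DataFrame(
        {
            "condition": "cell",
            "time_hr": sc.meta["hour"].to_numpy(dtype=float),
            "replicate": 1,
        },
        index=sc.counts.index,
    )
    return fit_pca(NormalizedMatrix(values, sheet, log2=False), n_components)


@dataclass
class ConvergenceCurve:
    """Centroid distance in fate-score space per sampling hour."""

    distance: pd.Series  # hour -> distance; NaN where a group was too small
    group_sizes: pd.DataFrame = field(default_factory=pd.DataFrame)
    top_fraction: float = 0.2


def convergence_curve(
    sc: SCCountMatrix,
    prestalk: GenePanel,
    prespore: GenePanel,
    top_fraction: float = 0.2,
) -> ConvergenceCurve:
    """Fate-separation distance per sampling hour.

    Within each hour, cells above the (1 - top_fraction) quantile of the
    prestalk score form the prestalk-high group; the curve is the Euclidean
    distance between that group's centroid and the remainder's centroid in
    the (prestalk score, prespore score) plane.  Hours where either group has
    fewer than two cells are reported as missing (NaN), not raised.
    """
    if not 0 < top_fraction < 1:
        raise InputError("top_fraction must lie in (0, 1)")
    st = panel_score(sc, prestalk)
    sp = panel_score(sc, prespore)
    hours = sorted(sc.meta["hour"].unique())
    dist, sizes = {}, {}
    for h in hours:
        cells = sc.meta.index[sc.meta["hour"] == h]
        s_st, s_sp = st.loc[cells], sp.loc[cells]
        cutoff = s_st.quantile(1 - top_fraction)
        high = s_st > cutoff
        n_hi, n_lo = int(high.sum()), int((~high).sum())
        sizes[h] = (n_hi, n_lo)
        if n_hi < 2 or n_lo < 2:
            dist[h] = np.nan
            continue
        hi = np.array([s_st[high].mean(), s_sp[high].mean()])
        lo = np.array([s_st[~high].mean(), s_sp[~high].mean()])
        dist[h] = float(np.linalg.norm(hi - lo))
    return ConvergenceCurve(
        distance=pd.Series(dist, name="centroid_distance"),
        group_sizes=pd.DataFrame(sizes, index=["prestalk_high", "rest"]).T,
        top_fraction=top_fraction,
    )


def estimate_merge_hour(curve: ConvergenceCurve, threshold_fraction: float = 0.25):
    """First hour at which the curve falls below a fraction of its initial value.

    Returns None when the curve never crosses the threshold.
    """
    d = curve.distance.dropna()
    if d.empty:
        raise InputError("convergence curve has no valid hours")
    ref = d.iloc[0]
    below = d[d < threshold_fraction * ref]
    return None if below.empty else float(below.index[0])
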