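"""Threshold gene classification, symmetry statistics and overlap testing.

All rules operate on replicate-averaged, size-factor-normalized counts (linear
scale) and use pseudocounted log2 fold changes so zero counts never divide by
zero.  The permutation test asks whether an observed overlap between two gene
panels could arise by drawing a same-sized panel uniformly at random from the
genome; on small universes the null can be enumerated exhaustively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .containers import GenePanel, InputError, NormalizedMatrix

#: overlap-test null switches to exact enumeration below this many panels
EXHAUSTIVE_LIMIT = 10**6


def log2fc(value_t: float, value_0: float, pseudocount: float = 1.0) -> float:
    """Pseudocounted log2 fold change of value_t over value_0."""
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    return float(np.log2((value_t + pseudocount) / (value_0 + pseudocount)))


def _timecourse(tc: NormalizedMatrix, condition: str) -> pd.DataFrame:
    if tc.log2:
        raise InputError("threshold rules expect linear-scale normalized counts")
    return tc.condition_timecourse(condition)


def classify_changing_genes(
    tc: NormalizedMatrix,
    condition: str,
    min_count: float = 100.0,
    min_abs_l2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> GenePanel:
    """Genes changing over a time course.

    A gene is changing when its normalized count exceeds ``min_count`` at some
    timepoint and its absolute pseudocounted log2 fold change between 0 hr and
    at least one later timepoint exceeds ``min_abs_l2fc``.
    """
    table = _timecourse(tc, condition)
    times = table.columns.to_numpy(dtype=float)
    if 0.0 not in times:
        raise InputError(f"condition {condition!r} has no 0 hr timepoint")
    v0 = table.loc[:, 0.0].to_numpy()
    other = table.loc[:, times != 0.0].to_numpy()
    l2fc = np.log2((other + pseudocount) / (v0[:, None] + pseudocount))
    selected = (table.to_numpy().max(axis=1) > min_count) & (
        np.abs(l2fc).max(axis=1) > min_abs_l2fc
    )
    return GenePanel(
        name=f"changing_{condition}",
        genes=frozenset(table.index[selected]),
        definition={
            "rule": "changing",
            "condition": condition,
            "min_count": min_count,
            "min_abs_l2fc": min_abs_l2fc,
            "pseudocount": pseudocount,
        },
    )


def direction_over_window(
    tc: NormalizedMatrix,
    condition: str,
    window: tuple[float, float],
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Label each gene up/down/flat by its fold change across a time window."""
    table = _timecourse(tc, condition)
    t_start, t_end = float(window[0]), float(window[1])
    times = table.columns.to_numpy(dtype=float)
    for t in (t_start, t_end):
        if t not in times:
            raise InputError(
                f"window endpoint {t} hr not sampled for {condition!r} (no interpolation)"
            )
    thresh = np.log2(fold)
    l2fc = np.log2(
        (table.loc[:, t_end].to_numpy() + pseudocount)
        / (table.loc[:, t_start].to_numpy() + pseudocount)
    )
    labels = np.where(l2fc > thresh, "up", np.where(l2fc < -thresh, "down", "flat"))
    return pd.Series(labels, index=table.index, name=f"direction_{condition}")


@dataclass
class OverlapFraction:
    overlap: int
    size: int

    @property
    def fraction(self) -> float:
        return self.overlap / self.size


def symmetry_overlap(set_a: GenePanel, set_b: GenePanel) -> OverlapFraction:
    """|A ∩ B| / |A|, with both counts retained."""
    if len(set_a) == 0:
        raise InputError("symmetry_overlap: reference set is empty")
    return OverlapFraction(overlap=len(set_a.genes & set_b.genes), size=len(set_a))


def define_aggregation_panel(dev_tc: NormalizedMatrix, fold: float = 2.0) -> GenePanel:
    """Aggregation-stage genes from a development time course.

    Mean expression over 4, 6 and 8 hr must exceed ``fold`` times both the
    initial mean (0, 2 hr) and the mound mean (10, 12, 14 hr).
    """
    table = _timecourse(dev_tc, "development")
    times = table.columns.to_numpy(dtype=float)
    required = {0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0}
    missing = sorted(required - set(times))
    if missing:
        raise InputError(f"development course missing timepoints {missing} hr")
    mid = table.loc[:, [4.0, 6.0, 8.0]].mean(axis=1)
    initial = table.loc[:, [0.0, 2.0]].mean(axis=1)
    mound = table.loc[:, [10.0, 12.0, 14.0]].mean(axis=1)
    selected = (mid > fold * initial) & (mid > fold * mound)
    return GenePanel(
        name="aggregation_specific",
        genes=frozenset(table.index[selected]),
        definition={"rule": "aggregation", "fold": fold},
    )


def define_early_induced(
    dediff_tc: NormalizedMatrix,
    condition: str,
    horizon_hr: float = 2.0,
    min_rel_induction: float = 0.5,
    pseudocount: float = 1.0,
    mode: str = "global_max",
) -> GenePanel:
    """Genes maximally induced within the first ``horizon_hr`` of dedifferentiation.

    mode "global_max" (default): the global maximum of the profile sits at
    t <= horizon and exceeds the 0 hr level by more than ``min_rel_induction``
    (pseudocounted ratio).  mode "any_rise": any timepoint within the horizon
    exceeds the 0 hr level by more than ``min_rel_induction``, regardless of
    where the global maximum falls.
    """
    table = _timecourse(dediff_tc, condition)
    times = table.columns.to_numpy(dtype=float)
    if not (times <= horizon_hr).any():
        raise InputError(f"no timepoints within {horizon_hr} hr")
    vals = table.to_numpy(dtype=float)
    v0 = table.loc[:, 0.0].to_numpy() if 0.0 in times else vals[:, 0]
    ratio = (vals + pseudocount) / (v0[:, None] + pseudocount)
    if mode == "global_max":
        argmax = vals.argmax(axis=1)  # earliest timepoint attaining the max
        within = times[argmax] <= horizon_hr
        induced = ratio[np.arange(len(vals)), argmax] > 1.0 + min_rel_induction
        selected = within & induced
    elif mode == "any_rise":
        early = times <= horizon_hr
        selected = (ratio[:, early] > 1.0 + min_rel_induction).any(axis=1)
    else:
        raise InputError(f"unknown mode {mode!r}")
    return GenePanel(
        name=f"early_induced_{condition}",
        genes=frozenset(table.index[selected]),
        definition={
            "rule": "early_induced",
            "condition": condition,
            "horizon_hr": horizon_hr,
            "min_rel_induction": min_rel_induction,
            "mode": mode,
        },
    )


@dataclass
class OverlapTestResult:
    """Observed overlap against a random-panel null."""

    observed_overlap: int
    panel_size: int
    null_overlaps: np.ndarray
    empirical_p: float
    n_permutations: int
    seed: int | None
    exhaustive: bool

    @property
    def observed_fraction(self) -> float:
        return self.observed_overlap / self.panel_size

    @property
    def null_median_fraction(self) -> float:
        return float(np.median(self.null_overlaps)) / self.panel_size


def overlap_permutation_test(
    panel: GenePanel,
    induced: GenePanel,
    universe,
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> OverlapTestResult:
    """Null distribution of |random panel ∩ induced| for panels drawn from universe.

    Each draw takes ``len(panel)`` genes uniformly without replacement from the
    universe.  ``method``: "sample" (Monte Carlo, add-one empirical p),
    "exhaustive" (enumerate every panel, exact tail p), or "auto" (exhaustive
    when the number of panels is at most :data:`EXHAUSTIVE_LIMIT`).
    """
    universe = pd.Index(sorted(universe))
    m = len(panel)
    if m == 0:
        raise InputError("empty panel")
    if m > len(universe):
        raise InputError("panel larger than universe")
    if not panel.genes <= set(universe):
        raise InputError("panel not contained in universe")
    if not induced.genes <= set(universe):
        raise InputError("induced set not contained in universe")
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")

    observed = len(panel.genes & induced.genes)
    induced_mask = universe.isin(induced.genes).astype(np.int8)

    if method not in ("auto", "sample", "exhaustive"):
        raise InputError(f"unknown method {method!r}")
    exhaustive = method == "exhaustive" or (
        method == "auto" and comb(len(universe), m) <= EXHAUSTIVE_LIMIT
    )

    if exhaustive:
        null = np.fromiter(
            (int(induced_mask[list(idx)].sum()) for idx in itertools.combinations(range(len(universe)), m)),
            dtype=np.int64,
        )
        p = float((null >= observed).sum() / len(null))
        return OverlapTestResult(observed, m, null, p, len(null), seed, True)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    chunk = max(1, min(n_permutations, int(2e7 // max(len(universe), 1)) or 1))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # draw b panels at once: top-m of iid uniforms is a uniform subset
        u = rng.random((b, len(universe)))
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        null[done : done + b] = induced_mask[idx].sum(axis=1)
        done += b
    p = float((1 + (null >= observed).sum()) / (n_permutations + 1))
    return OverlapTestResult(observed, m, null, p, n_permutations, seed, False)
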