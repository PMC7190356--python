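"""Cell-track motility statistics, speed clustering and event coupling.

Tracks are (time, x, y) sequences at a nominal 30 s frame interval.  Speed
profiles smoothed with a 10 min rolling window separate dedifferentiating
cells into a fast, rarely dividing cluster and a slow, frequently dividing
one; reporter traces are fitted with a flat-then-ramp changepoint model to
extract expression onset time and induction rate, which are then related to
the timing of the first division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import InputError


@dataclass
class CellTrack:
    track_id: str
    times: np.ndarray  # hours, strictly increasing
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    division_time: float | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise InputError(f"track {self.track_id}: ragged arrays")
        if np.any(np.diff(self.times) < 0):
            raise InputError(f"track {self.track_id}: times not increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise InputError(f"track {self.track_id}: non-finite coordinates")

    @property
    def divided(self) -> bool:
        return self.division_time is not None


@dataclass
class ExpressionTrace:
    track_id: str
    times: np.ndarray  # hours
    intensity: np.ndarray  # arbitrary units
    division_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InputError(f"trace {self.track_id}: times not strictly increasing")
        if not np.isfinite(self.intensity).all():
            raise InputError(f"trace {self.track_id}: non-finite intensities")


def frame_speeds(track: CellTrack) -> np.ndarray:
    """Per-interval speed in µm/min between consecutive frames."""
    if len(track.times) < 2:
        raise InputError("frame speeds need at least two frames")
    dt_min = np.diff(track.times) * 60.0
    if np.any(dt_min == 0):
        raise InputError(f"track {track.track_id}: duplicate timestamps")
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    return disp / dt_min


def rolling_speed(track: CellTrack, window_min: float = 10.0) -> pd.Series:
    """Centered moving average of frame speeds over a time window.

    Each inter-frame interval is stamped with its midpoint time; the smoothed
    value at an interval averages all interval speeds whose midpoints lie
    within +/- window/2 (inclusive) of its own.
    """
    speeds = frame_speeds(track)
    mid_hr = (track.times[:-1] + track.times[1:]) / 2.0
    half = window_min / 60.0 / 2.0
    out = np.empty_like(speeds)
    for i, t in enumerate(mid_hr):
        mask = np.abs(mid_hr - t) <= half + 1e-12
        out[i] = speeds[mask].mean()
    return pd.Series(out, index=mid_hr, name=track.track_id)


def persistence(track: CellTrack, window: tuple[float, float] | None = None):
    """Net displacement over path length within a time window; None if 0/0."""
    t = track.times
    if window is None:
        mask = np.ones_like(t, dtype=bool)
    else:
        mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise InputError("persistence needs at least two frames in the window")
    x, y = track.x[mask], track.y[mask]
    path = np.hypot(np.diff(x), np.diff(y)).sum()
    if path == 0:
        return None
    net = np.hypot(x[-1] - x[0], y[-1] - y[0])
    return float(net / path)


@dataclass
class SpeedClusterResult:
    labels: pd.Series  # track id -> 1..k, cluster 1 slowest
    cluster_mean_speed: pd.Series
    degenerate: bool


def cluster_speed_profiles(
    tracks: list[CellTrack], k: int = 2, window_min: float = 10.0
) -> SpeedClusterResult:
    """Ward/Euclidean clustering of rolling-speed profiles.

    Tracks must share a common time grid.  Labels are renumbered so cluster 1
    has the lowest mean speed.  Identical profiles make the split arbitrary;
    that case is flagged ``degenerate`` rather than raised.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    profiles = [rolling_speed(tr, window_min) for tr in tracks]
    grid = profiles[0].index
    for p in profiles[1:]:
        if len(p) != len(grid) or not np.allclose(p.index, grid):
            raise InputError(
                "tracks are not on a common time grid; resample before clustering"
            )
    X = np.vstack([p.to_numpy() for p in profiles])
    degenerate = bool(np.allclose(X, X[0]))
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    ids = [tr.track_id for tr in tracks]
    means = pd.Series(X.mean(axis=1), index=ids).groupby(raw).mean()
    order = {old: new + 1 for new, old in enumerate(means.sort_values().index)}
    labels = pd.Series([order[c] for c in raw], index=ids, name="cluster")
    mean_speed = pd.Series(X.mean(axis=1), index=ids).groupby(labels).mean()
    return SpeedClusterResult(labels=labels, cluster_mean_speed=mean_speed, degenerate=degenerate)


def division_association(labels: pd.Series, divided: pd.Series):
    """Cluster x divided contingency table with Pearson chi-square (no correction).

    Returns (table, chi2, p); p from the chi-square distribution with
    (r-1)(c-1) degrees of freedom.  Zero row/column margins are an error.
    """
    divided = divided.loc[labels.index]
    table = pd.crosstab(labels, divided.astype(bool))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("division association needs >=2 clusters and both outcomes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("contingency table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), float(p)


@dataclass
class OnsetFit:
    track_id: str
    inducing: bool
    onset_time: float | None
    rate: float  # intensity units per hour
    baseline: float
    residual: float  # RMS of the best fit


def trace_onset_fit(trace: ExpressionTrace, slope_sigma: float = 3.0) -> OnsetFit:
    """Fit a continuous flat-then-ramp model to a reporter trace.

    For each candidate breakpoint on the observed sample times the model
    ``y = c + r * max(0, t - t0)`` is solved by least squares; the breakpoint
    minimising the residual sum of squares wins.  The trace is called inducing
    when the fitted slope is positive and the ramp's total rise
    ``r * (t_end - t0)`` exceeds ``slope_sigma`` times the baseline-segment
    residual sd (i.e. the rise clears the noise floor); otherwise the onset is
    absent and the best flat fit is reported.
    """
    t, y = trace.times, trace.intensity
    n = len(t)
    if n < 6:
        raise InputError("onset fitting needs at least six samples")
    best = None
    # breakpoints leaving >=2 baseline and >=2 ramp samples
    for j in range(1, n - 2):
        t0 = t[j]
        ramp = np.maximum(0.0, t - t0)
        A = np.column_stack([np.ones(n), ramp])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            base_resid = resid[t <= t0]
            base_sd = float(base_resid.std(ddof=1)) if len(base_resid) > 1 else 0.0
            best = (sse, t0, float(coef[0]), float(coef[1]), base_sd)
    sse, t0, c, r, base_sd = best
    rms = float(np.sqrt(sse / n))
    rise = r * (t[-1] - t0)
    floor = 1e-8 * (np.abs(y).max() + 1.0)  # numerical zero for noiseless flats
    inducing = r > 0 and rise > max(slope_sigma * base_sd, floor)
    if inducing:
        return OnsetFit(trace.track_id, True, float(t0), r, c, rms)
    flat = float(np.mean(y))
    flat_rms = float(np.sqrt(np.mean((y - flat) ** 2)))
    return OnsetFit(trace.track_id, False, None, 0.0, flat, flat_rms)


@dataclass
class CouplingReport:
    n_dividers: int
    n_nondividers: int
    onset_division_r: float | None
    onset_division_p: float | None
    rate_ranksum_stat: float | None
    rate_ranksum_p: float | None
    onset_precedes_division_fraction: float | None
    missing: list


def coupling_stats(fits: list[OnsetFit], division_times: dict) -> CouplingReport:
    """Relate expression onset/rate to the first division.

    Pearson r between onset and division time over inducing dividers;
    two-sided Wilcoxon rank-sum comparing rates of dividers vs non-dividers;
    fraction of inducing dividers whose onset precedes division.  Tracks
    absent from ``division_times`` (or mapped to None) are non-dividers.
    """
    if len(fits) < 3:
        raise InputError("coupling statistics need at least three tracks")
    div = {tid: tv for tid, tv in division_times.items() if tv is not None}
    dividers = [f for f in fits if f.track_id in div]
    nondividers = [f for f in fits if f.track_id not in div]
    missing: list = []

    onset_r = onset_p = None
    inducing_div = [f for f in dividers if f.inducing]
    if len(inducing_div) >= 3:
        onsets = np.array([f.onset_time for f in inducing_div])
        dts = np.array([div[f.track_id] for f in inducing_div])
        if np.std(onsets) > 0 and np.std(dts) > 0:
            r, p = stats.pearsonr(onsets, dts)
            onset_r, onset_p = float(r), float(p)
        else:
            missing.append("onset_division_r (degenerate variance)")
    else:
        missing.append("onset_division_r (fewer than 3 inducing dividers)")

    ranksum_stat = ranksum_p = None
    if dividers and nondividers:
        u, p = stats.mannwhitneyu(
            [f.rate for f in dividers],
            [f.rate for f in nondividers],
            alternative="two-sided",
        )
        ranksum_stat, ranksum_p = float(u), float(p)
    else:
        missing.append("rate_ranksum (a group is empty)")

    precedes = None
    if inducing_div:
        precedes = float(
            np.mean([f.onset_time < div[f.track_id] for f in inducing_div])
        )
    else:
        missing.append("onset_precedes_division_fraction (no inducing dividers)")

    return CouplingReport(
        n_dividers=len(dividers),
        n_nondividers=len(nondividers),
        onset_division_r=onset_r,
        onset_division_p=onset_p,
        rate_ranksum_stat=ranksum_stat,
        rate_ranksum_p=ranksum_p,
        onset_precedes_division_fraction=precedes,
        missing=missing,
    )
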