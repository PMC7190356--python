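"""Synthetic data with the structure of a dedifferentiation study.

Four generators emulate the study design end to end:

* a bulk RNA-seq time course over five conditions (forward development 0-14 hr,
  dedifferentiation 0-24 hr in liquid medium and on bacteria, a mock buffer
  control, and an undifferentiated reference), two replicates each, with
  negative-binomial count noise and per-library depth factors;
* single-cell counts sampled hourly (0-6 hr) from two converging fates
  (prestalk/prespore), each fate carrying its own marker genes whose
  separation decays geometrically with sampling hour;
* cell tracks at 30 s frame intervals from two motility clusters — fast and
  rarely dividing versus slow and frequently dividing;
* fluorescence reporter traces that are flat until a planted onset, then rise
  linearly.

Gene mean profiles are piecewise linear in log2 space over a small library of
archetypes (reversing, condition-specific, transiently induced, biphasic
cell-cycle, unchanged), so the threshold rules downstream have planted
positives and negatives.  Every generated gene, cell, track and trace has
exactly one record in the returned :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, InvalidConfigError
from .single_cell import SCCountMatrix
from .tracks import CellTrack, ExpressionTrace

# distinct RNG streams per generator, derived from (seed, offset)
_STREAM = {"timecourse": 0, "sc": 1, "tracks": 2, "traces": 3}

DEV = "development"
LIQ = "dediff-liquid"
BAC = "dediff-bacteria"
BUF = "buffer"
UND = "undifferentiated"

#: log2 mean-expression anchors (hour, log2 value), interpolated linearly.
ARCHETYPES: dict[str, dict[str, list[tuple[float, float]]]] = {
    "reversal_up": {
        DEV: [(0, 9), (2, 9), (4, 7), (6, 6), (8, 5), (14, 5)],
        LIQ: [(0, 5), (0.5, 5.5), (1, 6.2), (2, 7.2), (3, 8), (4, 8.6), (5, 9), (24, 9)],
        BAC: [(0, 5), (0.5, 5.3), (1, 5.9), (2, 6.8), (3, 7.6), (4, 8.2), (5, 8.8), (6, 9), (24, 9)],
    },
    "reversal_down": {
        DEV: [(0, 5), (2, 5), (4, 7), (6, 8), (8, 9), (14, 9)],
        LIQ: [(0, 9), (0.5, 8.5), (1, 7.8), (2, 6.8), (3, 6), (4, 5.4), (5, 5), (24, 5)],
        BAC: [(0, 9), (0.5, 8.7), (1, 8.1), (2, 7.2), (3, 6.4), (4, 5.8), (5, 5.2), (6, 5), (24, 5)],
    },
    "dediff_specific": {
        DEV: [(0, 6), (14, 6)],
        LIQ: [(0, 6), (0.5, 6.5), (2, 8), (4, 9), (24, 9)],
        BAC: [(0, 6), (0.5, 6.3), (2, 7.6), (5, 9), (24, 9)],
    },
    "dev_specific": {
        DEV: [(0, 6), (2, 6), (6, 9), (14, 9)],
        LIQ: [(0, 6), (24, 6)],
        BAC: [(0, 6), (24, 6)],
    },
    # nutrient-shift-repressed genes: the log2 mirror of dediff_specific,
    # keeping the simulated gene population symmetric for stable size factors
    "dediff_repressed": {
        DEV: [(0, 8), (14, 8)],
        LIQ: [(0, 8), (0.5, 7.5), (2, 6), (4, 5), (24, 5)],
        BAC: [(0, 8), (0.5, 7.7), (2, 6.4), (5, 5), (24, 5)],
    },
    "aggregation_transient": {
        DEV: [(0, 6), (2, 6), (4, 8.5), (6, 9), (8, 8.5), (10, 6), (14, 6)],
        LIQ: [(0, 7), (0.5, 8.6), (1, 9), (2, 8.6), (3, 8), (4, 7.4), (6, 6.5), (8, 6), (24, 6)],
        BAC: [(0, 7), (0.5, 8.4), (1, 9), (2, 8.8), (3, 8.3), (5, 7), (6, 6.6), (8, 6), (24, 6)],
    },
    "cell_cycle_biphasic": {
        DEV: [(0, 8), (6, 6), (14, 6)],
        LIQ: [(0, 8), (1, 7.4), (2, 6.8), (3, 6.3), (4, 6), (5, 6), (6, 6.3), (8, 7), (12, 8), (24, 8.7)],
        BAC: [(0, 8), (1, 7.4), (2, 6.8), (3, 6.3), (4, 6), (5, 6), (6, 6.3), (8, 7), (12, 8), (24, 8.7)],
    },
    "unchanged": {
        DEV: [(0, 7), (14, 7)],
        LIQ: [(0, 7), (24, 7)],
        BAC: [(0, 7), (24, 7)],
    },
}

DEFAULT_ARCHETYPE_FRACTIONS = {
    "reversal_up": 0.25,
    "reversal_down": 0.25,
    "dediff_specific": 0.10,
    "dediff_repressed": 0.05,
    "dev_specific": 0.10,
    "aggregation_transient": 0.08,
    "cell_cycle_biphasic": 0.07,
    "unchanged": 0.10,
}

DEFAULT_TIMEPOINTS = {
    DEV: [0, 2, 4, 6, 8, 10, 12, 14],
    LIQ: [0, 0.5, 1, 2, 3, 4, 5, 6, 8, 12, 24],
    BAC: [0, 0.5, 1, 2, 3, 4, 5, 6, 8, 12, 24],
    BUF: [0, 1, 2, 4, 6, 12, 24],
    UND: [0],
}


@dataclass
class SyntheticConfig:
    """Parameters of all four generators; defaults are the study design."""

    # bulk time course
    n_genes: int = 2000
    archetype_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    timepoints: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TIMEPOINTS.items()})
    n_replicates: int = 2
    nb_dispersion: float = 0.1
    library_scale_range: tuple = (0.7, 1.4)
    seed: int = 0
    # single cell
    n_cells_per_hour: int = 132
    sc_hours: tuple = (0, 1, 2, 3, 4, 5, 6)
    n_prestalk_markers: int = 48
    n_prespore_markers: int = 42
    prestalk_fraction: float = 0.2
    marker_high_score: float = 1.3  # log10 scale above baseline at hour 0
    marker_low_count: float = 0.5  # mean count of an off marker
    convergence_halflife_hr: float | None = 1.25  # None = no convergence
    n_background_genes: int = 150
    # tracks
    n_tracks: int = 120
    frame_interval_s: float = 30.0
    track_duration_min: float = 60.0
    cluster_speed_means: tuple = (1.0, 8.0)  # µm/min, slow then fast
    speed_noise_sd: float = 0.5  # µm/min, per frame
    division_probs: tuple = (0.9, 0.1)  # slow cluster divides often
    cluster_fractions: tuple = (0.5, 0.5)
    turn_sd_rad: float = 0.3
    capture_horizon_hr: float = 25.0
    # traces
    n_traces: int = 100
    trace_span_hr: tuple = (0.0, 16.0)
    trace_dt_hr: float = 0.25
    onset_range_hr: tuple = (4.0, 12.0)
    trace_slope: float = 0.2  # intensity per hour
    trace_baseline: float = 1.0
    trace_noise_sd: float = 0.08
    inducing_fraction: float = 0.8

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"archetype fractions sum to {total}, not 1")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise InvalidConfigError(f"unknown archetypes: {sorted(unknown)}")
        if any(len(v) == 0 for v in self.timepoints.values()) or not self.timepoints:
            raise InvalidConfigError("every condition needs at least one timepoint")
        lo, hi = self.library_scale_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("library_scale_range must lie in (0, inf)")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.frame_interval_s <= 0:
            raise InvalidConfigError("frame_interval_s must be positive")
        if self.n_prestalk_markers < 2 or self.n_prespore_markers < 2:
            raise InvalidConfigError("need at least 2 marker genes per fate")
        t0, t1 = self.trace_span_hr
        if not (t0 <= self.onset_range_hr[0] <= self.onset_range_hr[1] <= t1):
            raise InvalidConfigError("onset_range_hr must lie within trace_span_hr")


@dataclass
class SyntheticTruth:
    """Planted ground truth; only the fields of the generator used are set."""

    gene_archetype: pd.Series | None = None
    cell_fate: pd.DataFrame | None = None
    track_cluster: pd.Series | None = None
    planted_onsets: pd.DataFrame | None = None
    planted_merge_hour: float | None = None
    params: dict = field(default_factory=dict)


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _STREAM[stream]]))


def _assign_archetypes(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    """Deterministic largest-remainder counts per archetype, order shuffled."""
    names = sorted(config.archetype_fractions)
    fracs = np.array([config.archetype_fractions[a] for a in names])
    base = np.floor(fracs * config.n_genes).astype(int)
    remainder = fracs * config.n_genes - base
    short = config.n_genes - base.sum()
    for i in np.argsort(-remainder)[:short]:
        base[i] += 1
    labels = np.repeat(names, base)
    rng.shuffle(labels)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    return pd.Series(labels, index=genes, name="archetype")


def _profile_log2(archetype: str, condition: str, times: np.ndarray) -> np.ndarray:
    anchors = ARCHETYPES[archetype]
    if condition in anchors:
        pts = anchors[condition]
        tt = np.array([p[0] for p in pts], dtype=float)
        vv = np.array([p[1] for p in pts], dtype=float)
        return np.interp(times, tt, vv)
    if condition == BUF:  # mock dedifferentiation: stuck at the 0 hr state
        v0 = _profile_log2(archetype, LIQ, np.array([0.0]))[0]
        return np.full(len(times), v0)
    if condition == UND:  # vegetative reference = late dedifferentiation state
        v_end = _profile_log2(archetype, LIQ, np.array([24.0]))[0]
        return np.full(len(times), v_end)
    raise InvalidConfigError(f"no profile for condition {condition!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2) via gamma-Poisson mixing.

    dispersion == 0 is the deterministic limit: counts are the rounded means.
    """
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def generate_timecourse(config: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Bulk count matrix over all configured conditions, plus planted truth."""
    config.validate()
    rng = _rng(config, "timecourse")
    archetypes = _assign_archetypes(config, rng)
    genes = archetypes.index

    columns, rows = {}, []
    lo, hi = config.library_scale_range
    for condition, times in config.timepoints.items():
        times = np.asarray(times, dtype=float)
        means_log2 = np.vstack(
            [_profile_log2(a, condition, times) for a in archetypes]
        )  # gene x time
        means = 2.0**means_log2
        for j, t in enumerate(times):
            for rep in range(1, config.n_replicates + 1):
                depth = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                sid = f"{condition}_t{t:g}_r{rep}"
                columns[sid] = _nb_draw(rng, means[:, j] * depth, config.nb_dispersion)
                rows.append((sid, condition, float(t), rep))
    counts = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_hr", "replicate"]
    ).set_index("sample_id")
    truth = SyntheticTruth(gene_archetype=archetypes, params={"generator": "timecourse"})
    return CountMatrix(counts, samples), truth


def generate_sc_counts(config: SyntheticConfig) -> tuple[SCCountMatrix, SyntheticTruth]:
    """Single cells from two fates whose marker separation decays with hour.

    Own-fate marker means are placed so the *log10 score* separation decays by
    a factor 2^(-hour / convergence_halflife_hr); counts are Poisson.  The
    planted merge hour is the first sampled hour at which that factor falls
    below 0.25 (None when convergence is off).
    """
    config.validate()
    rng = _rng(config, "sc")
    pst_markers = [f"pst{g:03d}" for g in range(config.n_prestalk_markers)]
    psp_markers = [f"psp{g:03d}" for g in range(config.n_prespore_markers)]
    n_bg = config.n_background_genes
    bg_up = [f"bgu{g:03d}" for g in range(n_bg // 2)]
    bg_down = [f"bgd{g:03d}" for g in range(n_bg - n_bg // 2)]
    genes = pst_markers + psp_markers + bg_up + bg_down

    s_low = np.log10(config.marker_low_count + 1.0)
    hl = config.convergence_halflife_hr
    max_hour = max(config.sc_hours) or 1.0

    barcodes, fates, hours, rows = [], [], [], []
    for h in config.sc_hours:
        n = config.n_cells_per_hour
        n_pst = int(round(config.prestalk_fraction * n))
        fate = np.array(["prestalk"] * n_pst + ["prespore"] * (n - n_pst))
        rng.shuffle(fate)
        factor = 1.0 if hl is None else 2.0 ** (-h / hl)
        s_high = s_low + config.marker_high_score * factor
        mean_on = 10.0**s_high - 1.0
        for i in range(n):
            bc = f"cell_{h:g}h_{i:03d}"
            own_on = mean_on if fate[i] == "prestalk" else config.marker_low_count
            psp_on = mean_on if fate[i] == "prespore" else config.marker_low_count
            frac = h / max_hour
            means = np.concatenate(
                [
                    np.full(len(pst_markers), own_on),
                    np.full(len(psp_markers), psp_on),
                    np.full(len(bg_up), 10.0 ** (0.2 + 1.2 * frac) - 1.0),
                    np.full(len(bg_down), 10.0 ** (1.4 - 1.2 * frac) - 1.0),
                ]
            )
            rows.append(rng.poisson(means))
            barcodes.append(bc)
            fates.append(fate[i])
            hours.append(float(h))
    counts = pd.DataFrame(np.vstack(rows), index=barcodes, columns=genes)
    meta = pd.DataFrame({"hour": hours, "fate": fates}, index=barcodes)
    merge = None
    if hl is not None:
        crossed = [h for h in config.sc_hours if 2.0 ** (-h / hl) < 0.25]
        merge = float(min(crossed)) if crossed else None
    truth = SyntheticTruth(
        cell_fate=meta.copy(),
        planted_merge_hour=merge,
        params={
            "generator": "sc",
            "prestalk_markers": pst_markers,
            "prespore_markers": psp_markers,
        },
    )
    return SCCountMatrix(counts, meta[["hour"]].copy()), truth


def generate_tracks(config: SyntheticConfig) -> tuple[list[CellTrack], SyntheticTruth]:
    """Persistent-random-walk tracks from two planted motility clusters.

    Cluster 1 is slow and divides with high probability, cluster 2 fast and
    rarely dividing.  Setting both cluster speed means and the speed noise sd
    to 0 yields stationary cells (all frame speeds 0).
    """
    config.validate()
    rng = _rng(config, "tracks")
    dt_min = config.frame_interval_s / 60.0
    n_frames = int(round(config.track_duration_min / dt_min)) + 1
    times_hr = np.arange(n_frames) * dt_min / 60.0

    n1 = int(round(config.cluster_fractions[0] * config.n_tracks))
    cluster_of = np.array([1] * n1 + [2] * (config.n_tracks - n1))
    rng.shuffle(cluster_of)

    tracks, labels = [], {}
    for i in range(config.n_tracks):
        c = cluster_of[i]
        v = config.cluster_speed_means[c - 1]
        theta = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.normal(0, config.turn_sd_rad, n_frames - 1)
        )
        steps = (
            np.clip(rng.normal(v, config.speed_noise_sd, n_frames - 1), 0.0, None)
            * dt_min
        )
        x0, y0 = rng.uniform(0, 500, size=2)
        x = np.concatenate([[x0], x0 + np.cumsum(steps * np.cos(theta))])
        y = np.concatenate([[y0], y0 + np.cumsum(steps * np.sin(theta))])
        p_div = config.division_probs[c - 1]
        division = (
            float(rng.uniform(0.05, config.capture_horizon_hr))
            if rng.random() < p_div
            else None
        )
        tid = f"track{i:04d}"
        tracks.append(CellTrack(tid, times_hr, x, y, division_time=division))
        labels[tid] = "slow_dividing" if c == 1 else "fast_nondividing"
    truth = SyntheticTruth(
        track_cluster=pd.Series(labels, name="cluster"),
        params={"generator": "tracks"},
    )
    return tracks, truth


def generate_traces(config: SyntheticConfig) -> tuple[list[ExpressionTrace], SyntheticTruth]:
    """Flat-baseline-then-ramp reporter traces with planted onsets and slopes."""
    config.validate()
    rng = _rng(config, "traces")
    t0, t1 = config.trace_span_hr
    times = np.arange(t0, t1 + 1e-9, config.trace_dt_hr)
    traces, records = [], []
    for i in range(config.n_traces):
        tid = f"trace{i:04d}"
        inducing = rng.random() < config.inducing_fraction
        if inducing:
            onset = rng.uniform(*config.onset_range_hr)
            slope = config.trace_slope
            signal = config.trace_baseline + slope * np.maximum(0.0, times - onset)
        else:
            onset, slope = np.nan, 0.0
            signal = np.full_like(times, config.trace_baseline)
        noise = rng.normal(0, config.trace_noise_sd, size=len(times)) if config.trace_noise_sd > 0 else 0.0
        traces.append(ExpressionTrace(tid, times, signal + noise))
        records.append((tid, onset, slope))
    planted = pd.DataFrame(
        records, columns=["trace_id", "onset_hr", "slope"]
    ).set_index("trace_id")
    truth = SyntheticTruth(planted_onsets=planted, params={"generator": "traces"})
    return traces, truth
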