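"""Motility statistics, speed clustering, onset fitting and event coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dediff import (
    CellTrack,
    ExpressionTrace,
    InputError,
    SyntheticConfig,
    cluster_speed_profiles,
    coupling_stats,
    division_association,
    frame_speeds,
    generate_tracks,
    persistence,
    rolling_speed,
    trace_onset_fit,
)
from oracles import chi2_2x2_closed_form, rolling_mean_loops


def _track(times_hr, x, y, **kw):
    return CellTrack("t0", np.asarray(times_hr), np.asarray(x), np.asarray(y), **kw)


class TestFrameSpeeds:
    def test_stationary_cell(self):
        tr = _track([0, 1 / 120, 2 / 120], [5, 5, 5], [2, 2, 2])
        assert (frame_speeds(tr) == 0).all()

    def test_unit_conversion_30s_frames(self):
        # 10 µm per 30 s frame = 20 µm/min
        tr = _track([0, 1 / 120], [0, 10], [0, 0])
        assert frame_speeds(tr)[0] == pytest.approx(20.0)

    def test_mean_speed_equals_path_over_time(self, rng):
        t = np.arange(20) / 120
        tr = _track(t, rng.normal(0, 5, 20), rng.normal(0, 5, 20))
        path = np.hypot(np.diff(tr.x), np.diff(tr.y)).sum()
        total_min = (t[-1] - t[0]) * 60
        assert frame_speeds(tr).mean() == pytest.approx(path / total_min)

    def test_duplicate_timestamps_error(self):
        with pytest.raises(InputError):
            frame_speeds(_track([0, 0, 1 / 120], [0, 1, 2], [0, 0, 0]))

    def test_rigid_motion_invariance(self, rng):
        t = np.arange(15) / 120
        x, y = rng.normal(0, 5, 15), rng.normal(0, 5, 15)
        base = frame_speeds(_track(t, x, y))
        phi = 0.83
        xr = 10 + x * np.cos(phi) - y * np.sin(phi)
        yr = -4 + x * np.sin(phi) + y * np.cos(phi)
        assert np.allclose(frame_speeds(_track(t, xr, yr)), base)


class TestRollingSpeed:
    def test_constant_speed_unchanged(self):
        t = np.arange(50) / 120
        tr = _track(t, np.arange(50) * 2.0, np.zeros(50))
        rolled = rolling_speed(tr, 10.0)
        assert np.allclose(rolled, rolled.iloc[0])

    def test_impulse_spread_over_window(self):
        t = np.arange(81) / 120
        x = np.zeros(81)
        x[40:] = 5.0  # single 5 µm jump mid-track
        rolled = rolling_speed(_track(t, x, np.zeros(81)), 10.0)
        # 10 min window at 30 s frames covers 21 interval midpoints
        peak_frame_speed = 5.0 / 0.5
        assert rolled.max() == pytest.approx(peak_frame_speed / 21)

    def test_matches_loop_oracle(self, rng):
        t = np.arange(60) / 120
        tr = _track(t, np.cumsum(rng.normal(0, 2, 60)), np.cumsum(rng.normal(0, 2, 60)))
        got = rolling_speed(tr, 10.0)
        want = rolling_mean_loops(list(got.index), list(frame_speeds(tr)), 10.0)
        assert np.allclose(got.to_numpy(), want)


class TestPersistence:
    def test_straight_line_is_one(self):
        tr = _track([0, 0.01, 0.02], [0, 1, 2], [0, 1, 2])
        assert persistence(tr) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        tr = _track([0, 0.01, 0.02], [0, 5, 0], [0, 0, 0])
        assert persistence(tr) == pytest.approx(0.0)

    def test_stationary_reported_absent(self):
        tr = _track([0, 0.01, 0.02], [1, 1, 1], [2, 2, 2])
        assert persistence(tr) is None


class TestSpeedClustering:
    def test_recovers_planted_clusters(self):
        tracks, truth = generate_tracks(SyntheticConfig(seed=5))
        res = cluster_speed_profiles(tracks, k=2)
        planted = truth.track_cluster.map(
            {"slow_dividing": 1, "fast_nondividing": 2}
        ).loc[res.labels.index]
        assert (res.labels == planted).mean() >= 0.95

    def test_cluster_one_is_slower(self):
        tracks, _ = generate_tracks(SyntheticConfig(seed=6, n_tracks=40))
        res = cluster_speed_profiles(tracks, k=2)
        assert res.cluster_mean_speed[1] <= res.cluster_mean_speed[2]

    def test_identical_profiles_flagged_degenerate(self):
        t = np.arange(30) / 120
        tracks = [
            CellTrack(f"t{i}", t, np.arange(30) * 1.0, np.zeros(30)) for i in range(6)
        ]
        res = cluster_speed_profiles(tracks, k=2)
        assert res.degenerate

    def test_unequal_grids_error(self):
        a = CellTrack("a", np.arange(30) / 120, np.arange(30) * 1.0, np.zeros(30))
        b = CellTrack("b", np.arange(20) / 120, np.arange(20) * 1.0, np.zeros(20))
        with pytest.raises(InputError, match="grid"):
            cluster_speed_profiles([a, b], k=2)


class TestDivisionAssociation:
    def test_matches_closed_form(self):
        labels = pd.Series([1] * 30 + [2] * 30, index=[f"t{i}" for i in range(60)])
        divided = pd.Series(
            [True] * 25 + [False] * 5 + [True] * 10 + [False] * 20, index=labels.index
        )
        _, chi2, p = division_association(labels, divided)
        assert chi2 == pytest.approx(chi2_2x2_closed_form(25, 5, 10, 20), rel=1e-12)
        assert chi2 == pytest.approx(15.4286, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_balanced_identical_rates_give_zero(self):
        labels = pd.Series([1] * 20 + [2] * 20, index=range(40))
        divided = pd.Series(([True] * 10 + [False] * 10) * 2, index=range(40))
        _, chi2, _ = division_association(labels, divided)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_is_error(self):
        labels = pd.Series([1, 1, 2, 2])
        divided = pd.Series([True, True, True, True])
        with pytest.raises(InputError):
            division_association(labels, divided)

    def test_planted_difference_detected_across_seeds(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=seed, n_tracks=60, track_duration_min=10)
            tracks, truth = generate_tracks(cfg)
            labels = truth.track_cluster.map(
                {"slow_dividing": 1, "fast_nondividing": 2}
            )
            divided = pd.Series({t.track_id: t.divided for t in tracks})
            try:
                _, chi2, _ = division_association(labels, divided)
            except InputError:  # a margin emptied by sampling noise
                continue
            hits += chi2 > 3.841
        assert hits / n_seeds >= 0.95

    def test_null_rates_rarely_exceed_critical_value(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                seed=10_000 + seed, n_tracks=60, track_duration_min=10,
                division_probs=(0.5, 0.5),
            )
            tracks, truth = generate_tracks(cfg)
            labels = truth.track_cluster.map(
                {"slow_dividing": 1, "fast_nondividing": 2}
            )
            divided = pd.Series({t.track_id: t.divided for t in tracks})
            try:
                _, chi2, _ = division_association(labels, divided)
            except InputError:
                continue
            hits += chi2 > 3.841
        assert hits / n_seeds <= 0.10


def _ramp_trace(onset=8.0, slope=0.2, noise=0.0, seed=0, tid="tr"):
    t = np.arange(0, 16.01, 0.25)
    y = 1.0 + slope * np.maximum(0.0, t - onset)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(t))
    return ExpressionTrace(tid, t, y)


class TestOnsetFit:
    def test_noiseless_recovery_exact_on_grid(self):
        fit = trace_onset_fit(_ramp_trace())
        assert fit.inducing
        assert fit.onset_time == pytest.approx(8.0, abs=0.25)
        assert fit.rate == pytest.approx(0.2, abs=1e-6)

    def test_flat_trace_not_inducing(self):
        tr = ExpressionTrace("flat", np.arange(10.0), np.full(10, 3.0))
        fit = trace_onset_fit(tr)
        assert not fit.inducing and fit.onset_time is None and fit.rate == 0.0

    def test_noisy_flat_trace_not_inducing(self):
        rng = np.random.default_rng(4)
        tr = ExpressionTrace("nf", np.arange(0, 16.01, 0.25),
                             1.0 + rng.normal(0, 0.08, 65))
        assert not trace_onset_fit(tr).inducing

    def test_recovery_median_error_at_five_percent_noise(self):
        errors = []
        for i in range(100):
            onset = 4.0 + (i % 32) * 0.25
            fit = trace_onset_fit(
                _ramp_trace(onset=onset, noise=0.08, seed=i, tid=f"t{i}")
            )
            assert fit.inducing
            errors.append(abs(fit.onset_time - onset))
        assert np.median(errors) <= 0.5

    def test_too_few_samples_error(self):
        with pytest.raises(InputError):
            trace_onset_fit(ExpressionTrace("x", [0, 1, 2], [0, 0, 0]))


class TestCouplingStats:
    def _fits(self, onsets, rates, inducing=True):
        from dediff import OnsetFit

        return [
            OnsetFit(f"t{i}", inducing, o if inducing else None, r, 1.0, 0.0)
            for i, (o, r) in enumerate(zip(onsets, rates))
        ]

    def test_perfect_linear_relation(self):
        onsets = [2.0, 4.0, 6.0, 9.0]
        fits = self._fits(onsets, [0.2] * 4)
        report = coupling_stats(fits, {f"t{i}": o + 5 for i, o in enumerate(onsets)})
        assert report.onset_division_r == pytest.approx(1.0)
        assert report.onset_precedes_division_fraction == 1.0

    def test_rate_comparison_groups(self):
        fits = self._fits([2, 3, 4], [1.0, 1.1, 1.2]) + [
            f for f in self._fits([0, 0, 0], [0.1, 0.2, 0.3], inducing=False)
        ]
        for i, f in enumerate(fits[3:]):
            f.track_id = f"n{i}"
        report = coupling_stats(fits, {"t0": 5.0, "t1": 6.0, "t2": 7.0})
        assert report.n_dividers == 3 and report.n_nondividers == 3
        assert report.rate_ranksum_p is not None

    def test_no_dividers_gives_partial_report(self):
        fits = self._fits([2, 3, 4], [0.2] * 3)
        report = coupling_stats(fits, {})
        assert report.onset_division_r is None
        assert report.missing

    def test_ranksum_null_p_uniform(self):
        # identically distributed rates for both groups: p-values ~ U(0,1)
        pvals = []
        for seed in range(1000):
            r = np.random.default_rng(seed)
            rates = r.normal(1.0, 0.3, 50)
            onsets = r.uniform(2, 10, 25)
            fits = self._fits(onsets, rates[:25]) + [
                f
                for f in self._fits([0] * 25, rates[25:], inducing=False)
            ]
            for i, f in enumerate(fits[25:]):
                f.track_id = f"n{i}"
            divisions = {f"t{i}": o + 5 for i, o in enumerate(onsets)}
            report = coupling_stats(fits, divisions)
            pvals.append(report.rate_ranksum_p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05
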