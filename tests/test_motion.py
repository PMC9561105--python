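"""MSD, windowed diffusivity estimation, segmentation, and quality control."""

import numpy as np
import pytest

import fbpm
from fbpm.motion import DiffusivityTrace, _merge_short_runs


def _traj(x, y, frame_rate=60.0, pid=0, valid=None):
    frames = np.arange(len(x))
    return fbpm.Trajectory(pid, frames, frames / frame_rate, np.asarray(x, float),
                           np.asarray(y, float), valid)


def _trace_from_values(d_values, frame_rate=60.0, window=30):
    d = np.asarray(d_values, dtype=float)
    centers = np.arange(len(d)) + window // 2
    return DiffusivityTrace(0, window, centers, centers / frame_rate, d)


class TestMsd:
    def test_stationary_particle_msd_is_zero(self):
        traj = _traj(np.full(100, 3.0), np.full(100, -1.0))
        assert np.all(fbpm.msd(traj, 10) == 0)

    def test_ballistic_motion_closed_form(self):
        t = np.arange(200) / 60.0
        v = 2.5
        traj = _traj(v * t, np.zeros_like(t))
        got = fbpm.msd(traj, 5)
        lags = np.arange(1, 6) / 60.0
        np.testing.assert_allclose(got, (v * lags) ** 2, rtol=1e-10)

    def test_brownian_slope_recovers_diffusivity(self):
        traj = fbpm.brownian_trajectory(0.4, 100_000, seed=12)
        m = fbpm.msd(traj, 5)
        lags = np.arange(1, 6) / 60.0
        slope = np.sum(lags * m) / np.sum(lags**2)
        assert slope / 4.0 == pytest.approx(0.4, rel=0.02)

    def test_lag_bounds_enforced(self):
        traj = _traj(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            fbpm.msd(traj, 10)
        with pytest.raises(ValueError):
            fbpm.msd(traj, 0)

    def test_invalid_frames_excluded(self):
        x = np.zeros(50)
        valid = np.ones(50, bool)
        valid[10] = False
        x[10] = 1e6  # corrupted position must not leak into MSD
        traj = _traj(x, np.zeros(50), valid=valid)
        m = fbpm.msd(traj, 3)
        assert np.all(m == 0.0)


class TestDiffusivityTrace:
    def test_unbiased_on_free_brownian_ensemble(self):
        d_true = 0.4
        means = []
        for k in range(60):
            traj = fbpm.brownian_trajectory(d_true, 3000, seed=1000 + k)
            means.append(fbpm.diffusivity_trace(traj).D_um2_s.mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - d_true) < 3 * se

    def test_static_noise_floor_is_small_and_nonnegative(self):
        rng = np.random.default_rng(4)
        sigma = 0.02
        xy = rng.standard_normal((5000, 2)) * sigma
        traj = _traj(xy[:, 0], xy[:, 1])
        tr = fbpm.diffusivity_trace(traj)
        assert np.all(tr.D_um2_s >= 0)
        # static floor ~ 16σ² for the lag-1..5 origin-constrained slope
        assert tr.D_um2_s.mean() < 30 * sigma**2

    def test_square_wave_diffusivity_tracked_within_window(self):
        # alternate D = 0.4 / 0.01 every 5 s; the trace must cross the
        # midpoint within one window length of each true switch
        rng = np.random.default_rng(9)
        frame_rate, window = 60.0, 30
        seg_len, n_seg = 300, 8
        d_levels = np.tile([0.4, 0.01], n_seg // 2)
        steps = []
        for d in d_levels:
            steps.append(rng.standard_normal((seg_len, 2)) * np.sqrt(2 * d / frame_rate))
        xy = np.cumsum(np.vstack(steps), axis=0)
        traj = _traj(xy[:, 0], xy[:, 1])
        tr = fbpm.diffusivity_trace(traj, window=window)
        mid = 0.205
        low = tr.D_um2_s < mid
        for k in range(1, n_seg):
            t_switch = k * seg_len
            idx = np.flatnonzero(np.abs(tr.center_frame - t_switch) <= window)
            want_low = d_levels[k] < mid
            assert np.any(low[idx] == want_low)

    def test_short_trajectory_warns_and_returns_empty(self):
        traj = _traj(np.zeros(10), np.zeros(10))
        with pytest.warns(UserWarning, match="shorter than"):
            tr = fbpm.diffusivity_trace(traj, window=30)
        assert len(tr) == 0

    def test_trace_length_contract(self):
        traj = fbpm.brownian_trajectory(0.1, 500, seed=3)
        tr = fbpm.diffusivity_trace(traj, window=30)
        assert len(tr) == 500 - 30 + 1


class TestSegmentStates:
    def test_all_unbound_when_trace_above_threshold(self):
        tr = _trace_from_values(np.full(200, 0.2))
        st = fbpm.segment_states(tr, fbpm.SegmentationConfig.for_cutoff(0.05))
        assert not st.bound.any()
        assert st.transitions == []

    def test_single_frame_dip_debounced(self):
        d = np.full(100, 0.2)
        d[50] = 0.001
        st = fbpm.segment_states(
            _trace_from_values(d), fbpm.SegmentationConfig(d_hi=0.05, d_lo=0.03, min_dwell=3)
        )
        assert not st.bound.any()

    def test_hysteresis_holds_state_between_thresholds(self):
        # dip below d_lo, then hover between d_lo and d_hi: still bound
        d = np.concatenate([np.full(20, 0.2), np.full(20, 0.01), np.full(20, 0.04),
                            np.full(20, 0.2)])
        st = fbpm.segment_states(
            _trace_from_values(d), fbpm.SegmentationConfig(d_hi=0.05, d_lo=0.03, min_dwell=1)
        )
        assert st.bound[20:60].all()
        assert not st.bound[:20].any() and not st.bound[60:].any()

    def test_padding_invariance(self):
        rng = np.random.default_rng(8)
        core = np.concatenate([np.full(50, 0.2), np.full(60, 0.01), np.full(50, 0.2)])
        core = core + rng.normal(0, 0.002, core.size)
        cfg = fbpm.SegmentationConfig.for_cutoff(0.05, min_dwell=30)
        base = fbpm.segment_states(_trace_from_values(core), cfg)
        padded = fbpm.segment_states(
            _trace_from_values(np.concatenate([np.full(40, 0.2), core, np.full(40, 0.2)])),
            cfg,
        )
        assert np.array_equal(padded.bound[40:-40], base.bound)
        assert len(padded.transitions) == len(base.transitions)

    def test_agreement_with_simulator_ground_truth(self, sandwich_run):
        gt = sandwich_run["gt"]
        agree = [
            np.mean(st.bound == gt[i].bound)
            for i, st in enumerate(sandwich_run["states"])
        ]
        assert np.mean(agree) >= 0.95

    def test_every_true_dwell_longer_than_2s_detected(self, sandwich_run):
        gt = sandwich_run["gt"]
        frame_rate = sandwich_run["config"].frame_rate
        for i, st in enumerate(sandwich_run["states"]):
            ev = gt[i].events
            long_bound = ev[(ev["state"] != "unbound")
                            & (ev["t_end_s"] - ev["t_start_s"] >= 2.0)]
            for _, row in long_bound.iterrows():
                f0 = int(row["t_start_s"] * frame_rate)
                f1 = int(row["t_end_s"] * frame_rate)
                assert st.bound[f0:f1].any()

    def test_transitions_alternate(self, sandwich_run):
        for st in sandwich_run["states"]:
            dirs = [d for d, _ in st.transitions]
            assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_merge_short_runs_absorbs_minority(self):
        s = np.array([0, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0], dtype=bool)
        out = _merge_short_runs(s, 3)
        assert not out[:7].any()
        assert out[7:11].all()


class TestQcFilter:
    def _build(self, trajs):
        traces = [fbpm.diffusivity_trace(t) for t in trajs]
        cfg = fbpm.SegmentationConfig.for_cutoff(0.05)
        states = [
            fbpm.segment_states(tr, cfg, full_frames=t.frame, full_times=t.t_s)
            for t, tr in zip(trajs, traces)
        ]
        return fbpm.TrajectorySet(trajs), traces, states

    def test_stuck_particle_excluded(self):
        rng = np.random.default_rng(2)
        free = [
            fbpm.brownian_trajectory(0.3, 2000, seed=100 + k, particle_id=k,
                                     x0=20.0 * k, y0=0.0)
            for k in range(5)
        ]
        # D = 0.005 μm²/s: below the 0.01 stuck threshold
        xy = rng.standard_normal((2000, 2)) * np.sqrt(2 * 0.005 / 60.0)
        stuck = fbpm.Trajectory(99, np.arange(2000), np.arange(2000) / 60.0,
                                np.cumsum(xy[:, 0]) + 200, np.cumsum(xy[:, 1]))
        ts, traces, states = self._build(free + [stuck])
        _, _, _, report = fbpm.qc_filter(ts, traces, states, warn_fraction=0.5)
        assert 99 in report.stuck
        assert report.excluded_ids == {99}

    def test_duplicated_trajectory_pair_flagged_colliding(self):
        base = [
            fbpm.brownian_trajectory(0.3, 2000, seed=200 + k, particle_id=k,
                                     x0=30.0 * k, y0=0.0)
            for k in range(6)
        ]
        twin = fbpm.Trajectory(50, base[0].frame, base[0].t_s,
                               base[0].x_um + 0.05, base[0].y_um)
        ts, traces, states = self._build(base + [twin])
        _, _, _, report = fbpm.qc_filter(ts, traces, states, warn_fraction=0.5)
        assert {0, 50} <= set(report.colliding)

    def test_hyperactive_particle_excluded(self):
        n = 240
        n_quiet = 30  # large ensemble so the outlier cannot mask itself
        quiet = [_trace_from_values(np.full(n, 0.2)) for _ in range(n_quiet)]
        chatter = np.where(np.arange(n) // 8 % 2 == 0, 0.3, 0.001)
        traces = quiet + [_trace_from_values(chatter)]
        cfg = fbpm.SegmentationConfig.for_cutoff(0.05, min_dwell=3)
        states = [fbpm.segment_states(tr, cfg) for tr in traces]
        for pid, (tr, st) in enumerate(zip(traces, states)):
            tr.particle_id = pid
            st.particle_id = pid
        trajs = [
            fbpm.brownian_trajectory(0.2, n + 29, seed=300 + k, particle_id=k,
                                     x0=25.0 * k, y0=0.0)
            for k in range(n_quiet + 1)
        ]
        filtered, _, _, report = fbpm.qc_filter(
            fbpm.TrajectorySet(trajs), traces, states, warn_fraction=0.5
        )
        assert report.hyperactive == [n_quiet]

    def test_clean_ensemble_keeps_everyone(self, sandwich_run):
        ts = sandwich_run["trajset"]
        _, _, _, report = fbpm.qc_filter(
            ts, sandwich_run["traces"], sandwich_run["states"]
        )
        assert report.excluded_fraction < 0.10

    def test_all_excluded_raises(self):
        traj = fbpm.Trajectory(0, np.arange(100), np.arange(100) / 60.0,
                               np.zeros(100), np.zeros(100))
        tr = _trace_from_values(np.full(71, 0.001))
        st = fbpm.segment_states(tr, fbpm.SegmentationConfig.for_cutoff(0.05))
        with pytest.raises(ValueError, match="every particle"):
            fbpm.qc_filter(fbpm.TrajectorySet([traj]), [tr], [st])
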