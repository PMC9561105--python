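"""Simulator contracts: kinetic rates, ground truth, stationarity, rendering."""

import numpy as np
import pytest
from scipy import stats

import fbpm
from fbpm.simulate import render_frames


@pytest.fixture(scope="module")
def quick_cfg():
    return fbpm.SimConfig(n_particles=2, block_s=20.0, seed=5, fov_um=(50.0, 50.0))


class TestEffectiveOnRate:
    def test_sandwich_limits(self):
        s = fbpm.KineticScenario(mode="sandwich", k_on_max=0.02, c_half=50.0, k_ns=0.002)
        assert fbpm.effective_on_rate(0.0, s) == pytest.approx(0.002, rel=1e-12)
        assert fbpm.effective_on_rate(50.0, s) == pytest.approx(0.002 + 0.01, rel=1e-12)
        assert fbpm.effective_on_rate(1e9, s) == pytest.approx(0.022, rel=1e-3)

    def test_competition_limits(self):
        s = fbpm.KineticScenario(mode="competition", k_on_max=0.02, c_half=50.0, k_ns=0.002)
        assert fbpm.effective_on_rate(0.0, s) == pytest.approx(0.022, rel=1e-12)
        assert fbpm.effective_on_rate(50.0, s) == pytest.approx(0.012, rel=1e-12)
        assert fbpm.effective_on_rate(1e9, s) == pytest.approx(0.002, rel=1e-3)

    def test_monotone_in_concentration(self):
        c = np.logspace(-2, 4, 50)
        up = fbpm.effective_on_rate(c, fbpm.KineticScenario(mode="sandwich"))
        down = fbpm.effective_on_rate(c, fbpm.KineticScenario(mode="competition"))
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fbpm.effective_on_rate(-1.0, fbpm.KineticScenario())

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            fbpm.KineticScenario(mode="direct")
        with pytest.raises(ValueError):
            fbpm.KineticScenario(k_off=-0.1)
        with pytest.raises(ValueError):
            fbpm.KineticScenario(p_multi=0.5, k_off_multi=1.0, k_off=0.25)


class TestSimulateParticle:
    def test_no_binding_channel_gives_no_bound_frames(self, spec28, quick_cfg):
        scen = fbpm.KineticScenario(k_on_max=0.0, k_ns=0.0)
        _, gt = fbpm.simulate_particle(spec28, scen, quick_cfg, seed=1, concentration=100.0)
        assert not gt.bound.any()
        assert set(gt.events["state"]) == {"unbound"}

    def test_instantaneous_unbinding_leaves_no_long_dwells(self, spec28):
        cfg = fbpm.SimConfig(n_particles=1, block_s=30.0, substeps=30, seed=2)
        scen = fbpm.KineticScenario(k_on_max=1.0, c_half=1.0, k_off=600.0, k_ns=0.0)
        with pytest.warns(UserWarning, match="coarse"):
            _, gt = fbpm.simulate_particle(spec28, scen, cfg, seed=3, concentration=100.0)
        ev = gt.events
        bound = ev[ev["state"] != "unbound"]
        assert len(bound) > 0  # binding did happen
        frame_t = 1.0 / cfg.frame_rate
        assert ((bound["t_end_s"] - bound["t_start_s"]) <= 2 * frame_t).all()

    def test_bit_identical_for_same_seed(self, spec28, quick_cfg):
        scen = fbpm.KineticScenario()
        t1, g1 = fbpm.simulate_particle(spec28, scen, quick_cfg, seed=9, concentration=50.0)
        t2, g2 = fbpm.simulate_particle(spec28, scen, quick_cfg, seed=9, concentration=50.0)
        assert np.array_equal(t1.x_um, t2.x_um)
        assert np.array_equal(t1.y_um, t2.y_um)
        assert np.array_equal(g1.states, g2.states)

    def test_binding_event_count_matches_poisson_oracle(self, spec28):
        # expected count = k_on_total * total simulated unbound time
        cfg = fbpm.SimConfig(n_particles=150, block_s=300.0, seed=17)
        scen = fbpm.KineticScenario(k_on_max=0.02, c_half=50.0, k_ns=0.0, k_off=0.25)
        _, gt = fbpm.simulate_fov(spec28, scen, cfg, concentration=50.0)
        ev = gt.events
        k_on = fbpm.effective_on_rate(50.0, scen)
        unbound_time = (
            ev.loc[ev["state"] == "unbound", "t_end_s"]
            - ev.loc[ev["state"] == "unbound", "t_start_s"]
        ).sum()
        n_bind = sum(gt[i].n_binding_events for i in range(cfg.n_particles))
        lam = k_on * unbound_time
        assert abs(n_bind - lam) <= 3 * np.sqrt(lam)


class TestGroundTruthStatistics:
    def test_bound_dwells_exponential_with_mean_inverse_koff(self, sandwich_run):
        ev = sandwich_run["gt"].events
        spec_ev = ev[ev["state"] == "bound_specific"]
        # drop recording-edge-truncated dwells
        dur = (spec_ev["t_end_s"] - spec_ev["t_start_s"]).to_numpy()
        ok = (spec_ev["t_start_s"] > 0) & (spec_ev["t_end_s"] < 300.0)
        dur = dur[ok.to_numpy()]
        tau = 1.0 / sandwich_run["scenario"].k_off
        assert dur.size > 30
        assert abs(dur.mean() - tau) < 3 * tau / np.sqrt(dur.size)

    def test_unbound_dwells_exponential_with_effective_rate(self, spec28):
        # high-rate scenario to accumulate many complete unbound dwells
        cfg = fbpm.SimConfig(n_particles=30, block_s=300.0, seed=23)
        scen = fbpm.KineticScenario(k_on_max=0.2, c_half=50.0, k_ns=0.0, k_off=1.0)
        _, gt = fbpm.simulate_fov(spec28, scen, cfg, concentration=1e6)
        ev = gt.events
        ub = ev[ev["state"] == "unbound"]
        ok = (ub["t_start_s"] > 0) & (ub["t_end_s"] < 300.0)
        dur = (ub["t_end_s"] - ub["t_start_s"]).to_numpy()[ok.to_numpy()]
        tau = 1.0 / fbpm.effective_on_rate(1e6, scen)
        assert dur.size > 500
        assert abs(dur.mean() - tau) < 4 * tau / np.sqrt(dur.size)

    def test_unbound_height_distribution_is_barometric(self, spec1):
        # long single-particle run; subsample every 10 s to decorrelate
        cfg = fbpm.SimConfig(n_particles=1, block_s=5000.0, seed=31, sigma_loc_um=0.0)
        scen = fbpm.KineticScenario(k_on_max=0.0, k_ns=0.0)
        _, gt = fbpm.simulate_particle(spec1, scen, cfg, seed=11)
        h = gt.heights_um[:: 10 * 60]
        h_b = fbpm.boltzmann_mean_height(spec1)
        assert stats.kstest(h, "expon", args=(0, h_b)).pvalue > 0.01

    def test_activity_direction_sandwich_vs_competition(self, spec28):
        def total_events(mode, conc, seed):
            cfg = fbpm.SimConfig(n_particles=20, block_s=120.0, seed=seed)
            scen = fbpm.KineticScenario(mode=mode, k_on_max=0.05, c_half=50.0)
            _, gt = fbpm.simulate_fov(spec28, scen, cfg, concentration=conc)
            return len(gt.events) - cfg.n_particles  # transitions = events - 1 per particle

        sandwich = [total_events("sandwich", c, 101) for c in (0.0, 50.0, 500.0)]
        competition = [total_events("competition", c, 103) for c in (0.0, 50.0, 500.0)]
        assert sandwich[0] < sandwich[1] < sandwich[2]
        assert competition[0] > competition[1] > competition[2]


class TestSimulateFov:
    def test_deterministic_and_distinct(self, spec28, quick_cfg):
        scen = fbpm.KineticScenario()
        ts1, _ = fbpm.simulate_fov(spec28, scen, quick_cfg, concentration=50.0)
        ts2, _ = fbpm.simulate_fov(spec28, scen, quick_cfg, concentration=50.0)
        assert ts1.particle_ids == [0, 1]
        for a, b in zip(ts1, ts2):
            assert np.array_equal(a.x_um, b.x_um)
        assert not np.array_equal(ts1[0].x_um, ts1[1].x_um)

    def test_windowed_diffusivity_is_bimodal_in_mixed_run(self, sandwich_run):
        gt = sandwich_run["gt"]
        d_by_state = {True: [], False: []}
        for i, tr in enumerate(sandwich_run["traces"]):
            bound = gt[i].bound[tr.center_frame]
            d_by_state[True].append(tr.D_um2_s[bound])
            d_by_state[False].append(tr.D_um2_s[~bound])
        d_bound = np.concatenate(d_by_state[True])
        d_unbound = np.concatenate(d_by_state[False])
        assert d_bound.size > 100 and d_unbound.size > 100
        # two well-separated populations around the published 0.05 cutoff
        assert np.median(d_bound) < 0.03
        assert np.median(d_unbound) > 0.05

    def test_csv_round_trip(self, spec28, quick_cfg, tmp_path):
        scen = fbpm.KineticScenario()
        ts, _ = fbpm.simulate_fov(spec28, scen, quick_cfg, concentration=0.0)
        path = tmp_path / "traj.csv"
        ts.to_csv(path)
        back = fbpm.TrajectorySet.from_csv(path)
        assert back.particle_ids == ts.particle_ids
        np.testing.assert_allclose(back[0].x_um, ts[0].x_um, rtol=0, atol=1e-9)


class TestRenderFrames:
    def test_single_stationary_particle_peak_position(self):
        frames = np.zeros(3, dtype=int)
        traj = fbpm.Trajectory(0, np.arange(3), np.arange(3) / 60,
                               np.full(3, 10.0), np.full(3, 6.9))
        stack = render_frames(
            fbpm.TrajectorySet([traj]), pixel_size_um=1.0, shape=(32, 32),
            poisson_noise=False,
        )
        for f in range(3):
            iy, ix = np.unravel_index(np.argmax(stack[f]), stack[f].shape)
            assert (ix, iy) == (10, 7)

    def test_flux_conservation(self):
        traj = fbpm.Trajectory(0, [0], [0.0], [16.0], [16.0])
        stack = render_frames(
            fbpm.TrajectorySet([traj]), pixel_size_um=1.0, shape=(32, 32),
            background=50.0, photon_scale=4000.0, poisson_noise=False,
        )
        excess = stack[0].astype(float) - 50.0
        assert excess.sum() == pytest.approx(4000.0, rel=0.01)

    def test_out_of_bounds_clipped_with_warning(self):
        traj = fbpm.Trajectory(0, [0], [0.0], [1000.0], [16.0])
        with pytest.warns(UserWarning, match="clipped"):
            render_frames(fbpm.TrajectorySet([traj]), pixel_size_um=1.0, shape=(32, 32))
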