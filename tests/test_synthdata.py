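"""Generator-level checks: trajectory statistics, tuning models, Poisson
spike counts, stimulus trains, opto kernels, LFP construction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mecopto import synthdata as sd


class TestTrajectory:
    def test_positions_stay_in_box(self):
        traj = sd.simulate_trajectory(600, box_size_cm=75, seed=1)
        assert traj.x.min() >= 0 and traj.x.max() <= 75
        assert traj.y.min() >= 0 and traj.y.max() <= 75

    def test_deterministic_under_seed(self):
        a = sd.simulate_trajectory(60, seed=7)
        b = sd.simulate_trajectory(60, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.hd, b.hd)

    def test_mean_speed_near_target(self):
        traj = sd.simulate_trajectory(600, speed_mean_cm_s=15.0, seed=1)
        mean_speed = traj.speed().mean()
        assert abs(mean_speed - 15.0) / 15.0 < 0.20

    def test_sampling_rate_and_monotone_time(self):
        traj = sd.simulate_trajectory(10, fs_hz=30, seed=0)
        assert len(traj.t) == 300
        assert np.all(np.diff(traj.t) > 0)

    @pytest.mark.parametrize("bad", [dict(duration_s=-1), dict(fs_hz=0)])
    def test_invalid_arguments_rejected(self, bad):
        kwargs = dict(duration_s=10.0, fs_hz=30.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sd.simulate_trajectory(**kwargs)


class TestRateFunction:
    def test_grid_peak_rate_at_lattice_node(self, grid_cell):
        fn = sd.rate_function(grid_cell)
        r = fn(np.array([7.0]), np.array([13.0]), np.array([0.0]), np.array([0.0]))
        assert r[0] == pytest.approx(grid_cell.peak_rate_hz)

    def test_grid_six_maxima_at_spacing(self, grid_cell):
        # the six nearest analytic maxima around a node sit one lattice
        # spacing away; locate them numerically from coarse starts
        fn = sd.rate_function(grid_cell)
        node = np.array([7.0, 13.0])

        def neg(p):
            return -fn(np.array([p[0]]), np.array([p[1]]), np.zeros(1), np.zeros(1))[0]

        found = []
        for ang in range(0, 360, 15):
            start = node + 40.0 * np.array(
                [np.cos(np.radians(ang)), np.sin(np.radians(ang))]
            )
            res = minimize(neg, start, method="Nelder-Mead")
            p = res.x
            d = np.hypot(*(p - node))
            if 1.0 < d and -neg(p) > 0.999 * grid_cell.peak_rate_hz:
                if not any(np.hypot(*(p - q)) < 5.0 for q in found):
                    found.append(p)
        dists = sorted(np.hypot(*(p - node)) for p in found)[:6]
        assert len(dists) == 6
        assert np.allclose(dists, 40.0, atol=0.5)

    def test_uniform_von_mises_is_flat(self):
        cell = sd.GroundTruthCell("h", "hd", peak_rate_hz=8.0, hd_kappa=0.0)
        fn = sd.rate_function(cell)
        hd = np.arange(0.0, 360.0, 10.0)
        r = fn(np.zeros_like(hd), np.zeros_like(hd), hd, np.zeros_like(hd))
        assert np.allclose(r, 8.0)

    def test_speed_cell_rectified_linear(self):
        cell = sd.GroundTruthCell(
            "s", "speed", speed_slope_hz_per_cm_s=0.5, speed_intercept_hz=-2.0
        )
        fn = sd.rate_function(cell)
        speeds = np.array([0.0, 4.0, 20.0])
        r = fn(np.zeros(3), np.zeros(3), np.zeros(3), speeds)
        assert np.allclose(r, [0.0, 0.0, 8.0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sd.GroundTruthCell("x", "place")


class TestGenerateSpikes:
    def test_zero_rate_gives_empty_train(self, traj120):
        spk = sd.generate_spikes(np.zeros(len(traj120.t)), traj120, seed=0)
        assert len(spk) == 0

    def test_constant_rate_poisson_count(self, traj600):
        spk = sd.generate_spikes(np.full(len(traj600.t), 10.0), traj600, seed=4)
        expected = 10.0 * traj600.duration
        assert abs(len(spk) - expected) < 3 * np.sqrt(expected)

    def test_deterministic_and_sorted(self, traj120):
        cell = sd.GroundTruthCell("u", "untuned", peak_rate_hz=5.0)
        a = sd.generate_spikes(sd.rate_function(cell), traj120, seed=9)
        b = sd.generate_spikes(sd.rate_function(cell), traj120, seed=9)
        assert np.array_equal(a, b)
        assert np.all(np.diff(a) >= 0)
        assert a[0] >= 0 and a[-1] <= traj120.duration

    def test_poisson_count_law_over_seeds(self, traj120):
        # 4-sigma band on the total count, many independent seeds
        rate = 20.0
        mu = rate * traj120.duration
        counts = [
            len(sd.generate_spikes(np.full(len(traj120.t), rate), traj120, seed=s))
            for s in range(100)
        ]
        assert abs(np.mean(counts) - mu) < 4 * np.sqrt(mu) / np.sqrt(100)


class TestStimTrain:
    @pytest.mark.parametrize(
        "freq,period_ms", [(8.0, 125.0), (12.0, 1000.0 / 12.0)]
    )
    def test_inter_onset_interval(self, freq, period_ms):
        st = sd.generate_stim_train(freq, 10.0, 600.0)
        assert np.allclose(np.diff(st.onsets) * 1000.0, period_ms)

    def test_onset_count(self):
        st = sd.generate_stim_train(8.0, 62.4, 1.0)
        assert len(st.onsets) == 8

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            sd.generate_stim_train(8.0, 125.0, 10.0)


class TestOptoKernel:
    def test_identity_profile_keeps_rate_statistics(self, traj600, stim8):
        cell = sd.GroundTruthCell("u", "untuned", peak_rate_hz=10.0)
        base = sd.generate_spikes(sd.rate_function(cell), traj600, seed=1)
        out = sd.apply_opto_response(
            sd.rate_function(cell), stim8, sd.OptoProfile(), traj600, seed=2
        )
        mu = 10.0 * traj600.duration
        assert abs(len(out) - mu) < 4 * np.sqrt(mu)
        assert abs(len(out) - len(base)) < 4 * np.sqrt(2 * mu)

    def test_full_inhibition_silences_window(self, traj600, stim8):
        prof = sd.OptoProfile(inh_depth=1.0, inh_onset_ms=10.0, inh_recovery_ms=20.0)
        cell = sd.GroundTruthCell("u", "untuned", peak_rate_hz=30.0)
        out = sd.apply_opto_response(sd.rate_function(cell), stim8, prof, traj600, seed=3)
        idx = np.searchsorted(stim8.onsets, out, side="right") - 1
        tau_ms = (out - stim8.onsets[np.clip(idx, 0, None)]) * 1000.0
        # right after inh_onset the linear-recovery gain averages 0.025 over
        # [10, 11) ms; the pre-pulse window has gain 1
        n_post = np.sum((tau_ms >= 10.0) & (tau_ms < 11.0))
        n_pre = np.sum((tau_ms >= 100.0) & (tau_ms < 101.0))
        assert n_post < 0.1 * n_pre

    def test_gain_kernel_analytic_recovery(self):
        prof = sd.OptoProfile(inh_depth=1.0, inh_onset_ms=10.0, inh_recovery_ms=20.0)
        assert sd.opto_gain(np.array([9.9]), prof)[0] == 1.0
        assert sd.opto_gain(np.array([10.0]), prof)[0] == 0.0
        assert sd.opto_gain(np.array([20.0]), prof)[0] == pytest.approx(0.5)
        assert sd.opto_gain(np.array([30.0]), prof)[0] == 1.0

    def test_excitation_bump_height_and_support(self):
        prof = sd.OptoProfile(exc_gain=3.0, exc_latency_ms=5.0, exc_width_ms=2.0)
        tau = np.array([4.9, 5.0, 6.9, 7.1])
        assert np.allclose(sd.opto_gain(tau, prof), [1.0, 4.0, 4.0, 1.0])


class TestLfp:
    def test_pure_sinusoid_spectral_peak(self, traj120):
        lfp = sd.generate_lfp(
            traj120, theta_f0_hz=8.0, noise_sd_uv=0.0, amp0_uv=50.0, seed=0
        )
        f = np.fft.rfftfreq(len(lfp.samples), 1.0 / lfp.fs)
        p = np.abs(np.fft.rfft(lfp.samples))
        assert abs(f[np.argmax(p)] - 8.0) < 0.1

    def test_artifact_free_signal_matches_no_stim(self, traj120):
        stim = sd.generate_stim_train(8.0, 10.0, 120.0)
        a = sd.generate_lfp(traj120, stim=stim, artifact_amp_uv=0.0, seed=5)
        b = sd.generate_lfp(traj120, stim=None, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_artifacts_add_transients_at_onsets(self, traj120):
        stim = sd.generate_stim_train(8.0, 10.0, 120.0)
        a = sd.generate_lfp(traj120, stim=stim, artifact_amp_uv=500.0, seed=5)
        b = sd.generate_lfp(traj120, stim=None, seed=5)
        diff = a.samples - b.samples
        i = int(round(stim.onsets[10] * a.fs))
        assert abs(diff[i]) > 100.0
        assert np.allclose(diff[i - 20 : i], 0.0)

    def test_low_sampling_rate_rejected(self, traj120):
        with pytest.raises(ValueError):
            sd.generate_lfp(traj120, fs_hz=50.0)


class TestGenerateSession:
    def test_day_structure_and_stim_placement(self):
        cells = [sd.GroundTruthCell("g", "grid")]
        cfg = sd.SessionConfig(cells=cells, duration_s=60.0)
        bundles, manifest = sd.generate_session(cfg, seed=1)
        assert [b.role for b in bundles] == ["baseline1", "stimulation", "baseline2"]
        assert bundles[0].stim is None and bundles[2].stim is None
        assert bundles[1].stim is not None
        assert all(len(b.units) == 1 for b in bundles)
        assert manifest["cells"][0]["cell_id"] == "g"

    def test_duplicate_cell_ids_rejected(self):
        cells = [sd.GroundTruthCell("a", "untuned"), sd.GroundTruthCell("a", "hd")]
        with pytest.raises(ValueError):
            sd.SessionConfig(cells=cells)
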