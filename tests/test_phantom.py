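"""Flow phantom: waveforms, rendering, coils, simulation, ground truth."""

import dataclasses

import numpy as np
import pytest

from spiralpc.nufft import NufftPlan
from spiralpc.phantom import (PhantomConfig, VesselSpec, beat_onsets,
                              bimodal_onsets, bipolar_moment_integrals,
                              concomitant_phase_map, default_config,
                              ground_truth_measures, render_frame_pair,
                              simulate_acquisition, simulate_coils,
                              velocity_waveform)


VESSEL = VesselSpec("AO", (0.0, 0.0), 10.0, 100.0, systole_fraction=0.4)
ONSETS = np.array([0.0, 1000.0, 2000.0, 3000.0, 4000.0])


class TestVelocityWaveform:
    def test_systolic_peak_reaches_peak_velocity(self):
        t_pk = 0.5 * VESSEL.systole_fraction * 1000.0
        assert velocity_waveform(t_pk, ONSETS, VESSEL) == \
            pytest.approx(100.0, rel=1e-9)

    def test_identical_beats_zero_cv(self):
        pk = [max(velocity_waveform(np.arange(on, on + 1000.0), ONSETS,
                                    VESSEL)) for on in ONSETS[:-1]]
        assert np.std(pk) == pytest.approx(0.0, abs=1e-9)

    def test_respiratory_modulation_bounds_cv(self):
        """With 10 % respiratory amplitude the per-beat peak-velocity CV is
        positive and at most ~7 % (the sd of a sampled sinusoid)."""
        onsets = np.arange(0.0, 20000.0, 911.0)
        pk = [max(velocity_waveform(np.arange(on, on + 911.0, 1.0), onsets,
                                    VESSEL, resp_amp=0.1, resp_period=4.0))
              for on in onsets[:-1]]
        # direct-evaluation oracle of the modulation at the systolic peaks
        t_pk = onsets[:-1] + 0.5 * VESSEL.systole_fraction * 911.0
        oracle = 100.0 * (1 + 0.1 * np.sin(2e-3 * np.pi * t_pk / 4.0))
        assert np.allclose(pk, oracle, rtol=1e-3)
        cv = 100 * np.std(pk, ddof=1) / np.mean(pk)
        assert 0.0 < cv <= 7.5

    def test_before_first_onset_is_baseline(self):
        v = dataclasses.replace(VESSEL, baseline=3.0)
        assert velocity_waveform(-50.0, ONSETS, v) == 3.0

    def test_nonmonotone_onsets_rejected(self):
        with pytest.raises(ValueError):
            velocity_waveform(10.0, np.array([0.0, 500.0, 400.0]), VESSEL)


class TestRendering:
    def test_magnitudes_equal_fc_fe(self):
        cfg = default_config(matrix=64)
        onsets = beat_onsets(cfg, 2000.0)
        fc, fe = render_frame_pair(250.0, cfg, onsets)
        assert np.allclose(np.abs(fc), np.abs(fe), atol=1e-12)

    def test_static_pixel_zero_phase_difference(self):
        cfg = default_config(matrix=64, concomitant=False)
        onsets = beat_onsets(cfg, 2000.0)
        fc, fe = render_frame_pair(250.0, cfg, onsets)
        corner = np.angle(fe[3, 3] * np.conj(fc[3, 3]))
        assert corner == pytest.approx(0.0, abs=1e-12)

    def test_venc_maps_to_pi_and_wraps(self):
        """Center pixel at v = venc gives phase pi; v = 1.5 venc wraps to
        -pi/2 via 2 pi arithmetic."""
        vessels = (VesselSpec("AO", (0.0, 0.0), 20.0, 100.0,
                              systole_fraction=1.0),)
        cfg = default_config(matrix=64, vessels=vessels, venc=100.0,
                             concomitant=False, resp_amp=0.0)
        onsets = np.array([0.0, 1000.0, 2000.0])
        t_pk = 500.0
        fc, fe = render_frame_pair(t_pk, cfg, onsets)
        c = cfg.matrix // 2
        dphi = np.angle(fe[c, c] * np.conj(fc[c, c]))
        assert abs(dphi) == pytest.approx(np.pi, rel=1e-3)
        cfg2 = dataclasses.replace(cfg, venc=100.0 / 1.5)
        fc2, fe2 = render_frame_pair(t_pk, cfg2, onsets)
        dphi2 = np.angle(fe2[c, c] * np.conj(fc2[c, c]))
        assert dphi2 == pytest.approx(-0.5 * np.pi, rel=1e-2)

    def test_concomitant_phase_scaling(self):
        cfg = default_config(matrix=64)
        phi1 = concomitant_phase_map(cfg)
        phi2 = concomitant_phase_map(dataclasses.replace(cfg, b0=1.1))
        assert np.allclose(phi1, 2.0 * phi2, rtol=1e-12)
        c = cfg.matrix // 2
        assert phi1[c, c] == pytest.approx(0.0, abs=1e-12)


class TestCoils:
    def test_rss_positive_and_seeded(self):
        m1 = simulate_coils(6, 64, seed=3)
        m2 = simulate_coils(6, 64, seed=3)
        assert np.array_equal(m1.maps, m2.maps)
        assert np.all(m1.rss() > 0)

    def test_single_coil_allowed(self):
        assert simulate_coils(1, 32).maps.shape == (1, 32, 32)

    def test_zero_coils_rejected(self):
        with pytest.raises(ValueError):
            simulate_coils(0, 32)


class TestAcquisition:
    def test_dc_consistency(self, small_setup):
        """With a k=(0,0) sample the signal equals the spatial sum of the
        coil-weighted image."""
        cfg = small_setup["config"]
        onsets = small_setup["onsets"]
        maps = small_setup["maps"]
        frame = small_setup["schedule"].frames[0]
        fc, _ = render_frame_pair(frame.mid_time, cfg, onsets)
        ks = small_setup["kspace"]
        row = np.flatnonzero((ks.frame_index == 0) & (ks.encoding == "FC"))[0]
        dc = ks.data[row, :, 0]  # spiral starts at the origin
        oracle = (maps.maps * fc).sum(axis=(1, 2))
        assert np.allclose(dc, oracle, rtol=1e-4)

    def test_forward_adjoint_recovers_truth_32(self):
        """Dense-DFT-level check: noise-free fully-sampled simulation +
        gridding correlates > 0.99 with the coil-combined truth."""
        from spiralpc.trajectory import (SpiralDesignSpec, build_schedule,
                                         density_compensation_weights,
                                         design_dual_density_spiral,
                                         rotate_interleaf)
        spec = SpiralDesignSpec(fov=300.0, resolution=300.0 / 32,
                                center_density=1.0, outer_density=1.0)
        il = design_dual_density_spiral(spec)
        cfg = default_config(matrix=32, n_coils=1, noise_sigma=0.0)
        onsets = beat_onsets(cfg, 100.0)
        fcimg, _ = render_frame_pair(30.0, cfg, onsets)
        n_arms = 2 * int(np.ceil(il.n_design))  # Nyquist-complete + margin
        arms = [rotate_interleaf(il, 360.0 * i / n_arms)
                for i in range(n_arms)]
        traj = np.vstack([a.k_samples for a in arms])
        w = density_compensation_weights(arms)
        plan = NufftPlan(traj, 32, cfg.pixel_mm)
        rec = plan.adjoint(plan.forward(fcimg), weights=w)
        num = abs(np.vdot(rec, fcimg))
        den = np.linalg.norm(rec) * np.linalg.norm(fcimg)
        assert num / den > 0.99

    def test_bitwise_reproducible(self, small_setup):
        cfg = dataclasses.replace(small_setup["config"], noise_sigma=1.0)
        a = simulate_acquisition(small_setup["schedule"], cfg,
                                 small_setup["maps"],
                                 small_setup["interleaf"],
                                 onsets=small_setup["onsets"])
        b = simulate_acquisition(small_setup["schedule"], cfg,
                                 small_setup["maps"],
                                 small_setup["interleaf"],
                                 onsets=small_setup["onsets"])
        assert np.array_equal(a.data, b.data)

    def test_labels_match_schedule(self, small_setup):
        ks = small_setup["kspace"]
        sched = small_setup["schedule"]
        assert ks.n_acquisitions == 4 * sched.n_frames
        for f in range(sched.n_frames):
            enc = ks.encoding[ks.frame_index == f]
            assert list(enc) == ["FC", "FE", "FC", "FE"]


class TestGroundTruth:
    def test_parabolic_peak_flow_closed_form(self):
        """Q_peak = v_c * pi r^2 / 2 (mean of a parabolic profile)."""
        cfg = default_config(
            vessels=(VesselSpec("AO", (0, 0), 10.0, 100.0),), resp_amp=0.0,
            rr_cv=0.0)
        onsets = np.array([0.0, 1000.0, 2000.0, 3000.0])
        beats, _ = ground_truth_measures(cfg, onsets, 3000.0)
        q_peak = beats["AO"][0]["peak_flow_rate"]
        oracle = 100.0 * np.pi * 10.0 ** 2 / 2.0 * 0.01  # cm/s*mm^2 -> mL/s
        assert q_peak == pytest.approx(oracle, rel=1e-4)

    def test_symmetric_vessels_give_unit_qpqs(self):
        v = VesselSpec("AO", (-40, 0), 12.0, 90.0)
        m = VesselSpec("MPA", (40, 0), 12.0, 90.0)
        cfg = default_config(vessels=(v, m), resp_amp=0.0, rr_cv=0.0)
        onsets = np.arange(0.0, 4000.0, 900.0)
        _, qpqs = ground_truth_measures(cfg, onsets, 4000.0)
        assert qpqs == pytest.approx(1.0, abs=1e-6)

    def test_net_flow_matches_quadrature(self):
        """Net flow equals an independent fine-quadrature of the prescribed
        waveform over the beat."""
        cfg = default_config(
            vessels=(VesselSpec("AO", (0, 0), 10.0, 80.0),), resp_amp=0.05)
        onsets = np.array([100.0, 950.0, 1900.0])
        beats, _ = ground_truth_measures(cfg, onsets, 1900.0)
        tt = np.arange(100.0, 950.0, 0.01)
        vv = velocity_waveform(tt, onsets, cfg.vessels[0],
                               cfg.resp_amp, cfg.resp_period)
        oracle = np.trapezoid(0.5 * vv * np.pi * 100.0 * 0.01, tt) * 1e-3
        assert beats["AO"][0]["net_flow"] == pytest.approx(oracle, rel=1e-4)

    def test_bimodal_onsets_alternate(self):
        on = bimodal_onsets(8000.0, jitter=0.0)
        rr = np.diff(on)
        assert np.allclose(rr[::2], 650.0) and np.allclose(rr[1::2], 1150.0)

    def test_bipolar_moments_match_sampled_waveform(self):
        """The closed-form first moment and Gz^2 integral agree with a
        numeric integration of the sampled trapezoid bipolar."""
        from spiralpc.constants import GAMMA_RAD_PER_S_T
        from spiralpc.velocimetry import (concomitant_integral,
                                          encoding_waveforms)
        cfg = default_config(venc=150.0)
        m1, int_g2 = bipolar_moment_integrals(cfg)
        phase = GAMMA_RAD_PER_S_T * m1 * 1e-9 * cfg.venc * 1e-2
        assert phase == pytest.approx(np.pi, rel=1e-9)
        g_fe, _, dt = encoding_waveforms(cfg.venc, cfg.bipolar_amplitude,
                                         cfg.bipolar_ramp, dt_ms=0.001)
        t = np.arange(g_fe.size) * dt
        m1_num = abs(np.trapezoid(g_fe * t, t))
        assert m1_num == pytest.approx(m1, rel=5e-3)
        assert concomitant_integral(g_fe, dt) == pytest.approx(int_g2,
                                                               rel=5e-3)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(venc=-10.0), dict(resp_amp=1.5), dict(rr_cv=-0.1),
        dict(vessels=(VesselSpec("AO", (140.0, 0.0), 20.0, 100.0),))])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            default_config(**bad)
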