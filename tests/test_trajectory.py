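"""Dual-density spiral design, rotation, and golden-angle scheduling."""

import dataclasses

import numpy as np
import pytest

from spiralpc.constants import GOLDEN_ANGLE_DEG, K_PER_G
from spiralpc.trajectory import (GradientLimits, InfeasibleSpiralError,
                                 SpiralDesignSpec, acceleration_factor,
                                 build_schedule, design_dual_density_spiral,
                                 matrix_size, rotate_interleaf)


class TestDesign:
    def test_reaches_kmax(self, table1_spec, table1_interleaf):
        k_max = 1.0 / (2.0 * table1_spec.resolution)
        assert k_max == pytest.approx(0.21739, abs=1e-5)
        assert table1_interleaf.k_radius.max() == pytest.approx(k_max,
                                                                rel=0.01)

    def test_starts_at_origin(self, table1_interleaf):
        assert np.allclose(table1_interleaf.k_samples[0], 0.0)

    def test_radius_envelope_monotone(self, table1_interleaf):
        r = table1_interleaf.k_radius
        assert np.all(np.diff(r) > -1e-9)

    def test_duration_within_readout(self, table1_spec, table1_interleaf):
        assert table1_interleaf.duration <= table1_spec.readout_duration

    def test_gradient_and_slew_limits(self, table1_spec, table1_interleaf):
        g = table1_interleaf.gradients
        lim = table1_spec.limits
        assert np.hypot(g[:, 0], g[:, 1]).max() <= lim.g_max
        slew = np.diff(g, axis=0) / (table1_interleaf.dwell * 1e-3)
        assert np.hypot(slew[:, 0], slew[:, 1]).max() <= lim.s_max

    def test_gradients_consistent_with_k(self, table1_interleaf):
        """Finite-differencing k reproduces the stored gradient waveform."""
        il = table1_interleaf
        dk = np.diff(il.k_samples, axis=0) / (il.dwell * 1e-3)
        g_mid = 0.5 * (il.gradients[:-1] + il.gradients[1:])
        # the terminal sample sits at the traversal end, off the dwell grid
        resid = np.abs(dk / K_PER_G - g_mid)[:-1]
        assert resid.max() < 0.05 * np.abs(il.gradients).max()

    def test_fully_sampled_count_matches_protocol(self, table1_interleaf):
        assert table1_interleaf.n_full == 12

    def test_arm_spacing_matches_designed_pitch(self, table1_spec,
                                                table1_interleaf):
        """Radial gap between adjacent arms of the n_design-fold rotated set
        equals 1/(fov*density) in both density zones."""
        il = table1_interleaf
        t = np.arange(il.n_samples) * il.dwell * 1e-3
        frac = t / table1_spec.readout_duration
        r = il.k_radius
        drdt = np.gradient(r, t)
        dth = np.gradient(np.unwrap(np.arctan2(il.k_samples[:, 1],
                                               il.k_samples[:, 0])), t)
        pitch = 2 * np.pi * drdt / np.maximum(dth, 1e-12)  # dr per turn
        spacing = pitch / il.n_design
        expected = 1.0 / (table1_spec.fov * table1_spec.density_at(frac))
        zone = slice(30, il.n_samples - 30)  # away from start/end transients
        ok = np.abs(spacing[zone] - expected[zone]) < 0.08 * expected[zone]
        assert ok.mean() > 0.95

    def test_relaxed_limits_shorten_duration(self, table1_spec,
                                             table1_interleaf):
        relaxed = dataclasses.replace(
            table1_spec, limits=GradientLimits(1e6, 1e9))
        il = design_dual_density_spiral(relaxed)
        assert il.duration < table1_interleaf.duration
        assert il.k_radius.max() == pytest.approx(table1_spec.k_max, rel=0.01)

    def test_infeasible_spec_raises(self):
        spec = SpiralDesignSpec(readout_duration=0.05,
                                limits=GradientLimits(5.0, 20.0))
        with pytest.raises(InfeasibleSpiralError, match="constraint"):
            design_dual_density_spiral(spec)

    @pytest.mark.parametrize("bad", [
        dict(center_fraction=0.0), dict(center_fraction=1.2),
        dict(outer_density=-1.0), dict(resolution=400.0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SpiralDesignSpec(**bad)

    def test_matrix_size_rounds_up_even(self):
        assert matrix_size(300, 2.3) == 132
        assert matrix_size(256, 2.0) == 128


class TestAcceleration:
    def test_protocol_acceleration_factor(self, table1_spec,
                                          table1_interleaf):
        r = acceleration_factor(table1_spec, 2, table1_interleaf)
        assert r == pytest.approx(6.0)

    def test_fully_sampled_gives_unity(self, table1_spec, table1_interleaf):
        n = table1_interleaf.n_full
        assert acceleration_factor(table1_spec, n, table1_interleaf) == 1.0

    def test_single_interleaf(self, table1_spec, table1_interleaf):
        assert acceleration_factor(table1_spec, 1, table1_interleaf) == 12.0

    def test_invalid_count(self, table1_spec, table1_interleaf):
        with pytest.raises(ValueError):
            acceleration_factor(table1_spec, 0, table1_interleaf)


class TestRotation:
    def test_identity_and_period(self, table1_interleaf):
        for ang in (0.0, 360.0):
            rot = rotate_interleaf(table1_interleaf, ang)
            assert np.allclose(rot.k_samples, table1_interleaf.k_samples,
                               atol=1e-9)
            assert np.allclose(rot.gradients, table1_interleaf.gradients,
                               atol=1e-9)

    def test_half_turn_negates(self, table1_interleaf):
        rot = rotate_interleaf(table1_interleaf, 180.0)
        assert np.allclose(rot.k_samples, -table1_interleaf.k_samples,
                           atol=1e-12)

    def test_composition(self, table1_interleaf):
        a = rotate_interleaf(rotate_interleaf(table1_interleaf, 40.0), 50.0)
        b = rotate_interleaf(table1_interleaf, 90.0)
        assert np.allclose(a.k_samples, b.k_samples, atol=1e-12)

    def test_counterclockwise_sense(self, table1_interleaf):
        rot = rotate_interleaf(table1_interleaf, 90.0)
        # CCW by 90 deg maps (x, y) -> (-y, x)
        k = table1_interleaf.k_samples[50]
        assert np.allclose(rot.k_samples[50], [-k[1], k[0]], atol=1e-12)

    def test_nonfinite_angle_rejected(self, table1_interleaf):
        with pytest.raises(ValueError):
            rotate_interleaf(table1_interleaf, np.nan)


class TestSchedule:
    def test_protocol_framing(self):
        s = build_schedule(4.0, 11.0)
        assert s.n_frames == 90
        assert s.frame_duration == 44.0

    def test_single_frame_boundary(self):
        assert build_schedule(0.044, 11.0).n_frames == 1

    def test_too_short_scan_raises(self):
        with pytest.raises(ValueError):
            build_schedule(0.043, 11.0)

    def test_golden_angle_sequence(self):
        s = build_schedule(4.0, 11.0)
        phi = (1 + np.sqrt(5)) / 2
        oracle = [(n * (360 - 360 / phi)) % 360 for n in range(3)]
        got = [f.base_angle for f in s.frames[:3]]
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got[1] == pytest.approx(137.50776, abs=1e-5)

    def test_frame_layout(self):
        s = build_schedule(4.0, 11.0)
        for f in s.frames[:5]:
            enc = [r.encoding for r in f.readouts]
            assert enc == ["FC", "FE", "FC", "FE"]
            assert f.readouts[2].base_angle == pytest.approx(
                (f.readouts[0].base_angle + 180.0) % 360.0)
            starts = [r.start_time for r in f.readouts]
            assert np.allclose(np.diff(starts), s.tr)

    def test_start_times_contiguous(self):
        s = build_schedule(1.0, 11.0)
        starts = [r.start_time for f in s.frames for r in f.readouts]
        assert np.allclose(np.diff(starts), s.tr)

    def test_frame_count_brackets_scan_time(self):
        for scan in (0.8, 1.37, 4.0):
            s = build_schedule(scan, 11.0)
            assert s.frame_duration * s.n_frames <= scan * 1e3
            assert scan * 1e3 < s.frame_duration * (s.n_frames + 1)

    def test_golden_angle_window_uniformity(self):
        """Any 90-frame window covers angles with max gap below 8 deg."""
        s = build_schedule(4.0, 11.0)
        ang = np.sort([f.base_angle % 360 for f in s.frames])
        gaps = np.diff(np.r_[ang, ang[0] + 360.0])
        assert gaps.max() < 8.0
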