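"""Phase-contrast velocimetry: phase difference, Maxwell correction,
VENC scaling, and temporal phase unwrapping.

Sign convention: positive velocity is through-plane along the slice normal
of the flow-encoding bipolar, i.e. a positive phase of ``FE * conj(FC)``.
Background (eddy-current) phase is reported, not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .constants import GAMMA_RAD_PER_S_T

__all__ = ["VelocitySeries", "phase_difference", "maxwell_correction",
           "concomitant_integral", "to_velocity", "unwrap_temporal"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VelocitySeries:
    """Through-plane velocity maps, cm/s.

    ``low_confidence`` marks pixels whose FC magnitude was (near) zero, where
    the phase difference is defined as 0.
    """

    v_maps: np.ndarray          # (n_frames, N, N) cm/s
    frame_times: np.ndarray     # ms, strictly increasing
    venc: float                 # cm/s
    wrap_corrected: bool = False
    maxwell_corrected: bool = False
    low_confidence: np.ndarray | None = None

    def __post_init__(self):
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        ft = np.asarray(self.frame_times)
        if ft.size > 1 and np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")


def phase_difference(fc, fe, mag_floor_rel: float = 1e-3):
    """Pixelwise phase difference arg(FE * conj(FC)), radians in (-pi, pi].

    Accepts :class:`~spiralpc.recon.ImageSeries` or bare complex arrays of
    matching shape.  Returns ``(dphi, low_confidence)``; where the FC
    magnitude is below ``mag_floor_rel`` times its maximum the phase is set
    to 0 and the low-confidence mask bit raised.
    """
    fc_arr = np.asarray(getattr(fc, "frames", fc))
    fe_arr = np.asarray(getattr(fe, "frames", fe))
    if fc_arr.shape != fe_arr.shape:
        raise ValueError(
            f"FC/FE shape mismatch: {fc_arr.shape} vs {fe_arr.shape}")
    prod = fe_arr * np.conj(fc_arr)
    dphi = np.angle(prod)
    floor = mag_floor_rel * np.abs(fc_arr).max()
    low = np.abs(fc_arr) < floor
    dphi = np.where(low, 0.0, dphi)
    return dphi, low


def concomitant_integral(g_z: np.ndarray, dt_ms: float) -> float:
    """Time integral of Gz^2 over a sampled waveform, (mT/m)^2 * ms.

    Gradient waveforms are piecewise linear between samples, so the square
    is integrated exactly per segment: int (g0 + (g1-g0) t/h)^2 dt =
    h/3 * (g0^2 + g0 g1 + g1^2).
    """
    g = np.asarray(g_z, float)
    g0, g1 = g[:-1], g[1:]
    return float(dt_ms / 3.0 * np.sum(g0 * g0 + g0 * g1 + g1 * g1))


def maxwell_correction(dphi: np.ndarray, g_z_fe: np.ndarray,
                       g_z_fc: np.ndarray, dt_ms: float, b0: float,
                       fov_mm: float | None = None,
                       slice_offset_mm: float = 0.0) -> np.ndarray:
    """Subtract the lowest-order concomitant-field phase difference.

    For a transverse slice the through-plane encoding gradient Gz produces
    the concomitant field ``Gz^2 (x^2+y^2) / (8 B0)``; integrating over the
    FE and FC waveforms and differencing gives the quadratic phase map that
    is removed here.  The in-plane readout gradients are identical between
    the two encodings and cancel.  Only these self-squared lowest-order
    terms are handled.

    Parameters
    ----------
    dphi : (..., N, N) phase-difference maps, radians.
    g_z_fe, g_z_fc : through-plane gradient waveforms, mT/m, at ``dt_ms``.
    b0 : main field, T.
    fov_mm : in-plane field of view; if None the correction is skipped with
        a logged warning (missing geometry).
    """
    if fov_mm is None:
        log.warning("maxwell_correction: slice geometry missing; skipped")
        return np.asarray(dphi)
    matrix = dphi.shape[-1]
    delta = (concomitant_integral(g_z_fe, dt_ms)
             - concomitant_integral(g_z_fc, dt_ms)) * 1e-9  # (T/m)^2 * s
    c = (np.arange(matrix) - matrix // 2) * (fov_mm / matrix)
    x, y = np.meshgrid(c, c, indexing="ij")
    r2_m = (x ** 2 + y ** 2) * 1e-6
    phi_c = GAMMA_RAD_PER_S_T / (8.0 * b0) * r2_m * delta
    return np.asarray(dphi) - phi_c


def trapezoid_bipolar(amplitude: float, ramp_ms: float, flat_ms: float,
                      dt_ms: float) -> np.ndarray:
    """Sampled bipolar Gz waveform: +lobe then -lobe (trapezoids), mT/m."""
    n_r = max(int(round(ramp_ms / dt_ms)), 1)
    n_f = max(int(round(flat_ms / dt_ms)), 0)
    up = np.linspace(0, amplitude, n_r, endpoint=False)
    flat = np.full(n_f, amplitude)
    down = np.linspace(amplitude, 0, n_r, endpoint=False)
    lobe = np.concatenate([up, flat, down])
    return np.concatenate([lobe, -lobe, [0.0]])


def encoding_waveforms(venc_cm_s: float, amplitude: float, ramp_ms: float,
                       dt_ms: float = 0.005
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Model Gz waveforms of the two encodings for a given VENC.

    The flow-encoding bipolar is two back-to-back trapezoid lobes whose
    flat time is solved so the first moment gives phase pi at ``venc``
    (|m1| = amplitude * (flat + ramp) * (flat + 2 ramp) for this geometry);
    the flow-compensated encoding is modeled with zero net
    velocity-encoding gradient.  Returns ``(g_fe, g_fc, dt_ms)`` in mT/m.
    """
    venc_si = venc_cm_s * 1e-2
    m1 = np.pi / (GAMMA_RAD_PER_S_T * venc_si) * 1e9  # mT/m * ms^2
    flat = 0.5 * (-3.0 * ramp_ms
                  + np.sqrt(ramp_ms * ramp_ms + 4.0 * m1 / amplitude))
    if flat >= 0:
        g_fe = trapezoid_bipolar(amplitude, ramp_ms, flat, dt_ms)
    else:
        # slew-limited triangular lobes at reduced amplitude
        r_tri = (m1 * ramp_ms / (2.0 * amplitude)) ** (1.0 / 3.0)
        g_fe = trapezoid_bipolar(amplitude * r_tri / ramp_ms, r_tri, 0.0,
                                 dt_ms)
    return g_fe, np.zeros_like(g_fe), dt_ms


def to_velocity(dphi: np.ndarray, venc: float,
                frame_times: np.ndarray | None = None,
                low_confidence: np.ndarray | None = None,
                maxwell_corrected: bool = False) -> VelocitySeries:
    """Map phase difference to velocity: v = venc * dphi / pi (cm/s)."""
    if venc <= 0:
        raise ValueError("venc must be positive")
    dphi = np.asarray(dphi)
    if frame_times is None:
        frame_times = np.arange(dphi.shape[0], dtype=float)
    return VelocitySeries(v_maps=venc * dphi / np.pi,
                          frame_times=np.asarray(frame_times, float),
                          venc=venc, low_confidence=low_confidence,
                          maxwell_corrected=maxwell_corrected)


def unwrap_temporal(series: VelocitySeries) -> VelocitySeries:
    """Pixelwise temporal phase unwrapping.

    Sweeping forward in time, each frame is shifted by the integer multiple
    of 2*venc that minimizes its jump against the previous (already
    unwrapped) frame.  Idempotent on series whose frame-to-frame jumps are
    already below venc.
    """
    v = np.asarray(series.v_maps)
    if v.shape[0] < 2:
        raise ValueError("temporal unwrapping needs at least two frames")
    venc = series.venc
    out = v.copy()
    for t in range(1, v.shape[0]):
        jump = out[t - 1] - out[t]
        out[t] = out[t] + 2.0 * venc * np.round(jump / (2.0 * venc))
    return replace(series, v_maps=out, wrap_corrected=True)
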