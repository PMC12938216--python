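"""Dual-density spiral-out trajectory design and golden-angle scheduling.

The readout is a variable-density Archimedean spiral designed under hardware
gradient amplitude and slew-rate limits.  The central portion of the readout
samples k-space radially at a multiple of the Nyquist arm spacing (1/FOV) and
the periphery at a lower multiple; the density transition is specified as a
fraction of the readout *time* and smoothed with a short cosine taper so the
gradient waveform stays continuous.

Design procedure
----------------
1. A time-optimal traversal of the spiral is integrated with the arm pitch as
   a free parameter.  The pitch is opened (radially faster, i.e. more rotated
   copies ``n_design`` would be needed for a full set) exactly as far as the
   gradient system forces in order to reach ``k_max`` within the prescribed
   readout window — but never tighter than the density prescription itself,
   so that relaxing the hardware limits shortens the readout instead of
   absurdly tightening the spiral.
2. The *fully-sampled interleaf count* ``n_full`` is the total
   Nyquist-weighted annular sampling requirement of the dual-density
   prescription divided by the number of samples one interleaf delivers at
   the ADC dwell (rounded up).  The quoted acceleration factor is ``n_full``
   divided by the number of interleaves actually acquired per velocity
   encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi

from .constants import GOLDEN_ANGLE_DEG, K_PER_G

__all__ = [
    "GradientLimits",
    "SpiralDesignSpec",
    "SpiralInterleaf",
    "AcquisitionSchedule",
    "Readout",
    "FrameSchedule",
    "InfeasibleSpiralError",
    "design_dual_density_spiral",
    "rotate_interleaf",
    "build_schedule",
    "density_compensation_weights",
    "acceleration_factor",
    "matrix_size",
]


class InfeasibleSpiralError(ValueError):
    """Raised when no spiral can reach k_max within the readout window."""


@dataclass(frozen=True)
class GradientLimits:
    """Hardware gradient limits.

    Attributes
    ----------
    g_max : float
        Maximum gradient amplitude, mT/m.
    s_max : float
        Maximum slew rate, T/m/s (numerically equal to mT/m per ms).
    """

    g_max: float = 26.0
    s_max: float = 45.0

    def __post_init__(self):
        if not (self.g_max > 0 and self.s_max > 0):
            raise ValueError("gradient limits must be positive")


@dataclass(frozen=True)
class SpiralDesignSpec:
    """Prescription for one dual-density spiral-out interleaf.

    Defaults follow the real-time protocol: 300 mm FOV, 2.3 mm resolution,
    5.32 ms readout, the central 30 % of the readout at twice the Nyquist
    arm density and the remainder at 0.6x, on a 26 mT/m / 45 T/m/s system.
    The ADC dwell defaults to the value implied by the receiver bandwidth
    of 1116 Hz/px at the rounded-up even matrix size.
    """

    fov: float = 300.0            # mm
    resolution: float = 2.3       # mm
    readout_duration: float = 5.32  # ms
    center_fraction: float = 0.30
    center_density: float = 2.0   # multiple of Nyquist
    outer_density: float = 0.6    # multiple of Nyquist
    dwell: float | None = None    # µs; None -> derived from bandwidth
    bandwidth_per_pixel: float = 1116.0  # Hz/px
    taper_fraction: float = 0.05  # cosine density taper width, readout fraction
    limits: GradientLimits = field(default_factory=GradientLimits)

    def __post_init__(self):
        if not 0.0 < self.center_fraction < 1.0:
            raise ValueError("center_fraction must lie in (0, 1)")
        if self.center_density <= 0 or self.outer_density <= 0:
            raise ValueError("densities must be positive")
        if not self.resolution < self.fov:
            raise ValueError("resolution must be smaller than FOV")
        if self.readout_duration <= 0:
            raise ValueError("readout_duration must be positive")

    @property
    def k_max(self) -> float:
        """Edge of k-space, cycles/mm."""
        return 1.0 / (2.0 * self.resolution)

    @property
    def matrix(self) -> int:
        return matrix_size(self.fov, self.resolution)

    @property
    def dwell_us(self) -> float:
        if self.dwell is not None:
            return float(self.dwell)
        return 1e6 / (self.bandwidth_per_pixel * self.matrix)

    def density_at(self, time_fraction: np.ndarray | float) -> np.ndarray:
        """Radial sampling density (multiple of Nyquist) vs readout fraction."""
        lo = self.center_fraction - self.taper_fraction / 2.0
        hi = self.center_fraction + self.taper_fraction / 2.0
        f = np.clip((np.asarray(time_fraction, float) - lo) / (hi - lo), 0.0, 1.0)
        w = 0.5 * (1.0 + np.cos(np.pi * f))
        return self.outer_density + (self.center_density - self.outer_density) * w


def matrix_size(fov: float, resolution: float) -> int:
    """Image matrix: fov/resolution rounded up to the next even integer."""
    n = int(np.ceil(fov / resolution))
    return n + (n % 2)


@dataclass(frozen=True)
class SpiralInterleaf:
    """One spiral-out readout.

    ``k_samples`` are (kx, ky) in cycles/mm at ADC dwell spacing, starting at
    the k-space origin; ``gradients`` the corresponding (gx, gy) in mT/m.
    ``n_design`` is the (real-valued) number of rotated copies whose arm
    spacing matches the designed pitch; ``n_full`` the integer number of
    copies needed to satisfy the dual-density sample budget.
    """

    k_samples: np.ndarray    # (N, 2) cycles/mm
    gradients: np.ndarray    # (N, 2) mT/m
    dwell: float             # µs
    duration: float          # ms
    n_design: float = float("nan")
    n_full: int = 0
    required_samples: float = float("nan")

    @property
    def n_samples(self) -> int:
        return self.k_samples.shape[0]

    @property
    def k_radius(self) -> np.ndarray:
        return np.hypot(self.k_samples[:, 0], self.k_samples[:, 1])


@dataclass(frozen=True)
class Readout:
    encoding: str          # "FC" | "FE"
    base_angle: float      # degrees, counterclockwise
    start_time: float      # ms


@dataclass(frozen=True)
class FrameSchedule:
    index: int
    base_angle: float
    readouts: tuple[Readout, ...]

    @property
    def mid_time(self) -> float:
        t0 = self.readouts[0].start_time
        t1 = self.readouts[-1].start_time
        return 0.5 * (t0 + t1)


@dataclass(frozen=True)
class AcquisitionSchedule:
    frames: tuple[FrameSchedule, ...]
    tr: float              # ms
    frame_duration: float  # ms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_times(self) -> np.ndarray:
        return np.array([f.mid_time for f in self.frames])


# ---------------------------------------------------------------------------
# time-optimal integration


def _integrate(spec: SpiralDesignSpec, n_arms: float, dt: float = 2e-4,
               safety: float = 0.99):
    """Integrate the slew-/amplitude-limited traversal of the spiral whose
    full set of ``n_arms`` rotated copies realizes the density prescription.

    Returns (t, r, theta) arrays on the fine time grid (ms), or None if
    ``k_max`` was not reached within 4x the readout window.
    """
    from math import cos, pi, sqrt

    lim = spec.limits
    a_max = K_PER_G * min(lim.s_max, 1e7) * safety   # cycles/mm/ms^2
    v_max = K_PER_G * min(lim.g_max, 1e7) * safety   # cycles/mm/ms
    k_max = spec.k_max
    t_ro = spec.readout_duration
    two_pi_fov = 2.0 * pi * spec.fov

    # scalar density schedule (cosine taper around the transition)
    lo = spec.center_fraction - spec.taper_fraction / 2.0
    hi = spec.center_fraction + spec.taper_fraction / 2.0
    dc, do = spec.center_density, spec.outer_density
    inv_width = 1.0 / (hi - lo)

    t = r = theta = v = 0.0
    ts = [0.0]
    rs = [0.0]
    thetas = [0.0]
    t_limit = 4.0 * t_ro
    a2 = a_max * a_max
    while r < k_max:
        f = (t / t_ro - lo) * inv_width
        if f <= 0.0:
            d = dc
        elif f >= 1.0:
            d = do
        else:
            d = do + (dc - do) * 0.5 * (1.0 + cos(pi * f))
        rp = n_arms / (two_pi_fov * d)        # dr/dtheta
        r2 = r * r
        rp2 = rp * rp
        hyp = r2 + rp2
        kappa = (r2 + 2.0 * rp2) / (hyp * sqrt(hyp))
        v_lim = sqrt(a_max / kappa)
        if v_max < v_lim:
            v_lim = v_max
        a_norm = kappa * v * v
        gap = a2 - a_norm * a_norm
        v = v + (sqrt(gap) * dt if gap > 0.0 else 0.0)
        if v > v_lim:
            v = v_lim
        dtheta = v * dt / sqrt(hyp)
        theta += dtheta
        r += rp * dtheta
        t += dt
        ts.append(t)
        rs.append(r)
        thetas.append(theta)
        if t > t_limit:
            return None
    return np.asarray(ts), np.asarray(rs), np.asarray(thetas)


def _duration(spec: SpiralDesignSpec, n_arms: float, dt: float = 1e-3) -> float:
    out = _integrate(spec, n_arms, dt=dt)
    return np.inf if out is None else out[0][-1]


def _required_samples(spec: SpiralDesignSpec, t: np.ndarray, r: np.ndarray) -> float:
    """Total Nyquist-weighted sample count of the dual-density prescription.

    At density d the prescription asks for d * FOV^2 samples per unit k-space
    area; the annular requirement is integrated along the designed radius
    profile r(t), which maps the time-based density schedule onto k-radius.
    """
    d = spec.density_at(t / spec.readout_duration)
    drdt = np.gradient(r, t)
    integrand = d * 2.0 * np.pi * r * drdt
    return float(spec.fov ** 2 * np.trapezoid(integrand, t))


def design_dual_density_spiral(spec: SpiralDesignSpec) -> SpiralInterleaf:
    """Design the time-optimal dual-density spiral-out interleaf.

    Results are cached per spec; treat the returned arrays as read-only.

    Raises
    ------
    InfeasibleSpiralError
        If k_max cannot be reached within the readout window even with a
        maximally opened pitch, naming the binding hardware constraint.
    """
    return _design_cached(spec)


@lru_cache(maxsize=32)
def _design_cached(spec: SpiralDesignSpec) -> SpiralInterleaf:
    t_ro = spec.readout_duration

    # 1. pitch fit: smallest n_arms whose time-optimal traversal fits the window
    n_hi = 512.0
    if _duration(spec, n_hi) > t_ro:
        # even a nearly radial arm cannot get there in time
        v_max = K_PER_G * spec.limits.g_max
        ramp = v_max / (K_PER_G * spec.limits.s_max)
        reachable = v_max * (t_ro - min(ramp, t_ro) / 2.0)
        binding = "slew rate" if ramp > t_ro else "gradient amplitude"
        raise InfeasibleSpiralError(
            f"k_max {spec.k_max:.4f} cycles/mm unreachable in "
            f"{t_ro:.3f} ms readout; binding constraint: {binding} "
            f"(max reachable radius ~{reachable:.4f} cycles/mm)")
    n_lo = 0.25
    if _duration(spec, n_lo) <= t_ro:
        n_star = n_lo
    else:
        lo, hi = n_lo, n_hi
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if _duration(spec, mid) > t_ro:
                lo = mid
            else:
                hi = mid
        n_star = hi

    # the coarse-dt bisection can land a hair over the window; tighten the
    # pitch until the finely integrated duration fits
    t, r, theta = _integrate(spec, n_star)
    while t[-1] > t_ro:
        n_star *= 1.004
        t, r, theta = _integrate(spec, n_star)

    # 2. sample budget at the trial pitch
    n_samples = int(np.floor(t_ro * 1e3 / spec.dwell_us))
    req = _required_samples(spec, t, r)
    n_full = int(np.ceil(req / n_samples - 1e-9))

    # 3. never design tighter than the density prescription itself: if the
    #    hardware is not binding, use the prescription's own pitch and let
    #    the readout underrun the window.
    n_design = max(n_star, float(n_full))
    if n_design != n_star:
        t, r, theta = _integrate(spec, n_design)

    # resample onto the ADC dwell grid (clamped at the traversal end so the
    # final sample sits at k_max even when the readout underruns the window)
    dwell_ms = spec.dwell_us * 1e-3
    n_out = min(n_samples, int(np.ceil(t[-1] / dwell_ms)) + 1)
    t_s = np.minimum(np.arange(n_out) * dwell_ms, t[-1])
    # the integrator may overshoot k_max by one fine step; clamp the radius
    r_s = np.minimum(np.interp(t_s, t, r), spec.k_max)
    th_s = np.interp(t_s, t, theta)
    k = np.column_stack([r_s * np.cos(th_s), r_s * np.sin(th_s)])

    # gradients from the fine-grid trajectory derivative, sampled at dwell
    kx_f = r * np.cos(theta)
    ky_f = r * np.sin(theta)
    gx_f = np.gradient(kx_f, t) / K_PER_G
    gy_f = np.gradient(ky_f, t) / K_PER_G
    g = np.column_stack([np.interp(t_s, t, gx_f), np.interp(t_s, t, gy_f)])

    return SpiralInterleaf(
        k_samples=k, gradients=g, dwell=spec.dwell_us, duration=float(t[-1]),
        n_design=float(n_design), n_full=n_full, required_samples=req)


def rotate_interleaf(interleaf: SpiralInterleaf, angle: float) -> SpiralInterleaf:
    """Rotate k-samples and gradients counterclockwise by ``angle`` degrees."""
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    phi = np.deg2rad(angle)
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    return replace(interleaf,
                   k_samples=interleaf.k_samples @ rot.T,
                   gradients=interleaf.gradients @ rot.T)


def acceleration_factor(spec: SpiralDesignSpec, acquired_per_encoding: int,
                        interleaf: SpiralInterleaf | None = None) -> float:
    """Undersampling factor R = n_full / interleaves acquired per encoding."""
    if acquired_per_encoding < 1:
        raise ValueError("acquired_per_encoding must be >= 1")
    if interleaf is None:
        interleaf = design_dual_density_spiral(spec)
    return interleaf.n_full / acquired_per_encoding


def build_schedule(scan_time: float, tr: float) -> AcquisitionSchedule:
    """Golden-angle FC/FE frame schedule.

    Each 4*TR frame holds FC(θ), FE(θ), FC(θ+180°), FE(θ+180°) back-to-back;
    θ advances by the golden angle from frame to frame.

    Parameters
    ----------
    scan_time : float
        Total scan time, seconds.
    tr : float
        Repetition time, ms.
    """
    if scan_time <= 0 or tr <= 0:
        raise ValueError("scan_time and tr must be positive")
    frame_duration = 4.0 * tr
    n_frames = int(np.floor(scan_time * 1e3 / frame_duration))
    if n_frames < 1:
        raise ValueError(
            f"scan time {scan_time} s shorter than one frame "
            f"({frame_duration} ms)")
    frames = []
    for n in range(n_frames):
        base = (n * GOLDEN_ANGLE_DEG) % 360.0
        t0 = n * frame_duration
        readouts = (
            Readout("FC", base, t0),
            Readout("FE", base, t0 + tr),
            Readout("FC", (base + 180.0) % 360.0, t0 + 2 * tr),
            Readout("FE", (base + 180.0) % 360.0, t0 + 3 * tr),
        )
        frames.append(FrameSchedule(index=n, base_angle=base, readouts=readouts))
    return AcquisitionSchedule(frames=tuple(frames), tr=tr,
                               frame_duration=frame_duration)


# ---------------------------------------------------------------------------
# density compensation


def density_compensation_weights(
        interleaves: Sequence[SpiralInterleaf] | np.ndarray,
        nominal_cell_area: float = 1.0) -> np.ndarray:
    """Voronoi-cell-area density compensation weights.

    Accepts a list of interleaves (samples are stacked in order) or a raw
    (M, 2) array of k-space points.  Coincident samples share their cell's
    weight equally.  Unbounded edge cells are closed by a guard ring placed
    just outside the sample cloud; for degenerate clouds (< 4 distinct
    points) all samples share ``nominal_cell_area`` equally.

    Returns strictly positive weights, one per input sample.
    """
    if isinstance(interleaves, np.ndarray):
        pts = np.asarray(interleaves, float)
    else:
        if len(interleaves) == 0:
            raise ValueError("need at least one interleaf")
        pts = np.vstack([il.k_samples for il in interleaves])
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected (M, 2) sample coordinates")
    m = pts.shape[0]

    # group coincident samples
    r_max = float(np.hypot(pts[:, 0], pts[:, 1]).max())
    scale = max(r_max, 1e-12)
    key = np.round(pts / (1e-9 * scale)).astype(np.int64)
    uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                      return_counts=True)
    upts = np.zeros((uniq.shape[0], 2))
    np.add.at(upts, inverse, pts)
    upts /= counts[:, None]

    if upts.shape[0] < 4:
        return np.full(m, nominal_cell_area / m)

    # guard ring closes all real cells
    nn = _median_spacing(upts)
    n_guard = max(64, int(np.ceil(2 * np.pi * (r_max + nn) / max(nn, 1e-12))))
    n_guard = min(n_guard, 4096)
    ang = np.linspace(0, 2 * np.pi, n_guard, endpoint=False)
    guard_r = r_max + 2.0 * nn
    guard = guard_r * np.column_stack([np.cos(ang), np.sin(ang)])
    vor = Voronoi(np.vstack([upts, guard]))

    areas = np.empty(upts.shape[0])
    for i in range(upts.shape[0]):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            areas[i] = nn * nn  # should not happen with the guard ring
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    areas = np.maximum(areas, 1e-18)
    return areas[inverse] / counts[inverse]


def _median_spacing(pts: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(np.median(d[:, 1]))
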