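"""Pulsatile two-vessel digital flow phantom and spiral k-space simulation.

The phantom emulates a transverse chest slice at mid field: an elliptical
torso of static tissue containing an aorta-like (AO) and a main pulmonary
artery-like (MPA) vessel with pulsatile through-plane flow, beat-to-beat RR
variability, respiratory modulation of the systolic peak, smooth multi-coil
receive sensitivities, and complex Gaussian noise at a low-field-like SNR.

Signal model: two-point phase-contrast encoding.  The flow-encoded (FE)
image equals the flow-compensated (FC) image with an extra phase
``pi * v / venc`` inside the vessels (parabolic lumen profile) plus,
optionally, the lowest-order concomitant-field (Maxwell) phase of the
flow-encoding bipolar gradient, which downstream processing is expected to
remove.  No relaxation, slice-profile, or in-plane motion effects are
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import GAMMA_RAD_PER_S_T
from .nufft import NufftPlan
from .trajectory import AcquisitionSchedule, SpiralInterleaf, rotate_interleaf

__all__ = [
    "VesselSpec", "PhantomConfig", "CoilMaps", "KSpaceData",
    "beat_onsets", "velocity_waveform", "render_frame_pair",
    "simulate_coils", "simulate_acquisition", "ground_truth_measures",
    "default_config", "arrhythmia_config", "bipolar_moment_integrals",
]


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: a disc with parabolic through-plane velocity profile."""

    label: str                  # "AO" | "MPA"
    center: tuple[float, float]  # (x, y) mm from isocenter
    radius: float               # mm
    peak_velocity: float        # cm/s at lumen center, systolic peak
    systole_fraction: float = 0.38  # fraction of RR occupied by the pulse
    baseline: float = 0.0       # diastolic velocity, cm/s


@dataclass(frozen=True)
class PhantomConfig:
    matrix: int = 132
    fov: float = 300.0              # mm
    vessels: tuple[VesselSpec, ...] = (
        VesselSpec("AO", (-38.0, -5.0), 14.0, 115.0),
        VesselSpec("MPA", (30.0, 15.0), 16.0, 82.0),
    )
    rr_mean: float = 900.0          # ms
    rr_cv: float = 0.05             # fractional RR standard deviation
    resp_period: float = 4.0        # s
    resp_amp: float = 0.06          # fractional modulation of systolic peak
    background_magnitude: float = 1.0
    vessel_magnitude: float = 1.4
    venc: float = 200.0             # cm/s
    noise_sigma: float = 8.0        # k-space noise std (a.u.); calibrated so
                                    # the zero-filled per-frame recon has
                                    # vessel-lumen magnitude SNR ~ 10
    n_coils: int = 8
    seed: int = 1234
    b0: float = 0.55                # T
    concomitant: bool = True
    bipolar_amplitude: float = 20.0  # mT/m, flow-encoding lobe amplitude
    bipolar_ramp: float = 0.3       # ms

    def __post_init__(self):
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if not 0.0 <= self.resp_amp < 1.0:
            raise ValueError("resp_amp must lie in [0, 1)")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        half = self.fov / 2.0
        for v in self.vessels:
            if np.hypot(*v.center) + v.radius > half:
                raise ValueError(f"vessel {v.label} exceeds the FOV")

    @property
    def pixel_mm(self) -> float:
        return self.fov / self.matrix

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x, y) in mm, 'ij' indexed."""
        c = (np.arange(self.matrix) - self.matrix // 2) * self.pixel_mm
        return np.meshgrid(c, c, indexing="ij")


@dataclass(frozen=True)
class CoilMaps:
    """Complex receive sensitivities, (n_coils, N, N), unitless."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class KSpaceData:
    """Multi-coil non-Cartesian k-space with per-readout labels.

    One row per readout; maps 1:1 onto MRD-style acquisitions.
    """

    data: np.ndarray          # (n_acq, n_coils, n_k) complex
    traj: np.ndarray          # (n_acq, n_k, 2) cycles/mm
    encoding: np.ndarray      # (n_acq,) "FC" | "FE"
    base_angle: np.ndarray    # (n_acq,) degrees
    timestamp: np.ndarray     # (n_acq,) ms
    frame_index: np.ndarray   # (n_acq,) int
    header: dict = field(default_factory=dict)

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# cardiac timing and waveforms


def beat_onsets(config: PhantomConfig, scan_ms: float,
                rng: np.random.Generator | None = None,
                first_onset: float = 60.0) -> np.ndarray:
    """Draw beat onset times covering the scan.

    RR intervals are ``rr_mean * (1 + rr_cv * z)`` with z standard normal
    (clipped at ±3 sd to keep intervals physiologic), seeded via the config.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    onsets = [first_onset]
    while onsets[-1] < scan_ms + 2 * config.rr_mean:
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        rr = config.rr_mean * max(1.0 + config.rr_cv * z, 0.2)
        onsets.append(onsets[-1] + rr)
    return np.asarray(onsets)


def velocity_waveform(t, beat_onsets: np.ndarray, vessel: VesselSpec,
                      resp_amp: float = 0.0, resp_period: float = 4.0):
    """Lumen-center velocity v(t) in cm/s.

    Each beat carries a single raised-cosine (sin^2) systolic pulse spanning
    ``systole_fraction`` of its RR interval, on a flat diastolic baseline;
    times before the first onset sit at the baseline.  The pulsatile
    component is multiplied by ``1 + resp_amp * sin(2*pi*t / resp_period)``
    (t in ms, period in s).
    """
    onsets = np.asarray(beat_onsets, float)
    if onsets.ndim != 1 or np.any(np.diff(onsets) <= 0):
        raise ValueError("beat onsets must be strictly increasing")
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    idx = np.searchsorted(onsets, t, side="right") - 1
    v = np.full(t.shape, vessel.baseline, float)
    valid = (idx >= 0) & (idx < onsets.size - 1)
    if np.any(valid):
        on = onsets[idx[valid]]
        rr = onsets[idx[valid] + 1] - on
        tau = (t[valid] - on) / (vessel.systole_fraction * rr)
        pulse = np.where(tau < 1.0, np.sin(np.pi * np.clip(tau, 0, 1)) ** 2, 0.0)
        resp = 1.0 + resp_amp * np.sin(2e-3 * np.pi * t[valid] / resp_period)
        v[valid] = vessel.baseline + \
            (vessel.peak_velocity - vessel.baseline) * pulse * resp
    return float(v[0]) if scalar else v


# ---------------------------------------------------------------------------
# image rendering


def _torso_mask(config: PhantomConfig, soft: float = 2.0) -> np.ndarray:
    x, y = config.grid()
    a, b = 0.44 * config.fov, 0.32 * config.fov
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    return 0.5 * (1.0 - np.tanh((rho - 1.0) * a / soft / 2.0))


def _vessel_profiles(config: PhantomConfig):
    """Per-vessel (support mask, parabolic profile) on the pixel grid."""
    x, y = config.grid()
    out = []
    for v in config.vessels:
        rho2 = ((x - v.center[0]) ** 2 + (y - v.center[1]) ** 2) / v.radius ** 2
        inside = rho2 <= 1.0
        out.append((inside, np.where(inside, 1.0 - rho2, 0.0)))
    return out


def bipolar_moment_integrals(config: PhantomConfig) -> tuple[float, float]:
    """Closed-form moments of the modeled flow-encoding bipolar gradient.

    The bipolar consists of two adjacent trapezoidal lobes of opposite sign
    with amplitude ``bipolar_amplitude`` and ramp time ``bipolar_ramp``; the
    flat-top time is solved so the first moment encodes ``venc``
    (phase pi at v = venc).  Returns ``(m1, int_g2)``:

    * m1: first moment magnitude, mT/m * ms^2, with gamma*m1*v = pi at venc
    * int_g2: time integral of Gz^2 over the bipolar, (mT/m)^2 * ms

    used respectively for consistency checks and for the concomitant
    (Maxwell) phase of the encoding.
    """
    # required first moment in SI: m1 = pi / (gamma * venc)
    venc_si = config.venc * 1e-2                      # m/s
    m1_si = np.pi / (GAMMA_RAD_PER_S_T * venc_si)     # T/m * s^2
    m1 = m1_si * 1e3 * 1e6                            # mT/m * ms^2
    g = config.bipolar_amplitude
    r = config.bipolar_ramp
    # trapezoid lobe (ramp r, flat f, ramp r): area a = g*(f+r); back-to-back
    # opposite lobes have centroids one lobe duration f+2r apart, so
    # |m1| = a * (f + 2r) = g*(f+r)*(f+2r); solve the quadratic for f
    f = 0.5 * (-3.0 * r + np.sqrt(r * r + 4.0 * m1 / g))
    if f >= 0:
        # int g^2 dt: flat 2*g^2*f, four ramps 4*g^2*r/3
        int_g2 = 2.0 * g * g * f + 4.0 * g * g * r / 3.0
    else:
        # moment smaller than the shortest trapezoid: slew-limited
        # triangular lobes at reduced amplitude g' = g*r'/r with
        # |m1| = 2 g' r'^2 = (2 g / r) r'^3
        r_tri = (m1 * r / (2.0 * g)) ** (1.0 / 3.0)
        g_tri = g * r_tri / r
        int_g2 = 4.0 * g_tri * g_tri * r_tri / 3.0
    return float(m1), float(int_g2)


def concomitant_phase_map(config: PhantomConfig) -> np.ndarray:
    """Lowest-order concomitant phase difference (FE - FC), radians.

    For a transverse slice the self-squared term of the through-plane
    bipolar produces ``phi = gamma/(8 B0) * (x^2+y^2) * int(Gz^2) dt``;
    the in-plane spiral gradients are shared by FC and FE and cancel in the
    difference.
    """
    if not config.concomitant:
        return np.zeros((config.matrix, config.matrix))
    _, int_g2 = bipolar_moment_integrals(config)
    # SI: (mT/m)^2 * ms = 1e-6 (T/m)^2 * 1e-3 s
    int_g2_si = int_g2 * 1e-9
    x, y = config.grid()
    r2_m = (x ** 2 + y ** 2) * 1e-6  # m^2
    return GAMMA_RAD_PER_S_T / (8.0 * config.b0) * r2_m * int_g2_si


def render_frame_pair(t: float, config: PhantomConfig,
                      onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Render the (FC, FE) complex image pair at time ``t`` (ms).

    |FC| == |FE| pixelwise; arg(FE) - arg(FC) is ``pi*v/venc`` inside the
    vessels (parabolic profile) plus the concomitant term, zero in static
    tissue.  Velocities beyond venc wrap naturally through the complex
    exponential.
    """
    mag = config.background_magnitude * _torso_mask(config)
    vmap = np.zeros((config.matrix, config.matrix))
    for vessel, (inside, profile) in zip(config.vessels,
                                         _vessel_profiles(config)):
        vc = velocity_waveform(t, onsets, vessel,
                               config.resp_amp, config.resp_period)
        mag = np.where(inside, config.vessel_magnitude, mag)
        vmap += vc * profile

    x, y = config.grid()
    # mild smooth background phase (shim-like), shared by FC and FE
    phi0 = 0.25 * np.sin(2 * np.pi * x / config.fov) \
        + 0.18 * np.cos(2 * np.pi * y / config.fov)
    dphi = np.pi * vmap / config.venc + concomitant_phase_map(config)
    fc = mag * np.exp(1j * phi0)
    fe = mag * np.exp(1j * (phi0 + dphi))
    return fc, fe


def velocity_truth_series(config: PhantomConfig, onsets: np.ndarray,
                          frame_times: np.ndarray) -> np.ndarray:
    """Ground-truth velocity maps (cm/s) at the given frame times."""
    out = np.zeros((len(frame_times), config.matrix, config.matrix))
    profiles = _vessel_profiles(config)
    for i, t in enumerate(frame_times):
        for vessel, (_, profile) in zip(config.vessels, profiles):
            vc = velocity_waveform(float(t), onsets, vessel,
                                   config.resp_amp, config.resp_period)
            out[i] += vc * profile
    return out


def simulate_coils(n_coils: int, matrix: int, seed: int = 0) -> CoilMaps:
    """Smooth synthetic receive sensitivities.

    Gaussian magnitude lobes centered just outside the FOV on a ring around
    the object, with a gentle linear phase per coil; deterministic for a
    given seed.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    c = np.arange(matrix) - matrix // 2
    x, y = np.meshgrid(c, c, indexing="ij")
    maps = np.empty((n_coils, matrix, matrix), complex)
    radius = 0.62 * matrix
    width = 0.85 * matrix
    for i in range(n_coils):
        ang = 2 * np.pi * i / n_coils + rng.uniform(-0.1, 0.1)
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        magn = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width ** 2)))
        slope = rng.uniform(-0.5, 0.5, 2)
        phase = 2 * np.pi * (slope[0] * x + slope[1] * y) / matrix \
            + rng.uniform(0, 2 * np.pi)
        maps[i] = magn * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return CoilMaps(maps / rss.max())


def simulate_acquisition(schedule: AcquisitionSchedule, config: PhantomConfig,
                         maps: CoilMaps, interleaf: SpiralInterleaf,
                         onsets: np.ndarray | None = None) -> KSpaceData:
    """Simulate the undersampled multi-coil spiral acquisition.

    Every scheduled readout is the forward NUFFT of the coil-weighted frame
    image (rendered once per frame at its mid-time) along the rotated
    interleaf, plus seeded complex Gaussian noise.
    """
    if onsets is None:
        scan_ms = schedule.n_frames * schedule.frame_duration
        onsets = beat_onsets(config, scan_ms)
    rng = np.random.default_rng(config.seed + 1)
    n_k = interleaf.n_samples
    n_acq = 4 * schedule.n_frames
    data = np.empty((n_acq, maps.n_coils, n_k), complex)
    traj = np.empty((n_acq, n_k, 2))
    enc = np.empty(n_acq, dtype="U2")
    angles = np.empty(n_acq)
    stamps = np.empty(n_acq)
    fidx = np.empty(n_acq, dtype=int)

    plans: dict[float, NufftPlan] = {}
    i = 0
    for frame in schedule.frames:
        fc, fe = render_frame_pair(frame.mid_time, config, onsets)
        images = {"FC": maps.maps * fc, "FE": maps.maps * fe}
        for ro in frame.readouts:
            k = rotate_interleaf(interleaf, ro.base_angle).k_samples
            plan = plans.get(ro.base_angle)
            if plan is None:
                plan = NufftPlan(k, config.matrix, config.pixel_mm)
                plans[ro.base_angle] = plan
            s = plan.forward(images[ro.encoding])
            if config.noise_sigma > 0:
                s = s + config.noise_sigma * (
                    rng.standard_normal(s.shape)
                    + 1j * rng.standard_normal(s.shape))
            data[i] = s
            traj[i] = k
            enc[i] = ro.encoding
            angles[i] = ro.base_angle
            stamps[i] = ro.start_time
            fidx[i] = frame.index
            i += 1

    _, int_g2 = (bipolar_moment_integrals(config) if config.concomitant
                 else (0.0, 0.0))
    header = {
        "fov_mm": config.fov, "matrix": config.matrix, "tr_ms": schedule.tr,
        "venc_cm_s": config.venc, "b0_t": config.b0,
        "frame_duration_ms": schedule.frame_duration,
        "n_frames": schedule.n_frames, "seed": config.seed,
        "dwell_us": interleaf.dwell,
        "bipolar_amplitude_mT_m": config.bipolar_amplitude,
        "bipolar_ramp_ms": config.bipolar_ramp,
        "concomitant": int(config.concomitant),
    }
    return KSpaceData(data=data, traj=traj, encoding=enc, base_angle=angles,
                      timestamp=stamps, frame_index=fidx, header=header)


# ---------------------------------------------------------------------------
# analytic ground truth


def ground_truth_measures(config: PhantomConfig, onsets: np.ndarray,
                          scan_ms: float, dt: float = 0.25):
    """Analytic per-beat flow measures for each vessel, plus Qp/Qs.

    For the parabolic profile the instantaneous flow rate is
    ``Q(t) = v_c(t)/2 * pi R^2`` (mean lumen velocity is half the center
    velocity).  Net flow integrates Q over each complete beat within the
    scan (fine trapezoidal quadrature at ``dt`` ms); peak flow rate and peak
    velocity are beat maxima.  Units: mL, mL/s, cm/s.

    Returns ``(per_vessel, qp_qs)`` with ``per_vessel[label]`` a list of
    dicts per beat.
    """
    onsets = np.asarray(onsets, float)
    complete = [(onsets[i], onsets[i + 1]) for i in range(onsets.size - 1)
                if onsets[i] >= 0.0 and onsets[i + 1] <= scan_ms]
    per_vessel: dict[str, list[dict]] = {}
    mean_net: dict[str, float] = {}
    for vessel in config.vessels:
        area_mm2 = np.pi * vessel.radius ** 2
        beats = []
        for (t0, t1) in complete:
            tt = np.arange(t0, t1, dt)
            vc = velocity_waveform(tt, onsets, vessel,
                                   config.resp_amp, config.resp_period)
            # cm/s * mm^2 -> mL/s carries a factor 0.01
            q = 0.5 * vc * area_mm2 * 0.01
            beats.append({
                "rr": t1 - t0,
                "net_flow": float(np.trapezoid(q, tt) * 1e-3),  # ms -> s
                "peak_flow_rate": float(q.max()),
                "peak_velocity": float(vc.max()),
            })
        per_vessel[vessel.label] = beats
        if beats:
            mean_net[vessel.label] = float(
                np.mean([b["net_flow"] for b in beats]))
    qp_qs = None
    if "AO" in mean_net and "MPA" in mean_net and mean_net["AO"] > 0:
        qp_qs = mean_net["MPA"] / mean_net["AO"]
    return per_vessel, qp_qs


# ---------------------------------------------------------------------------
# presets


def default_config(**overrides) -> PhantomConfig:
    """The default study conditions (R=6-like undersampling, SNR ~ 10)."""
    return replace(PhantomConfig(), **overrides) if overrides else PhantomConfig()


def arrhythmia_config(**overrides) -> PhantomConfig:
    """Bimodal-RR preset exercising beat-to-beat analysis.

    Alternating short/long RR intervals emulate a bigeminy-like rhythm; use
    :func:`bimodal_onsets` to generate the matching onset list.
    """
    cfg = PhantomConfig(rr_mean=900.0, rr_cv=0.0)
    return replace(cfg, **overrides) if overrides else cfg


def bimodal_onsets(scan_ms: float, rr_short: float = 650.0,
                   rr_long: float = 1150.0, first_onset: float = 60.0,
                   jitter: float = 20.0, seed: int = 7) -> np.ndarray:
    """Alternating short/long beat onsets with mild seeded jitter (ms)."""
    rng = np.random.default_rng(seed)
    onsets = [first_onset]
    k = 0
    while onsets[-1] < scan_ms + rr_long:
        rr = (rr_short if k % 2 == 0 else rr_long) + rng.uniform(-jitter, jitter)
        onsets.append(onsets[-1] + rr)
        k += 1
    return np.asarray(onsets)
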