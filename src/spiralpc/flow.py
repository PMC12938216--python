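"""Vessel flow curves, beat segmentation, and hemodynamic parameters.

Unit chain: velocity maps in cm/s, pixel areas in mm^2, so

    q [mL/s] = sum_pixels v [cm/s] * area [mm^2] * 0.01

because 1 cm/s * 1 mm^2 = 0.01 cm^3/s.  Net flow integrates q over a beat
(trapezoidal, ms -> s), peak flow rate is the beat maximum of q, and peak
velocity the beat maximum of the ROI's per-frame velocity percentile
(100th, i.e. the single-pixel maximum, by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .velocimetry import VelocitySeries

__all__ = ["VesselROI", "FlowCurve", "BeatMeasures", "extract_flow_curve",
           "segment_beats", "beat_measures", "qp_qs",
           "coefficient_of_variation", "average_over_beats",
           "threshold_rois"]

ML_PER_CM_S_MM2 = 0.01


@dataclass(frozen=True)
class VesselROI:
    """Static vessel mask on the velocity grid."""

    mask: np.ndarray      # (N, N) boolean
    label: str            # "AO" | "MPA"
    pixel_area: float     # mm^2

    def __post_init__(self):
        if not np.any(self.mask):
            raise ValueError("ROI mask is empty")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


@dataclass(frozen=True)
class FlowCurve:
    t: np.ndarray   # ms
    q: np.ndarray   # mL/s
    label: str


@dataclass(frozen=True)
class BeatMeasures:
    rr: float               # ms
    net_flow: float         # mL/beat
    peak_flow_rate: float   # mL/s
    peak_velocity: float    # cm/s


def extract_flow_curve(v: VelocitySeries, roi: VesselROI) -> FlowCurve:
    """Instantaneous flow rate q(t) over the ROI, mL/s."""
    maps = np.asarray(v.v_maps)
    if maps.shape[-2:] != roi.mask.shape:
        raise ValueError("velocity maps and ROI geometry differ")
    q = maps[:, roi.mask].sum(axis=1) * roi.pixel_area * ML_PER_CM_S_MM2
    return FlowCurve(t=np.asarray(v.frame_times, float), q=q, label=roi.label)


def segment_beats(curve: FlowCurve,
                  trigger_times: np.ndarray | None = None,
                  smooth_ms: float = 60.0,
                  min_rr_ms: float = 350.0) -> list[tuple[float, float]]:
    """Split the record into complete beats.

    With ``trigger_times`` (phantom truth or recorded ECG) the windows run
    between consecutive triggers, keeping only windows fully inside the
    record.  Without triggers, systolic upstrokes are detected on the
    Gaussian-smoothed curve (sigma ``smooth_ms``): a beat onset is the
    crossing of 25 % of the peak-to-baseline amplitude before each systolic
    peak (peaks separated by at least ``min_rr_ms``).

    Returns a list of (t_start, t_end) in ms; empty with a warning if no
    complete beat is contained.
    """
    t, q = curve.t, curve.q
    if trigger_times is not None:
        trig = np.asarray(trigger_times, float)
        windows = [(trig[i], trig[i + 1]) for i in range(trig.size - 1)
                   if trig[i] >= t[0] - 1e-9 and trig[i + 1] <= t[-1] + 1e-9]
        if not windows:
            warnings.warn("no complete beat inside the record")
        return windows

    from scipy.signal import find_peaks
    dt = float(np.median(np.diff(t)))
    qs = gaussian_filter1d(q, max(smooth_ms / dt, 1e-6))
    base = np.percentile(qs, 10)
    amp = qs.max() - base
    if amp <= 0:
        warnings.warn("flat flow curve; no beats found")
        return []
    peaks, _ = find_peaks(qs, height=base + 0.5 * amp,
                          distance=max(int(min_rr_ms / dt), 1))
    onsets = []
    thresh = base + 0.25 * amp
    for p in peaks:
        i = p
        while i > 0 and qs[i] > thresh:
            i -= 1
        onsets.append(t[i])
    onsets = np.unique(onsets)
    windows = [(onsets[i], onsets[i + 1]) for i in range(len(onsets) - 1)]
    if not windows:
        warnings.warn("no complete beat inside the record")
    return windows


def beat_measures(curve: FlowCurve, v: VelocitySeries, roi: VesselROI,
                  window: tuple[float, float],
                  velocity_percentile: float = 100.0) -> BeatMeasures:
    """Hemodynamic parameters over one beat window."""
    t0, t1 = window
    if t0 < curve.t[0] - 1e-9 or t1 > curve.t[-1] + 1e-9:
        raise ValueError("beat window outside the record")
    sel = (curve.t >= t0) & (curve.t <= t1)
    tt, qq = curve.t[sel], curve.q[sel]
    net = float(np.trapezoid(qq, tt) * 1e-3)  # mL
    maps = np.asarray(v.v_maps)[sel][:, roi.mask]
    if velocity_percentile >= 100.0:
        pv = float(maps.max())
    else:
        pv = float(np.percentile(maps, velocity_percentile, axis=1).max())
    return BeatMeasures(rr=float(t1 - t0), net_flow=net,
                        peak_flow_rate=float(qq.max()), peak_velocity=pv)


def qp_qs(mpa_mean_net_flow: float, ao_mean_net_flow: float) -> float:
    """Pulmonary-to-systemic flow ratio from beat-averaged net flows."""
    if ao_mean_net_flow <= 0:
        raise ValueError("aortic net flow must be positive")
    return mpa_mean_net_flow / ao_mean_net_flow


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample sd / mean."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("CV needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def average_over_beats(measures: list[BeatMeasures]) -> BeatMeasures:
    """Arithmetic mean of each field over complete beats."""
    if not measures:
        raise ValueError("no beats to average")
    return BeatMeasures(
        rr=float(np.mean([m.rr for m in measures])),
        net_flow=float(np.mean([m.net_flow for m in measures])),
        peak_flow_rate=float(np.mean([m.peak_flow_rate for m in measures])),
        peak_velocity=float(np.mean([m.peak_velocity for m in measures])),
    )


def threshold_rois(magnitude: np.ndarray, velocity: np.ndarray,
                   pixel_area: float, min_pixels: int = 8
                   ) -> list[VesselROI]:
    """Optional Otsu-threshold vessel finder (NOT a contouring substitute).

    Thresholds the temporal standard deviation of the velocity maps (flowing
    pixels vary, static tissue does not) and returns connected components as
    ROIs labeled ``ROI0``, ``ROI1``, ... ordered by descending size.  A
    rough helper for data without masks; phantom pipelines should use the
    known vessel geometry.
    """
    from scipy.ndimage import label as cc_label
    from skimage.filters import threshold_otsu
    score = np.std(velocity, axis=0)
    mask = score > threshold_otsu(score)
    lab, n = cc_label(mask)
    rois = []
    sizes = [(np.sum(lab == i), i) for i in range(1, n + 1)]
    for rank, (sz, i) in enumerate(sorted(sizes, reverse=True)):
        if sz < min_pixels:
            continue
        rois.append(VesselROI(mask=lab == i, label=f"ROI{rank}",
                              pixel_area=pixel_area))
    return rois
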