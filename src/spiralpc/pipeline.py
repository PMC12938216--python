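"""End-to-end pipeline stages: simulate -> recon -> quantify -> report.

Each stage consumes the previous stage's artifacts from the output
directory and records the config hash and seed so every file can be traced
to its generating configuration.  The command-line interface in
:mod:`spiralpc.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import flow as fl
from . import phantom as ph
from . import velocimetry as vel
from .config import PipelineConfig, config_hash, save_config
from .espirit import estimate_coil_maps
from .mrd import read_mrd, write_image_series, write_mrd
from .recon import cs_sense_reconstruct
from .trajectory import build_schedule, design_dual_density_spiral

__all__ = ["simulate", "reconstruct", "quantify", "report", "run_all",
           "MissingArtifactError"]

log = logging.getLogger("spiralpc.pipeline")

RAW = "raw.mrd.h5"
TRUTH = "truth.h5"
TRUTH_BEATS = "truth_beats.csv"
RECON = "recon.h5"
BEATS = "beats.csv"
CURVES = "flow_curves.csv"
SUMMARY = "summary.json"
REPORT = "agreement.json"


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not been run; the message names it."""


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{producer}' stage first")
    return path


def _stamp(config: PipelineConfig, stage: str, t0: float, outdir: Path,
           **extra):
    entry = {"stage": stage, "config_hash": config_hash(config),
             "seed": config.seed, "wall_s": round(time.time() - t0, 2)}
    entry.update(extra)
    logpath = outdir / "pipeline_log.jsonl"
    with logpath.open("a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")
    log.info("%s done in %.1fs", stage, entry["wall_s"])


def simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Design the trajectory, simulate the phantom acquisition, write MRD."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.protocol.spiral_spec()
    interleaf = design_dual_density_spiral(spec)
    schedule = build_schedule(config.protocol.scan_time_s,
                              config.protocol.tr_ms)
    pcfg = config.phantom
    scan_ms = schedule.n_frames * schedule.frame_duration
    onsets = ph.beat_onsets(pcfg, scan_ms)
    maps = ph.simulate_coils(pcfg.n_coils, pcfg.matrix, seed=pcfg.seed)
    kspace = ph.simulate_acquisition(schedule, pcfg, maps, interleaf,
                                     onsets=onsets)
    kspace.header["config_hash"] = config_hash(config)
    kspace.header["n_full"] = interleaf.n_full
    write_mrd(kspace, outdir / RAW)

    frame_times = schedule.frame_times
    truth_v = ph.velocity_truth_series(pcfg, onsets, frame_times)
    with h5py.File(outdir / TRUTH, "w") as f:
        f["velocity_cm_s"] = truth_v
        f["frame_times_ms"] = frame_times
        f["beat_onsets_ms"] = onsets
        f["coil_maps"] = maps.maps
        f.attrs["config_hash"] = config_hash(config)
        f.attrs["scan_ms"] = scan_ms
    beats, qpqs = ph.ground_truth_measures(pcfg, onsets, scan_ms)
    rows = [dict(vessel=lbl, beat=i, rr_ms=b["rr"],
                 net_flow_ml=b["net_flow"],
                 peak_flow_ml_s=b["peak_flow_rate"],
                 peak_vel_cm_s=b["peak_velocity"])
            for lbl, bl in beats.items() for i, b in enumerate(bl)]
    pd.DataFrame(rows).to_csv(outdir / TRUTH_BEATS, index=False)
    save_config(config, outdir / "config.lock.yaml")
    _stamp(config, "simulate", t0, outdir,
           n_acquisitions=kspace.n_acquisitions, n_full=interleaf.n_full,
           qp_qs_truth=qpqs)
    return outdir / RAW


def reconstruct(config: PipelineConfig, outdir: str | Path) -> Path:
    """ESPIRiT maps + CS-SENSE reconstruction of both encodings."""
    t0 = time.time()
    outdir = Path(outdir)
    kspace = read_mrd(_need(outdir / RAW, "simulate"))
    maps = estimate_coil_maps(kspace)
    fc, fe = cs_sense_reconstruct(kspace, maps, config.recon)
    with h5py.File(outdir / RECON, "w") as f:
        f["fc"] = fc.frames
        f["fe"] = fe.frames
        f["frame_times_ms"] = fc.frame_times
        for key, val in kspace.header.items():
            f.attrs[key] = val
    pix = kspace.header["fov_mm"] / kspace.header["matrix"]
    dt = kspace.header["frame_duration_ms"]
    meta = {"config_hash": kspace.header.get("config_hash", ""),
            "venc_cm_s": kspace.header["venc_cm_s"]}
    for series, name in ((fc, "fc"), (fe, "fe")):
        write_image_series(np.abs(series.frames), outdir / f"{name}_mag.nii",
                           pix, dt, "a.u.", meta)
        write_image_series(np.angle(series.frames),
                           outdir / f"{name}_phase.nii", pix, dt, "rad", meta)
    _stamp(config, "recon", t0, outdir, n_frames=fc.n_frames)
    return outdir / RECON


def quantify(config: PipelineConfig, outdir: str | Path) -> Path:
    """Velocity maps, flow curves, per-beat measures, summary statistics."""
    t0 = time.time()
    outdir = Path(outdir)
    with h5py.File(_need(outdir / RECON, "recon"), "r") as f:
        fc = f["fc"][()]
        fe = f["fe"][()]
        frame_times = f["frame_times_ms"][()]
        header = dict(f.attrs)

    venc = float(header["venc_cm_s"])
    dphi, lowconf = vel.phase_difference(fc, fe)
    if int(header.get("concomitant", 0)):
        g_fe, g_fc, dt_g = vel.encoding_waveforms(
            venc, float(header["bipolar_amplitude_mT_m"]),
            float(header["bipolar_ramp_ms"]))
        dphi = vel.maxwell_correction(dphi, g_fe, g_fc, dt_g,
                                      float(header["b0_t"]),
                                      fov_mm=float(header["fov_mm"]))
        maxwell = True
    else:
        maxwell = False
    series = vel.to_velocity(dphi, venc, frame_times, lowconf,
                             maxwell_corrected=maxwell)
    series = vel.unwrap_temporal(series)

    pix = float(header["fov_mm"]) / int(header["matrix"])
    meta = {"config_hash": header.get("config_hash", ""), "venc_cm_s": venc,
            "wrap_corrected": True, "maxwell_corrected": maxwell}
    write_image_series(series.v_maps, outdir / "velocity.nii", pix,
                       float(header["frame_duration_ms"]), "cm/s", meta)
    write_image_series(series.low_confidence.astype(np.float32),
                       outdir / "velocity_mask.nii", pix,
                       float(header["frame_duration_ms"]), "bool", meta)

    # ROIs: the phantom's known vessel geometry
    rois = _phantom_rois(config)
    triggers = None
    if config.analysis.use_true_triggers and (outdir / TRUTH).exists():
        with h5py.File(outdir / TRUTH, "r") as f:
            triggers = f["beat_onsets_ms"][()]

    rows, curve_rows, summary = [], [], {}
    net_by_vessel = {}
    for roi in rois:
        curve = fl.extract_flow_curve(series, roi)
        curve_rows += [dict(vessel=roi.label, t_ms=t, q_ml_s=q)
                       for t, q in zip(curve.t, curve.q)]
        windows = fl.segment_beats(curve, trigger_times=triggers)
        beats = [fl.beat_measures(curve, series, roi, w,
                                  config.analysis.velocity_percentile)
                 for w in windows]
        for i, b in enumerate(beats):
            rows.append(dict(vessel=roi.label, beat=i, rr_ms=b.rr,
                             net_flow_ml=b.net_flow,
                             peak_flow_ml_s=b.peak_flow_rate,
                             peak_vel_cm_s=b.peak_velocity))
        if beats:
            mean = fl.average_over_beats(beats)
            net_by_vessel[roi.label] = mean.net_flow
            cv = {}
            if len(beats) >= 2:
                for name, vals in (
                        ("net_flow", [b.net_flow for b in beats]),
                        ("peak_flow_rate", [b.peak_flow_rate for b in beats]),
                        ("peak_velocity", [b.peak_velocity for b in beats]),
                        ("rr", [b.rr for b in beats])):
                    cv[name] = fl.coefficient_of_variation(vals)
            summary[roi.label] = {
                "n_beats": len(beats), "mean_rr_ms": mean.rr,
                "mean_net_flow_ml": mean.net_flow,
                "mean_peak_flow_ml_s": mean.peak_flow_rate,
                "mean_peak_vel_cm_s": mean.peak_velocity, "cv_percent": cv}
    if {"AO", "MPA"} <= net_by_vessel.keys():
        summary["qp_qs"] = fl.qp_qs(net_by_vessel["MPA"], net_by_vessel["AO"])
    summary["config_hash"] = config_hash(config)
    summary["seed"] = config.seed

    pd.DataFrame(rows).to_csv(outdir / BEATS, index=False)
    pd.DataFrame(curve_rows).to_csv(outdir / CURVES, index=False)
    (outdir / SUMMARY).write_text(json.dumps(summary, indent=2))
    _stamp(config, "quantify", t0, outdir)
    return outdir / SUMMARY


def _phantom_rois(config: PipelineConfig):
    pcfg = config.phantom
    x, y = pcfg.grid()
    rois = []
    for v in pcfg.vessels:
        mask = (x - v.center[0]) ** 2 + (y - v.center[1]) ** 2 <= v.radius ** 2
        rois.append(fl.VesselROI(mask=mask, label=v.label,
                                 pixel_area=pcfg.pixel_mm ** 2))
    return rois


def report(config: PipelineConfig, outdir: str | Path) -> Path:
    """Agreement statistics of measured vs ground-truth per-beat values."""
    from .stats import agreement_report
    t0 = time.time()
    outdir = Path(outdir)
    measured = pd.read_csv(_need(outdir / BEATS, "quantify"))
    truth = pd.read_csv(_need(outdir / TRUTH_BEATS, "simulate"))
    out = {"config_hash": config_hash(config), "seed": config.seed}
    lines = [f"{'parameter':<22}{'vessel':<8}{'bias':>10}{'MAE':>10}"
             f"{'ICC':>8}{'CI95':>18}{'p':>9}"]
    for vessel in sorted(set(measured.vessel) & set(truth.vessel)):
        m = measured[measured.vessel == vessel].sort_values("beat")
        tr = truth[truth.vessel == vessel].sort_values("beat")
        n = min(len(m), len(tr))
        if n < 3:
            continue
        for col in ("net_flow_ml", "peak_flow_ml_s", "peak_vel_cm_s"):
            a = m[col].to_numpy()[:n]
            b = tr[col].to_numpy()[:n]
            try:
                r = agreement_report(a, b)
            except ValueError:
                continue
            out[f"{vessel}.{col}"] = r.__dict__
            lines.append(
                f"{col:<22}{vessel:<8}{r.bias:>10.2f}{r.mae:>10.2f}"
                f"{r.icc:>8.3f}{f'[{r.icc_ci_low:.2f},{r.icc_ci_high:.2f}]':>18}"
                f"{r.p_value:>9.4f}")
    (outdir / REPORT).write_text(json.dumps(out, indent=2, default=float))
    (outdir / "agreement.txt").write_text("\n".join(lines) + "\n")
    _stamp(config, "report", t0, outdir)
    return outdir / REPORT


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    simulate(config, outdir)
    reconstruct(config, outdir)
    quantify(config, outdir)
    return report(config, outdir)
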