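"""Pipeline configuration: YAML in/out, defaults, and config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomConfig, VesselSpec
from .recon import ReconParams
from .trajectory import GradientLimits, SpiralDesignSpec

__all__ = ["ProtocolConfig", "AnalysisConfig", "PipelineConfig",
           "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition protocol (real-time spiral defaults)."""

    fov_mm: float = 300.0
    res_mm: float = 2.3
    tr_ms: float = 11.0
    readout_ms: float = 5.32
    scan_time_s: float = 4.0
    center_fraction: float = 0.30
    center_density: float = 2.0
    outer_density: float = 0.6
    gmax_mT_m: float = 26.0
    smax_T_m_s: float = 45.0
    bandwidth_hz_px: float = 1116.0
    acquired_per_encoding: int = 2

    def spiral_spec(self) -> SpiralDesignSpec:
        return SpiralDesignSpec(
            fov=self.fov_mm, resolution=self.res_mm,
            readout_duration=self.readout_ms,
            center_fraction=self.center_fraction,
            center_density=self.center_density,
            outer_density=self.outer_density,
            bandwidth_per_pixel=self.bandwidth_hz_px,
            limits=GradientLimits(self.gmax_mT_m, self.smax_T_m_s))


@dataclass(frozen=True)
class AnalysisConfig:
    roi_source: str = "phantom"        # "phantom" | path to mask NIfTI
    velocity_percentile: float = 100.0
    use_true_triggers: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    recon: ReconParams = field(default_factory=ReconParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 1234
    outdir: str = "spiralpc_out"


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_dict(v) for v in obj]
    return obj


def _build(cls, data: dict):
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for key, val in data.items():
        if key not in hints:
            raise KeyError(f"unknown config key '{key}' for {cls.__name__}")
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path_or_dict) -> PipelineConfig:
    """Load a pipeline config from YAML (path) or a nested dict."""
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    phantom_d = dict(data.get("phantom", {}))
    vessels = phantom_d.pop("vessels", None)
    if vessels is not None:
        phantom_d["vessels"] = tuple(
            VesselSpec(**v) if isinstance(v, dict) else VesselSpec(*v)
            for v in vessels)
        phantom_d["vessels"] = tuple(
            dataclasses.replace(v, center=tuple(v.center))
            for v in phantom_d["vessels"])
    seed = int(data.get("seed", PipelineConfig.seed))
    phantom_d.setdefault("seed", seed)
    return PipelineConfig(
        protocol=_build(ProtocolConfig, data.get("protocol", {})),
        phantom=_build(PhantomConfig, phantom_d),
        recon=_build(ReconParams, data.get("recon", {})),
        analysis=_build(AnalysisConfig, data.get("analysis", {})),
        seed=seed,
        outdir=str(data.get("outdir", PipelineConfig.outdir)))


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))
    return path


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash identifying the configuration."""
    blob = json.dumps(_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
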