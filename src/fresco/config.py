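"""JSON configuration: defaults mirror the real-time scan protocol."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .phantom import PhantomConfig
from .recon_net import UNetSpec
from .stream import TimingModel
from .trajectory import AcquisitionParams, DensitySpec

__all__ = ["default_config", "load_config", "save_config", "RunConfig"]


@dataclasses.dataclass
class RunConfig:
    acquisition: AcquisitionParams
    density: DensitySpec
    phantom: PhantomConfig
    recon: UNetSpec
    seg: UNetSpec
    timing: TimingModel
    crop: int = 64
    window: int = 24
    step: int = 18
    n_samples_per_arm: int = 512


def default_config() -> RunConfig:
    return RunConfig(
        acquisition=AcquisitionParams(),
        density=DensitySpec(),
        phantom=PhantomConfig(),
        recon=UNetSpec(),
        seg=UNetSpec(n_scales=2, init_filters=8, blocks_per_scale=2, out_channels=1),
        timing=TimingModel(),
    )


def load_config(path) -> RunConfig:
    base = default_config()
    raw = json.loads(Path(path).read_text())
    out = {}
    for f in dataclasses.fields(RunConfig):
        cur = getattr(base, f.name)
        if f.name in raw:
            if dataclasses.is_dataclass(cur):
                merged = {**dataclasses.asdict(cur), **raw[f.name]}
                if "hr_ramp" in merged and isinstance(merged["hr_ramp"], list):
                    merged["hr_ramp"] = tuple(merged["hr_ramp"])
                if "vessel_center" in merged and isinstance(merged["vessel_center"], list):
                    merged["vessel_center"] = tuple(merged["vessel_center"])
                out[f.name] = type(cur)(**merged)
            else:
                out[f.name] = raw[f.name]
        else:
            out[f.name] = cur
    return RunConfig(**out)


def save_config(path, cfg: RunConfig):
    d = {
        f.name: (dataclasses.asdict(getattr(cfg, f.name)) if dataclasses.is_dataclass(getattr(cfg, f.name)) else getattr(cfg, f.name))
        for f in dataclasses.fields(RunConfig)
    }
    Path(path).write_text(json.dumps(d, indent=2))
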