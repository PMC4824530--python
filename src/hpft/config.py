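"""Flat-YAML run configuration shared by the CLI workflows."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import HpftConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_HPFT_KEYS = {
    "epsilon",
    "ratio",
    "ncc_accept",
    "min_patch_area",
    "max_iterations",
    "fb_threshold",
    "budget",
    "seed",
}
_RUN_KEYS = {"camera", "noise", "reps", "out_dir", "log_level", "stride"}


@dataclass
class RunConfig:
    hpft: HpftConfig = field(default_factory=HpftConfig)
    camera: str | None = None
    noise: tuple[float, ...] = (2.0, 5.0, 10.0)
    reps: int = 30
    out_dir: str = "."
    log_level: str = "INFO"
    stride: int = 3  # frame subsampling of dense video sequences

    def __post_init__(self):
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if any(s <= 0 for s in self.noise):
            raise ValueError("noise sigmas must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key-value YAML file, filling defaults for absent keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(data) - _HPFT_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(_HPFT_KEYS | _RUN_KEYS)}"
        )
    hpft_kwargs = {k: data[k] for k in _HPFT_KEYS if k in data}
    run_kwargs = {k: data[k] for k in _RUN_KEYS if k in data}
    if "noise" in run_kwargs:
        v = run_kwargs["noise"]
        if isinstance(v, str):
            v = [float(x) for x in v.split(",")]
        run_kwargs["noise"] = tuple(float(x) for x in v)
    return RunConfig(hpft=HpftConfig(**hpft_kwargs), **run_kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    flat = {**asdict(cfg.hpft)}
    flat.update(
        {
            "camera": cfg.camera,
            "noise": list(cfg.noise),
            "reps": cfg.reps,
            "out_dir": cfg.out_dir,
            "log_level": cfg.log_level,
            "stride": cfg.stride,
        }
    )
    flat = {k: v for k, v in flat.items() if v is not None}
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))
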