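"""Run configuration and result serialization.

A :class:`RunConfig` gathers everything a reproducible run needs: the
passive cell constraints, the coupling grid, channel settings, stimulus
and protocol parameters, and the master seed. Configs round-trip
losslessly through YAML or JSON; every field has a documented default, so
a minimal file only overrides what differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import PassiveCellSpec
from .protocols import KltSettings

__all__ = ["RunConfig", "load_config", "save_config", "write_results", "config_hash"]


@dataclass(frozen=True)
class GridBlock:
    step: float = 0.05
    lo: float = 0.1
    hi: float = 0.9


@dataclass(frozen=True)
class ChannelBlock:
    gna_mode: str = "ref"  # "ref" (multiples of gNa_ref) | "absolute" (nS)
    gna_value: float = 1.0
    klt_placement: str = "none"
    klt_fraction: float = 0.1
    klt_mode: str = "frozen"

    def __post_init__(self) -> None:
        if self.gna_mode not in ("ref", "absolute"):
            raise ValueError(f"invalid gna_mode {self.gna_mode!r}")
        KltSettings(self.klt_placement, self.klt_fraction, self.klt_mode)  # validate

    def klt(self) -> KltSettings:
        return KltSettings(self.klt_placement, self.klt_fraction, self.klt_mode)


@dataclass(frozen=True)
class StimulusBlock:
    freq: float = 500.0  # Hz, afferent tone frequency
    noncoincident_mode: str = "antiphase"  # or "delay_500us"
    epsg_scale: float = 1.0


@dataclass(frozen=True)
class ProtocolBlock:
    n_trials: int = 100
    duration: float = 250.0  # ms
    gna_sweep_lo: float = 0.2
    gna_sweep_hi: float = 2.2
    gna_sweep_step: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    cell: PassiveCellSpec = field(default_factory=PassiveCellSpec)
    grid: GridBlock = field(default_factory=GridBlock)
    channels: ChannelBlock = field(default_factory=ChannelBlock)
    stimulus: StimulusBlock = field(default_factory=StimulusBlock)
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    seed: int = 0
    output_dir: str = "results"


_BLOCKS = {
    "cell": PassiveCellSpec,
    "grid": GridBlock,
    "channels": ChannelBlock,
    "stimulus": StimulusBlock,
    "protocol": ProtocolBlock,
}


class ConfigError(ValueError):
    """Configuration schema error naming the offending key."""


def _build_block(cls, data: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{path}.{key}' (allowed: {sorted(allowed)})")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in block '{path}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config; missing keys take defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                raise ConfigError(f"block '{key}' must be a mapping")
            kwargs[key] = _build_block(_BLOCKS[key], value, key)
        elif key in ("seed", "output_dir"):
            kwargs[key] = value
        else:
            raise ConfigError(
                f"unknown key '{key}' (allowed: {sorted([*_BLOCKS, 'seed', 'output_dir'])})"
            )
    return RunConfig(**kwargs)


def _to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = _to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full (defaults-filled) configuration."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_results(
    table: pd.DataFrame, path: str | Path, cfg: RunConfig | None = None, seed: int | None = None
) -> None:
    """Write a tidy CSV with a JSON sidecar of run metadata.

    Column order is preserved as given; reruns of a deterministic (or
    identically seeded) protocol produce byte-identical files because no
    timestamps enter the output.
    """
    import twocpt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    meta = {
        "version": twocpt.__version__,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "seed": seed if seed is not None else (cfg.seed if cfg is not None else None),
        "columns": list(table.columns),
        "n_rows": int(len(table)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
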