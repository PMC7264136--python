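"""Run configuration: a flat, diffable key = value text format.

One file declares a full run — edge-detection parameters, blank-slice
trimming, counting connectivity and the statistics alpha — so analyses are
reproducible from the config alone.  Command-line flags override file
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .canny import EdgeParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    edge_params: EdgeParams = field(default_factory=EdgeParams)
    blank_threshold: float = 10.0
    min_fraction: float = 0.005
    connectivity: int = 8
    min_component_size: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.blank_threshold <= 255:
            raise ValueError("blank_threshold must be in [0, 255]")
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must be in (0, 1)")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")


_EDGE_FIELDS = {f.name: f.type for f in fields(EdgeParams)}
_RUN_FIELDS = {f.name for f in fields(RunConfig)} - {"edge_params"}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in ("denoise_method", "threshold_mode"):
        return raw
    if key in ("connectivity", "min_component_size"):
        return int(raw)
    return float(raw)


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` file; unknown keys are an error."""
    edge_kwargs = {}
    run_kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key in _EDGE_FIELDS:
            edge_kwargs[key] = _parse_value(key, raw)
        elif key in _RUN_FIELDS:
            run_kwargs[key] = _parse_value(key, raw)
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return RunConfig(edge_params=EdgeParams(**edge_kwargs), **run_kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = ["# marquant run configuration"]
    for f in fields(EdgeParams):
        lines.append(f"{f.name} = {getattr(config.edge_params, f.name)}")
    for name in sorted(_RUN_FIELDS):
        lines.append(f"{name} = {getattr(config, name)}")
    Path(path).write_text("\n".join(lines) + "\n")
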