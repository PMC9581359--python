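"""Run configuration: defaults, flat keyed config files, and hashing.

The config file is a flat keyed text file, one ``key: value`` per line with
dotted section prefixes (it is also valid YAML, which is what parses it)::

    width.phi: 0.95
    width.grid_m: 200
    simulate.n: 7
    seed: 42
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

_KEYMAP = {
    "io.units": "units",
    "width.phi": "phi",
    "width.regime": "regime",
    "width.grid_m": "grid_m",
    "width.quadrature_points": "quadrature_points",
    "width.center_mode": "center_mode",
    "difficulty.w_min": "w_min",
    "kinematics.phases": "phases",
    "simulate.n": "n_trials",
    "simulate.condition": "condition",
    "simulate.speed_model": "speed_model",
    "compare.alpha": "alpha",
    "seed": "seed",
}


@dataclass(frozen=True)
class RunConfig:
    units: str = "mm"
    phi: float = 0.95
    regime: str = "hotelling"
    grid_m: int = 200
    quadrature_points: int = 256
    center_mode: str = "centroid"
    w_min: float = 1e-6
    phases: tuple | None = None           # list of (a, b) u-intervals
    n_trials: int = 7
    condition: str = "tennis_ball"
    speed_model: str = "minjerk"
    alpha: float = 0.05
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """RunConfig from a flat keyed file; missing keys keep their defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected flat key/value pairs")
    updates = {}
    for key, value in raw.items():
        if key not in _KEYMAP:
            raise ValueError(f"{path}: unknown config key {key!r}")
        field = _KEYMAP[key]
        if field == "phases" and value is not None:
            value = tuple(tuple(float(x) for x in pair) for pair in value)
        updates[field] = value
    return replace(cfg, **updates)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    inverse = {v: k for k, v in _KEYMAP.items()}
    flat = {}
    for field, value in asdict(cfg).items():
        if value is None:
            continue
        if field == "phases":
            value = [list(p) for p in value]
        flat[inverse[field]] = value
    Path(path).write_text(yaml.safe_dump(flat, default_flow_style=None, sort_keys=True))
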