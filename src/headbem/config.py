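"""Structured run configuration for the command-line workflows.

Configs are YAML documents with a ``version`` tag; unknown keys are rejected
so that typos fail loudly.  All randomness derives from the single top-level
``seed``.  The same dictionary drives library calls, so a config file is a
complete, reproducible description of an experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]

CONFIG_VERSION = 1

_DEFAULTS = {
    "version": CONFIG_VERSION,
    "seed": 0,
    "output_dir": "headbem_out",
    "geometry": {
        "radii_mm": {"pial": 78.0, "inner_skull": 81.0, "outer_skull": 87.0, "scalp": 92.0},
        "mesh_levels": {"pial": 3, "inner_skull": 3, "outer_skull": 3, "scalp": 3},
        "perturbation": {"amplitude": 0.0, "seed": 0, "max_degree": 4},
    },
    "model": {"kind": "4C", "K": 50.0, "brain_scale": 1.0},
    "solver": {"method": "LC", "isa": True},
    "sources": {"n": 200, "radius_range_mm": [58.0, 76.5], "orientation": "random",
                "min_depth_mm": 1.5},
    "sensors": {"n_electrodes": 256, "n_magnetometers": 102,
                "helmet_radius_mm": None, "coil_side_mm": 21.0},
    "verify": {"mesh_levels": [2, 3], "methods": ["LC", "LG"],
               "modalities": ["EEG", "MEG"], "n_sources": 10,
               "tolerances": {}},
    "study": {"k_ref_grid": [20, 30, 40, 50, 60, 70, 80],
              "k_test_grid": [20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120,
                              130, 140, 150, 160, 170],
              "test_kind": "3S", "method": "LG", "ref_method": "LG",
              "modality": "EEG"},
}


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


def _merge(defaults, user, path=""):
    if not isinstance(user, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and key != "tolerances" and not (
                    key in ("radii_mm", "mesh_levels") and not isinstance(uval, dict)):
                out[key] = _merge(dval, uval, f"{path}.{key}" if path else key)
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys in {path or '<root>'}: {sorted(unknown)}")
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with a stable content hash for logging."""

    data: dict
    path: str | None = None

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.data["output_dir"])

    def config_hash(self) -> str:
        payload = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:  # noqa: BLE001
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    version = raw.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ConfigError(f"{path}: unsupported config version {version}")
    data = _merge(_DEFAULTS, raw)
    _validate(data)
    return RunConfig(data=data, path=str(path))


def _validate(data: dict):
    model = data["model"]
    if model["kind"] not in ("4C", "3S"):
        raise ConfigError(f"model.kind must be 4C or 3S, got {model['kind']!r}")
    if float(model["K"]) <= 0:
        raise ConfigError("model.K must be positive")
    if data["solver"]["method"] not in ("LC", "LG"):
        raise ConfigError("solver.method must be LC or LG")
    radii = data["geometry"]["radii_mm"]
    order = ["pial", "inner_skull", "outer_skull", "scalp"]
    rr = [float(radii[k]) for k in order]
    if any(b <= a for a, b in zip(rr, rr[1:])):
        raise ConfigError(f"geometry.radii_mm must increase along {order}, got {rr}")
    amp = float(data["geometry"]["perturbation"]["amplitude"])
    if not 0.0 <= amp < 0.3:
        raise ConfigError("perturbation amplitude must be in [0, 0.3)")
    lo, hi = (float(x) for x in data["sources"]["radius_range_mm"])
    if not 0 < lo <= hi:
        raise ConfigError("sources.radius_range_mm must be 0 < lo <= hi")
    if hi > rr[0] - float(data["sources"]["min_depth_mm"]):
        raise ConfigError("sources extend closer to the brain boundary than min_depth_mm")
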