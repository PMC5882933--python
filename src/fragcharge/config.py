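"""YAML configuration with schema validation and run manifests.

Every parameter the method leaves open (lambda threshold, fit shells and
penalty weight, PB grid spacings, SCRF tolerance) surfaces here with its
documented default, and the full snapshot lands in every run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

_SCHEMA = {
    "lambda_threshold": (float, 4.0),
    "backend": {
        "kind": (str, "mock", ("mock", "ab_initio")),
        "gain": (float, 0.0),
        "basis": (str, "6-31g*"),
    },
    "fit": {
        "shells": (list, [1.4, 1.6, 1.8, 2.0]),
        "density": (float, 1.0),
        "w_link": (float, 0.1),
        "resp_restraint": (float, 0.0),
    },
    "mep": {
        "r_min": (float, 2.5),
        "r_max": (float, 4.5),
        "spacing": (float, 0.8),
    },
    "pb": {
        "spacing": (float, 0.4),
        "padding": (float, 8.0),
        "eps_in": (float, 1.0),
        "eps_out": (float, 80.0),
        "probe": (float, 1.4),
        "kappa": (float, 0.0),
    },
    "scrf": {
        "tolerance": (float, 0.1),
        "max_iter": (int, 10),
        "damping": (float, 1.0),
    },
}


def _validate(data: dict, schema: dict, path: str = "") -> dict:
    out = {}
    for key, rule in schema.items():
        here = f"{path}.{key}" if path else key
        if isinstance(rule, dict):
            sub = data.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _validate(sub, rule, here)
            continue
        typ, default, *choices = rule
        value = data.get(key, default)
        if typ is float and isinstance(value, int):
            value = float(value)
        if typ is list:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"{here}: expected a list")
            value = [float(v) for v in value]
        elif not isinstance(value, typ):
            raise ConfigError(
                f"{here}: expected {typ.__name__}, got {type(value).__name__}")
        if choices and value not in choices[0]:
            raise ConfigError(f"{here}: must be one of {choices[0]}")
        out[key] = value
    unknown = set(data) - set(schema)
    if unknown:
        here = path or "<root>"
        raise ConfigError(f"{here}: unknown field(s) {sorted(unknown)}")
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Load + validate a YAML config; missing fields take defaults."""
    data = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("<root>: config must be a mapping")
        data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return _validate(data, _SCHEMA)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    input_hashes: dict[str, str] = field(default_factory=dict)
    inventory: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("timings", None)  # wall time is not reproducible
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
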