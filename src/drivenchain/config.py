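"""Run configuration, profiles and provenance manifests.

Configuration is a single YAML document. Three named profiles cover the usual
scales: ``smoke`` (seconds, shape checks), ``desk`` (minutes, the scaled-down
study every quantitative desk test uses) and ``paper`` (the full protocol:
1680 parameter draws, N = 200, 51×51 grid — hours on one CPU, embarrassingly
parallel across rows). Any field can be overridden in the YAML.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import yaml

__all__ = ["PROFILES", "resolve_config", "load_config", "RunManifest", "file_sha256"]

try:
    _VERSION = version("drivenchain")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


# q_max = q_max_factor * pi / L with q_max_factor = grid_n - 1, which keeps the
# grid spacing at exactly 2*pi/L (the protocol grid's resolution) at every scale
PROFILES: dict[str, dict] = {
    "smoke": {
        "n_samples": 20,
        "n_bonds": 20,
        "grid_n": 11,
        "q_max_factor": 10.0,
        "schedule": {
            "n_equilibration_sweeps": 200,
            "n_sample_sweeps": 200,
            "sample_interval": 10,
            "max_rotation_angle": float(np.pi / 2),
        },
        "train_fraction": 0.7,
        "n_restarts": 2,
    },
    "desk": {
        "n_samples": 240,
        "n_bonds": 50,
        "grid_n": 21,
        "q_max_factor": 20.0,
        "schedule": {
            "n_equilibration_sweeps": 2000,
            "n_sample_sweeps": 8000,
            "sample_interval": 40,
            "max_rotation_angle": float(np.pi / 2),
        },
        "train_fraction": 0.7,
        "n_restarts": 5,
    },
    "paper": {
        "n_samples": 1680,
        "n_bonds": 200,
        "grid_n": 51,
        "q_max_factor": 50.0,
        "schedule": {
            "n_equilibration_sweeps": 20_000,
            "n_sample_sweeps": 10_000,
            "sample_interval": 100,
            "max_rotation_angle": float(np.pi / 2),
        },
        "train_fraction": 0.7,
        "n_restarts": 5,
    },
}

_COMMON_DEFAULTS = {
    "bond_length": 1.0,
    "self_avoiding": True,
    "norm_exponent": 2,
    "noise_level": None,
    "seed": 0,
    "split_seed": 11,
    "n_jobs": 1,
    "targets": "all",
}


def resolve_config(overrides: dict | None = None, profile: str | None = None) -> dict:
    """Merge profile defaults, common defaults and user overrides; validate.

    All schema violations are collected and reported at once.
    """
    overrides = dict(overrides or {})
    profile = profile or overrides.pop("profile", "desk")
    errors = []
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    cfg = {**_COMMON_DEFAULTS, **json.loads(json.dumps(PROFILES[profile]))}
    cfg["profile"] = profile
    sched_over = overrides.pop("schedule", {})
    if not isinstance(sched_over, dict):
        errors.append("schedule must be a mapping")
        sched_over = {}
    unknown = set(overrides) - set(cfg)
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg.update({k: v for k, v in overrides.items() if k in cfg})
    unknown_s = set(sched_over) - set(cfg["schedule"])
    if unknown_s:
        errors.append(f"unknown schedule keys: {sorted(unknown_s)}")
    cfg["schedule"].update({k: v for k, v in sched_over.items() if k in cfg["schedule"]})

    if not isinstance(cfg["n_samples"], int) or cfg["n_samples"] < 1:
        errors.append("n_samples must be a positive integer")
    if not isinstance(cfg["n_bonds"], int) or cfg["n_bonds"] < 3:
        errors.append("n_bonds must be an integer >= 3")
    if cfg["grid_n"] % 2 == 0 or cfg["grid_n"] < 1:
        errors.append("grid_n must be odd and positive")
    if not 0 < cfg["train_fraction"] < 1:
        errors.append("train_fraction must lie in (0, 1)")
    for key in ("n_equilibration_sweeps", "n_sample_sweeps", "sample_interval"):
        if cfg["schedule"].get(key, 0) < 1:
            errors.append(f"schedule.{key} must be >= 1")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def load_config(path) -> dict:
    """Read a YAML config file and resolve it against its profile."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return resolve_config(raw)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline artifact."""

    config: dict
    seeds: dict
    stage: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    tool_version: str = _VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def record_file(self, role: str, path, output: bool = True) -> None:
        entry = {"path": str(path), "sha256": file_sha256(path)}
        (self.outputs if output else self.inputs)[role] = entry

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
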