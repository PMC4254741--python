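"""Run configuration: YAML-backed, strictly validated, hashable.

Every paper-anchored default is overridable from the config file; unknown
keys are rejected with a message naming them, and values are validated by
the underlying dataclasses.  All randomness in a run flows from the single
top-level ``seed``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .automation_controller import (ControllerConfig, StepDurationModel)
from .axon_targeter import ControlConfig
from .errors import ConfigError
from .neuron_verifier import VerifierConfig
from .soma_finder import SomaDetectionConfig
from .virtual_rig.optics import OpticsConfig
from .virtual_rig.phantom import PhantomParams
from .virtual_rig.render import NoiseConfig
from .worm_locator import LocatorConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

# Config sections and the dataclass each one populates.
_SECTIONS = {
    "optics": OpticsConfig,
    "noise": NoiseConfig,
    "phantom": PhantomParams,
    "locator": LocatorConfig,
    "soma": SomaDetectionConfig,
    "verifier": VerifierConfig,
    "control": ControlConfig,
}
_TOP_LEVEL = {"seed", "n_worms", "imaging", "rejection_fractions",
              "laser_focus_offset_z", "pulses", "pulse_energy_nj",
              "out_dir"} | set(_SECTIONS)

# Fields that are tuples in the dataclasses but lists in YAML.
_TUPLE_FIELDS = {"rejection_fractions", "body_length_range",
                 "body_half_width_range", "soma_depth_range",
                 "soma_radius_range", "diameter_gate_um"}


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a simulation/automation run."""

    seed: int = 0
    n_worms: int = 350
    out_dir: str = "axobot_out"
    controller: ControllerConfig = field(default_factory=ControllerConfig)

    def to_dict(self) -> dict:
        ctrl = self.controller
        out = {
            "seed": self.seed,
            "n_worms": self.n_worms,
            "out_dir": self.out_dir,
            "imaging": ctrl.imaging,
            "rejection_fractions": list(ctrl.rejection_fractions),
            "laser_focus_offset_z": ctrl.laser_focus_offset_z,
            "pulses": ctrl.pulses,
            "pulse_energy_nj": ctrl.pulse_energy_nj,
        }
        attr = {"optics": "optics", "noise": "noise", "phantom": "phantom",
                "locator": "locator", "soma": "soma", "verifier": "verifier",
                "control": "control"}
        for section, name in attr.items():
            sub = dataclasses.asdict(getattr(ctrl, name))
            sub.pop("magnifications", None)   # objective set is fixed
            out[section] = sub
        return _jsonable(out)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls) if f.init}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{section}': {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**{**_defaults(cls), **kwargs})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def _defaults(cls) -> dict:
    """Default kwargs of a dataclass (so partial sections are allowed)."""
    out = {}
    for f in fields(cls):
        if not f.init:
            continue
        if f.default is not dataclasses.MISSING:
            out[f.name] = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            out[f.name] = f.default_factory()               # type: ignore[misc]
    return out


def from_dict(data: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain dictionary."""
    unknown = set(data) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown top-level keys: {', '.join(sorted(unknown))}")

    sections = {}
    for section, cls in _SECTIONS.items():
        sections[section] = _build_section(cls, data.get(section, {}) or {}, section)

    ctrl_kwargs = dict(
        imaging=data.get("imaging", "fast"),
        rejection_fractions=tuple(data.get("rejection_fractions",
                                           ControllerConfig().rejection_fractions)),
        optics=sections["optics"],
        noise=sections["noise"],
        phantom=sections["phantom"],
        locator=sections["locator"],
        soma=sections["soma"],
        verifier=sections["verifier"],
        control=sections["control"],
        durations=StepDurationModel(),
        laser_focus_offset_z=data.get("laser_focus_offset_z", 0.7),
        pulses=int(data.get("pulses", 300)),
        pulse_energy_nj=float(data.get("pulse_energy_nj", 4.0)),
    )
    try:
        controller = ControllerConfig(**ctrl_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        seed=int(data.get("seed", 0)),
        n_worms=int(data.get("n_worms", 350)),
        out_dir=str(data.get("out_dir", "axobot_out")),
        controller=controller,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration (for output provenance)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
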