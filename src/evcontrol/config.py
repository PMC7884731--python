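"""Run configuration: one structured document for the whole pipeline.

A :class:`RunConfig` bundles the study design, the EVC parameters, the
generator effect/noise blocks, the pupil impulse-response parameters and the
run options.  It round-trips to YAML (the CLI's ``--config``) and hashes
canonically so every output manifest can record exactly which configuration
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .behavior import BehaviorParams
from .design import DesignConfig, study_design
from .eeg_sim import ErpEffects
from .evc import EvcParams
from .pupil import IrfParams
from .pupil_sim import PupilSimParams

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    design: DesignConfig = field(default_factory=lambda: study_design(2))
    evc: EvcParams = field(default_factory=EvcParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    erp: ErpEffects = field(default_factory=ErpEffects)
    pupil: PupilSimParams = field(default_factory=PupilSimParams)
    irf: IrfParams = field(default_factory=IrfParams)
    seed: int = 0
    render_eeg: bool = False  # waveform rendering (heavier than amplitudes)
    noise_rms: float = 8.0
    artifact_fraction: float = 0.05

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "design": DesignConfig,
    "evc": EvcParams,
    "behavior": BehaviorParams,
    "erp": ErpEffects,
    "pupil": PupilSimParams,
    "irf": IrfParams,
}


def _coerce(cls, value):
    if isinstance(value, cls):
        return value
    value = dict(value)
    # YAML lists come back as lists; frozen dataclasses here expect tuples
    for k, v in value.items():
        if isinstance(v, list):
            value[k] = tuple(v)
    return cls(**value)


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path, a mapping, or pass one through."""
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    source = dict(source)
    if "study" in source:  # shorthand: pick a study's design defaults
        study = source.pop("study")
        source.setdefault("design", {})
        base = dataclasses.asdict(study_design(study))
        base.update(source["design"] if isinstance(source["design"], dict) else {})
        source["design"] = base
    kwargs = {}
    for key, val in source.items():
        if key in _BLOCKS:
            kwargs[key] = _coerce(_BLOCKS[key], val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
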