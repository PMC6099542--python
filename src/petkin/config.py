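"""Run configuration: YAML/JSON parsing into typed dataclasses."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .metabolism import BRAIN_CALIBRATION_POINTS, PLASMA_CALIBRATION_POINTS
from .synthetic import AifParams, GeneratorConfig, GroupKinetics

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Options for one end-to-end pipeline run.

    Either ``tac_path``/``plasma_path`` point at measured tables, or
    ``generator`` describes a synthetic cohort (the default).
    """

    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    tac_path: str | None = None
    plasma_path: str | None = None
    truth_path: str | None = None            # group labels for file-based cohorts
    pf_plasma_points: tuple = PLASMA_CALIBRATION_POINTS
    pf_brain_points: tuple = BRAIN_CALIBRATION_POINTS
    weights: str = "duration"
    vB: float = 0.05
    exclusion_threshold: float = 50.0
    kinetic_sides: str = "one"               # Welch sides for kinetic parameters
    seed: int = 0

    def __post_init__(self):
        if self.exclusion_threshold <= 0:
            raise ValidationError("exclusion threshold must be positive")
        if self.generator is None and not (self.tac_path and self.plasma_path):
            raise ValidationError("either a generator config or tac/plasma paths are required")
        if self.kinetic_sides not in ("one", "two"):
            raise ValidationError("kinetic_sides must be 'one' or 'two'")


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("run config must be a mapping")
    gen = data.get("generator", {})
    if gen is not None:
        gen = dict(gen)
        for key in ("control", "lps"):
            if key in gen:
                gen[key] = GroupKinetics(**{k: tuple(v) for k, v in gen[key].items()})
        if "aif" in gen:
            gen["aif"] = _build(AifParams, gen["aif"])
        if "sample_times" in gen:
            gen["sample_times"] = tuple(gen["sample_times"])
        data["generator"] = _build(GeneratorConfig, gen)
    for key in ("pf_plasma_points", "pf_brain_points"):
        if key in data:
            data[key] = tuple((float(t), float(f)) for t, f in data[key])
    return _build(RunConfig, data)
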