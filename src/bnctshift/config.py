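"""YAML configuration for the study pipeline.

A single structured text file drives phantom construction, the beam,
weighting constants, the prescription and the perturbation battery.  Keys
mirror the dataclass fields; unspecified keys keep the package defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .beam import BeamConfig
from .dose import WeightingConfig
from .plan import Prescription
from .study import StudyConfig

__all__ = ["load_study_config", "dump_study_config"]


def load_study_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "beam" in raw:
        beam = dict(raw.pop("beam"))
        if "beam_axis_position" in beam:
            beam["beam_axis_position"] = tuple(beam["beam_axis_position"])
        kwargs["beam"] = BeamConfig(**beam)
    if "weighting" in raw:
        kwargs["weighting"] = WeightingConfig(**raw.pop("weighting"))
    if "prescription" in raw:
        kwargs["prescription"] = Prescription(**raw.pop("prescription"))
    for key in ("families", "depths", "shift_magnitudes", "angles"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    kwargs.update(raw)
    return StudyConfig(**kwargs)


def dump_study_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
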