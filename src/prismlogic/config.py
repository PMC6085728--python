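"""Run configuration: a single YAML file plus dotted-key overrides.

Sections (all optional, every field defaulting to the published design):

.. code-block:: yaml

    architecture:
      side_bp: 21
      toehold_nt: 6
    signal:
      r_closed: 5.5
      threshold: 0.6
    engine:
      min_toehold: 2
      excess: 5
    sequence:
      max_unintended_stretch: 5
      gc_min: 0.40
      gc_max: 0.60
    seed: 1

Command-line overrides use dotted keys, e.g. ``signal.threshold=0.55``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import yaml

from .errors import InputError
from .geometry_signal import GeometryParams, SignalModel
from .strand_model import ArchitectureSpec, SequenceConstraints

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    signal: SignalModel = field(default_factory=SignalModel)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    sequence: SequenceConstraints = field(default_factory=SequenceConstraints)
    min_toehold: int = 2
    excess: int = 5
    seed: int = 1

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logging."""
        payload = {
            "architecture": dataclasses.asdict(self.architecture),
            "signal": dataclasses.asdict(self.signal),
            "geometry": dataclasses.asdict(self.geometry),
            "sequence": dataclasses.asdict(self.sequence),
            "engine": {"min_toehold": self.min_toehold, "excess": self.excess},
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def _apply_overrides(data: Dict, overrides: Sequence[str]) -> Dict:
    for item in overrides:
        if "=" not in item:
            raise InputError(f"override {item!r} must look like section.key=value")
        key, value = item.split("=", 1)
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = _coerce(value)
    return data


_SECTION_TYPES = {
    "architecture": ArchitectureSpec,
    "signal": SignalModel,
    "geometry": GeometryParams,
    "sequence": SequenceConstraints,
}


def load_config(path: Optional[str] = None, overrides: Sequence[str] = ()) -> RunConfig:
    """Load a config file (if given) and apply dotted-key overrides.

    Every section field is validated against the module invariants at
    construction time, before any run starts.
    """
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data = _apply_overrides(data, overrides)
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        section_data = data.get(section, {})
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section_data) - valid
        if unknown:
            raise InputError(f"unknown {section} fields: {sorted(unknown)}")
        kwargs[section] = cls(**section_data)
    engine = data.get("engine", {})
    return RunConfig(
        architecture=kwargs["architecture"],
        signal=kwargs["signal"],
        geometry=kwargs["geometry"],
        sequence=kwargs["sequence"],
        min_toehold=int(engine.get("min_toehold", 2)),
        excess=int(engine.get("excess", 5)),
        seed=int(data.get("seed", 1)),
    )
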