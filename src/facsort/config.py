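"""YAML run configuration.

One file with sections ``gating``, ``instrument``, ``protocol``, ``timing``
and ``paths`` plus a global ``seed``; every field of GateConfig,
InstrumentModel, SortPlan and SessionTiming is exposed under its own name.
Missing sections or fields fall back to package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError
from .gate_builder import GateConfig
from .sort_session import InstrumentModel, SessionTiming, SortPlan


@dataclass
class RunConfig:
    gating: GateConfig = field(default_factory=GateConfig)
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    protocol: SortPlan = field(default_factory=SortPlan)
    timing: SessionTiming = field(default_factory=SessionTiming)
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0


_SECTIONS = {
    "gating": GateConfig,
    "instrument": InstrumentModel,
    "protocol": SortPlan,
    "timing": SessionTiming,
}


def _build(cls, section: dict[str, Any], name: str):
    allowed = {f.name for f in fields(cls)} - {"gate"}
    unknown = set(section) - allowed
    if unknown:
        raise ValidationError(f"config section {name!r}: unknown key(s) {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` gives pure defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValidationError(f"{path}: section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, name)
    kwargs["paths"] = raw.get("paths", {}) or {}
    kwargs["seed"] = int(raw.get("seed", 0))
    return RunConfig(**kwargs)
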