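"""YAML/JSON configuration overrides for missions and waste streams.

A config file may override any mission parameter (crew, phase durations)
or waste-stream rate, e.g.::

    missions:
      mars: {crew: 4, residence_days: 300}
    waste_streams:
      carbon_dioxide: {rate: 1.1}
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import yaml

from .mission_resources import (
    MARS_MISSION,
    MOON_MISSION,
    MissionProfile,
    WasteStream,
    load_waste_streams,
)

__all__ = ["load_config", "apply_overrides"]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def apply_overrides(config: dict) -> tuple[dict[str, MissionProfile],
                                           dict[str, WasteStream]]:
    """Default missions and streams with config overrides applied."""
    missions = {"mars": MARS_MISSION, "moon": MOON_MISSION}
    for name, overrides in (config.get("missions") or {}).items():
        base = missions.get(name) or MissionProfile(name, 1, 0, 0, 0)
        missions[name] = replace(base, **overrides)
    streams = load_waste_streams()
    for name, overrides in (config.get("waste_streams") or {}).items():
        base = streams[name]
        if "rate" in overrides and "component_rates" not in overrides:
            # rescale tracked components with the total to keep fractions
            scale = overrides["rate"] / base.rate
            overrides = {
                **overrides,
                "component_rates": {k: v * scale
                                    for k, v in base.component_rates.items()},
            }
        streams[name] = replace(base, **overrides)
    return missions, streams
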