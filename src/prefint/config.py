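"""Declarative YAML configuration: radii overrides, species map, cutoffs,
seeds, and synthetic scenario specs."""

from __future__ import annotations

from pathlib import Path

import yaml

from prefint.model_io import SpeciesMap
from prefint.synthetic import Dewetting, Patch, ScenarioSpec


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration root must be a mapping")
    return cfg


def species_map_from_config(cfg: dict) -> SpeciesMap:
    return SpeciesMap.from_config(cfg.get("species", {}))


def radii_overrides_from_config(cfg: dict) -> dict[str, float]:
    return {str(k): float(v) for k, v in (cfg.get("radii") or {}).items()}


def scenario_from_config(cfg: dict) -> ScenarioSpec:
    """Build a ScenarioSpec from the ``scenario`` section of a config."""
    sc = dict(cfg.get("scenario", cfg))
    if "dewetting" in sc and sc["dewetting"] is not None:
        sc["dewetting"] = Dewetting(**sc["dewetting"])
    if "patch" in sc and sc["patch"] is not None:
        sc["patch"] = Patch(**sc["patch"])
    if "box" in sc:
        sc["box"] = tuple(sc["box"])
    return ScenarioSpec(**sc)
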