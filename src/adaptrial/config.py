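"""YAML serialization of scenario and design configurations."""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

from .cohort import ScenarioSpec
from .endpoints import VisitSchedule
from .engine import DesignConfig

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "load_design",
    "save_design",
]


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["biomarker_prevalences"] = dict(spec.biomarker_prevalences)
    d["ctdna_band_probs"] = list(spec.ctdna_band_probs)
    # (arm, signature) tuple keys become "arm:signature" strings in YAML.
    d["true_log_str"] = {
        f"{arm}:{sig}": float(v) for (arm, sig), v in spec.true_log_str.items()
    }
    d["visit_schedule"] = dataclasses.asdict(spec.visit_schedule)
    return d


def scenario_from_dict(d: dict) -> ScenarioSpec:
    d = dict(d)
    if "true_log_str" in d:
        effects = {}
        for key, v in d["true_log_str"].items():
            arm, sig = key.split(":")
            effects[(arm, sig)] = float(v)
        d["true_log_str"] = effects
    if "true_str" in d:  # convenience: ratios instead of log ratios
        effects = d.setdefault("true_log_str", {})
        for key, v in d.pop("true_str").items():
            arm, sig = key.split(":")
            effects[(arm, sig)] = math.log(float(v))
    if "ctdna_band_probs" in d:
        d["ctdna_band_probs"] = tuple(d["ctdna_band_probs"])
    if "visit_schedule" in d and isinstance(d["visit_schedule"], dict):
        d["visit_schedule"] = VisitSchedule(**d["visit_schedule"])
    return ScenarioSpec(**d)


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path, encoding="utf-8") as fh:
        return scenario_from_dict(yaml.safe_load(fh) or {})


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(spec), fh, sort_keys=False)


def load_design(path: str | Path) -> DesignConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    if "experimental_arms" in d:
        d["experimental_arms"] = tuple(d["experimental_arms"])
    return DesignConfig(**d)


def save_design(config: DesignConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["experimental_arms"] = list(config.experimental_arms)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
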