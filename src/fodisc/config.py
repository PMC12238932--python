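"""Run configuration: one document that pins every simulation choice.

A persisted RunConfig (YAML or JSON) plus a master seed fully determines
every output byte except timestamps.  Unknown keys are rejected rather
than ignored, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from fodisc import __version__
from fodisc.cohort import CellSpec, CATCH_ACCURACY_TARGETS, default_cells
from fodisc.staircase import StaircaseConfig
from fodisc.stimuli import DEFAULT_SAMPLE_RATE


@dataclass(frozen=True)
class AudioConfig:
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE
    export: bool = True


@dataclass(frozen=True)
class RunConfig:
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    cells: tuple[CellSpec, ...] = field(
        default_factory=lambda: tuple(default_cells())
    )
    lapse_rate: float = 0.02
    catch_accuracy_targets: dict = field(
        default_factory=lambda: dict(CATCH_ACCURACY_TARGETS)
    )
    audio: AudioConfig = field(default_factory=AudioConfig)

    def to_dict(self) -> dict:
        return {
            "staircase": asdict(self.staircase),
            "cells": [asdict(c) for c in self.cells],
            "lapse_rate": self.lapse_rate,
            "catch_accuracy_targets": dict(self.catch_accuracy_targets),
            "audio": asdict(self.audio),
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build(cls, payload: dict, context: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**payload)


def config_from_dict(payload: dict) -> RunConfig:
    payload = dict(payload)
    known = {"staircase", "cells", "lapse_rate", "catch_accuracy_targets",
             "audio"}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    if "staircase" in payload:
        kwargs["staircase"] = _build(StaircaseConfig, payload["staircase"],
                                     "staircase")
    if "cells" in payload:
        kwargs["cells"] = tuple(_build(CellSpec, c, "cell")
                                for c in payload["cells"])
    if "audio" in payload:
        kwargs["audio"] = _build(AudioConfig, payload["audio"], "audio")
    for key in ("lapse_rate", "catch_accuracy_targets"):
        if key in payload:
            kwargs[key] = payload[key]
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; None gives the defaults."""
    if path is None:
        return RunConfig()
    payload = yaml.safe_load(Path(path).read_text())
    if payload is None:
        return RunConfig()
    if not isinstance(payload, dict):
        raise ValueError("configuration document must be a mapping")
    return config_from_dict(payload)


def provenance(config: RunConfig, seed: int | None) -> dict:
    """Machine-readable provenance block written next to every output."""
    return {
        "artifact": "fodisc",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": seed,
    }
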