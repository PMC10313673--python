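"""YAML run configuration for the CLI and scripted experiments.

A run config mirrors :class:`~mosqid.trainer.TrainConfig` (with the miner
under the ``miner:`` key) plus an optional ``model:`` section mirroring
:class:`~mosqid.embednet.BackboneConfig` and a ``synthetic:`` section for
the generator.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .embednet import BackboneConfig
from .mining import MinerConfig
from .synth import SourceProfile, SyntheticSpec, default_class_generators, demo_spec
from .trainer import TrainConfig

__all__ = ["load_run_config", "train_config_from_dict", "backbone_config_from_dict",
           "synthetic_spec_from_dict"]


def train_config_from_dict(d: dict) -> TrainConfig:
    d = dict(d or {})
    miner = d.pop("miner", None)
    known = {f.name for f in fields(TrainConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown training config keys: {sorted(unknown)}")
    cfg = TrainConfig(**d)
    if miner is not None:
        cfg.miner = MinerConfig.from_dict(miner)
    return cfg


def backbone_config_from_dict(d: dict) -> BackboneConfig:
    d = dict(d or {})
    if "input_resolution" in d:
        d["input_resolution"] = tuple(d["input_resolution"])
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return BackboneConfig(**d)


def synthetic_spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d or {})
    if not d:
        return demo_spec()
    if "sources" in d:
        d["sources"] = [SourceProfile(**{**s, "background": tuple(s["background"])})
                        for s in d["sources"]]
    if "image_size" in d:
        d["image_size"] = tuple(d["image_size"])
    if "n_classes" in d and "class_generators" not in d:
        d["class_generators"] = default_class_generators(
            d["n_classes"], d.get("seed", 0))
    if "per_class" in d:  # shorthand for balanced classes
        per = d.pop("per_class")
        d["per_class_counts"] = [per] * d["n_classes"]
    return SyntheticSpec(**d)


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run config into typed sections.

    Returns a dict with keys ``train`` (TrainConfig), ``model``
    (BackboneConfig) and ``synthetic`` (SyntheticSpec or None).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "train": train_config_from_dict(raw.get("train", {})),
        "model": backbone_config_from_dict(raw.get("model", {})),
        "synthetic": (synthetic_spec_from_dict(raw["synthetic"])
                      if "synthetic" in raw else None),
    }
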