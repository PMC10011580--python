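"""Run configuration: one YAML document wiring every stage.

A run is reproducible from its persisted RunConfig alone: the global seed
feeds named substreams (phantom, folds, training, dropout) via
``numpy.random.SeedSequence``.  Every constant of the method — the gamma
ramp 0.02-0.15, the foreground weight cap 100, the 0.5 decision threshold,
the 3-voxel lesion floor, the 10% detection overlap, 18-connectivity, 20%
patch overlap, 32x96x96 patches, 3 folds, 30 epochs, lr 1e-4, batch 10 and
10 MC repeats — is a config default, not a hard-coded literal at the call
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .losses import LossConfig
from .network import NetworkConfig
from .phantom import CohortParams, PhantomParams
from .preprocess import AugmentParams
from .training import TrainConfig
from .volume_io import VolumeGrid

__all__ = ["RunConfig", "EvalConfig", "substream", "load_config",
           "save_config"]


@dataclass
class EvalConfig:
    min_lesion_voxels: int = 3
    detection_overlap: float = 0.1
    connectivity: int = 18
    threshold: float = 0.5
    n_mc: int = 10
    n_folds: int = 3
    patch_shape: tuple[int, int, int] = (32, 96, 96)
    overlap_fraction: float = 0.2


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    n_subjects: int = 20
    phantom: PhantomParams = field(default_factory=PhantomParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the global seed."""
    tag = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((seed, tag)))


def _to_plain(obj):
    if isinstance(obj, VolumeGrid):
        return {"shape": list(obj.shape), "spacing_mm": list(obj.spacing_mm)}
    if isinstance(obj, NetworkConfig):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_dir = raw.get("out_dir", cfg.out_dir)
    cfg.n_subjects = int(raw.get("n_subjects", cfg.n_subjects))
    if "phantom" in raw:
        d = dict(raw["phantom"])
        if "grid" in d:
            g = d["grid"]
            d["grid"] = VolumeGrid(tuple(g["shape"]),
                                   tuple(g.get("spacing_mm", (3, 1, 1))))
        cfg.phantom = PhantomParams(**d)
    if "cohort" in raw:
        d = dict(raw["cohort"])
        if "visit_weeks" in d:
            d["visit_weeks"] = tuple(d["visit_weeks"])
        cfg.cohort = CohortParams(**d)
    if "train" in raw:
        d = dict(raw["train"])
        if "loss" in d:
            d["loss"] = LossConfig(**d["loss"])
        if "network" in d:
            d["network"] = NetworkConfig.from_dict(d["network"])
        if "augment_params" in d and d["augment_params"] is not None:
            ap = dict(d["augment_params"])
            if "scale_range" in ap:
                ap["scale_range"] = tuple(ap["scale_range"])
            d["augment_params"] = AugmentParams(**ap)
        cfg.train = TrainConfig(**d)
    if "eval" in raw:
        d = dict(raw["eval"])
        if "patch_shape" in d:
            d["patch_shape"] = tuple(d["patch_shape"])
        cfg.eval = EvalConfig(**d)
    return cfg
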