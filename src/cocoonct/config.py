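"""Run configuration: one serializable object for the whole pipeline.

A RunConfig nests the per-stage configurations (phantom, clip window,
augmentation, model, training, postprocessing) plus the master seed and the
output root.  It round-trips losslessly through JSON or YAML, and its hash
is stamped into every artifact's provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from .phantom import PhantomSpec
from .postprocess import PostprocessConfig
from .preprocessing import AugmentationParams, ClipWindow
from .segmentation import ModelSpec, TrainConfig


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    clip_window: ClipWindow = field(default_factory=ClipWindow)
    augmentation: AugmentationParams | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    seed: int = 0
    n_volumes: int = 4
    n_val: int = 1
    count_range: tuple[int, int] | None = None
    output_root: str = "runs"
    log_level: str = "INFO"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom"] = PhantomSpec(**_retuple(d.get("phantom", {})))
        d["clip_window"] = ClipWindow(**d.get("clip_window", {}))
        aug = d.get("augmentation")
        d["augmentation"] = AugmentationParams(**_retuple(aug)) if aug else None
        d["model"] = ModelSpec(**_retuple(d.get("model", {})))
        tr = dict(d.get("training", {}))
        if "clip_window" in tr and isinstance(tr["clip_window"], dict):
            tr["clip_window"] = ClipWindow(**tr["clip_window"])
        if tr.get("augmentation"):
            tr["augmentation"] = AugmentationParams(**_retuple(tr["augmentation"]))
        d["training"] = TrainConfig(**tr)
        d["postprocess"] = PostprocessConfig(**d.get("postprocess", {}))
        if d.get("count_range") is not None:
            d["count_range"] = tuple(d["count_range"])
        return cls(**d)

    def save(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        d = self.to_dict()
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(d, fh, sort_keys=True)
            else:
                json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        path = os.fspath(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(d)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


_TUPLE_FIELDS = {"volume_shape", "voxel_spacing", "semi_axis_range", "larvae_range",
                 "zoom_range", "noise_sd_range", "smoothing_sigma_range",
                 "filters_per_depth"}


def _retuple(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def provenance_sidecar(path: str | os.PathLike, config: RunConfig, stage: str) -> None:
    """Write a provenance record (config hash, seed, stage) beside an artifact."""
    with open(os.fspath(path), "w") as fh:
        json.dump({"config_hash": config.hash(), "seed": config.seed, "stage": stage},
                  fh, indent=1, sort_keys=True)
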