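"""Run configuration: a single nested YAML file with schema validation.

Every tunable of the pipeline has a default here, so a run is fully
reproducible from the config file plus a seed. Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cells import CellSegConfig
from .quantify import BlobCountConfig
from .segmentation import SegmentationConfig
from .synthetic import SceneSpec, control_spec, knockdown_spec

__all__ = ["ExperimentConfig", "load_config", "config_hash", "config_to_dict"]


@dataclass(frozen=True)
class ExperimentConfig:
    """End-to-end experiment: simulate two groups, segment, quantify, compare."""

    scene_control: SceneSpec = field(default_factory=control_spec)
    scene_test: SceneSpec = field(default_factory=knockdown_spec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cell_segmentation: CellSegConfig = field(default_factory=CellSegConfig)
    blob_counting: BlobCountConfig = field(default_factory=BlobCountConfig)
    n_scenes_per_group: int = 10
    metrics: tuple[str, ...] = ("fc_count", "mean_fc_area_um2", "total_fc_area_um2")
    oracle_mode: bool = False
    t_variant: str = "student"
    n_boot: int = 0
    profile_bins: int = 20
    rng_seed: int = 0


_SECTION_TYPES = {
    "scene_control": SceneSpec,
    "scene_test": SceneSpec,
    "segmentation": SegmentationConfig,
    "cell_segmentation": CellSegConfig,
    "blob_counting": BlobCountConfig,
}

_TUPLE_FIELDS = {
    "image_size", "fa_count_law", "fa_area_law_um2", "fa_elongation_law",
    "gradient_slopes", "fiber_base_intensity", "metrics", "sigma_span",
}


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown key {context}.{key}")
        if key in _SECTION_TYPES and isinstance(value, dict):
            value = _build(_SECTION_TYPES[key], value, f"{context}.{key}")
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from YAML, applying defaults for
    everything the file omits."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    cfg = _build(ExperimentConfig, data, "config")
    cfg.scene_control.validate()
    cfg.scene_test.validate()
    cfg.segmentation.validate()
    if cfg.n_scenes_per_group < 2:
        raise ValueError("n_scenes_per_group must be >= 2")
    return cfg


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def detuple(x):
        if isinstance(x, tuple):
            return [detuple(v) for v in x]
        if isinstance(x, dict):
            return {k: detuple(v) for k, v in x.items()}
        return x

    return detuple(d)


def config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
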