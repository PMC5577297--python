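"""End-to-end orchestration: simulate -> segment -> cells -> quantify ->
profile -> compare, with a run manifest for reproducibility.

Oracle mode bypasses segmentation and quantifies the generator's ground
truth directly; it isolates the statistical stage from segmentation error
and is used as a consistency check in testing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cells import SeedPoint, assign_contacts, segment_cells
from .config import ExperimentConfig, config_hash, config_to_dict
from .image import write_json
from .profiles import FiberPath, aggregate_profiles, profile_along_fiber
from .quantify import CellRecord, per_cell_summary, shape_parameters
from .segmentation import segment_focal_contacts
from .stats import compare_groups
from .synthetic import (CHANNEL_ACTIN, CHANNEL_CONTACT, CHANNEL_FASCIN,
                        SyntheticGroundTruth, generate_group,
                        truth_cell_label_map)

__all__ = ["RunManifest", "run_experiment", "quantify_scene",
           "truth_cell_records"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    rng_seed: int
    tool_version: str
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def truth_cell_records(truth: SyntheticGroundTruth) -> list[CellRecord]:
    """Per-cell records computed directly from the ground-truth tables."""
    px = truth.spec.pixel_size_um
    out = []
    for cell in truth.cells:
        areas = [c.area_um2 for c in truth.contacts if c.cell_id == cell.cell_id]
        total = float(sum(areas))
        out.append(CellRecord(
            cell_id=cell.cell_id,
            fc_count=len(areas),
            mean_fc_area_um2=(total / len(areas)) if areas else float("nan"),
            total_fc_area_um2=total,
            cell_area_um2=float(cell.footprint.sum()) * px * px,
        ))
    return out


def quantify_scene(channels, truth: SyntheticGroundTruth,
                   cfg: ExperimentConfig) -> list[CellRecord]:
    """Segment and quantify one scene's contact channel.

    Cell regions come from the ground-truth footprints via their centroid
    seed points (the semi-automatic step: a human would click the cells).
    """
    if cfg.oracle_mode:
        return truth_cell_records(truth)
    image = channels[CHANNEL_CONTACT]
    labels = segment_focal_contacts(image, cfg.segmentation)
    cells = truth_cell_label_map(truth)
    assignments = assign_contacts(labels, cells, image.pixel_size_um)
    records = shape_parameters(
        labels, image, assignments,
        core_erosion_px=cfg.segmentation.core_erosion_px,
        ring_width_px=cfg.segmentation.ring_width_px)
    return per_cell_summary(records, cells, image.pixel_size_um)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None,
                   rng_seed: int | None = None) -> dict:
    """Run the full two-group experiment; returns a result dictionary and,
    when ``out_dir`` is given, writes tables plus a run manifest.

    Deterministic for a fixed config and seed.
    """
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    manifest = RunManifest(config_hash=config_hash(cfg), rng_seed=seed,
                           tool_version=__version__)

    control_scenes, test_scenes = generate_group(
        cfg.scene_control, cfg.scene_test, cfg.n_scenes_per_group, seed)
    manifest.stage_counts["scenes_per_group"] = cfg.n_scenes_per_group
    manifest.stage_counts["true_contacts_control"] = sum(
        len(t.contacts) for _, t in control_scenes)
    manifest.stage_counts["true_contacts_test"] = sum(
        len(t.contacts) for _, t in test_scenes)

    def quantify_all(scenes, group: str) -> list[CellRecord]:
        records: list[CellRecord] = []
        for i, (channels, truth) in enumerate(scenes):
            for rec in quantify_scene(channels, truth, cfg):
                # make cell ids unique across scenes of a group
                records.append(dataclasses.replace(
                    rec, cell_id=rec.cell_id + 10000 * i))
        manifest.stage_counts[f"cells_{group}"] = len(records)
        manifest.stage_counts[f"detected_contacts_{group}"] = int(
            sum(r.fc_count for r in records))
        return records

    control_records = quantify_all(control_scenes, "control")
    test_records = quantify_all(test_scenes, "test")

    comparisons = {}
    for metric in cfg.metrics:
        sc, st, res = compare_groups(control_records, test_records, metric,
                                     t_variant=cfg.t_variant,
                                     n_boot=cfg.n_boot, seed=seed)
        comparisons[metric] = {
            "control": {"n": sc.n, "mean": sc.mean, "sd": sc.sd, "sem": sc.sem},
            "test": {"n": st.n, "mean": st.mean, "sd": st.sd, "sem": st.sem},
            "comparison": dataclasses.asdict(res),
        }

    profiles_summary = None
    if cfg.scene_control.morphology_mode == "stretched":
        profiles = []
        for channels, truth in control_scenes:
            chans = [channels[CHANNEL_ACTIN], channels[CHANNEL_FASCIN]]
            for fib in truth.fibers:
                profiles.append(profile_along_fiber(
                    chans, FiberPath(fib.fiber_id, fib.cell_id, fib.vertices),
                    n_bins=cfg.profile_bins))
        if profiles:
            agg = aggregate_profiles(profiles)
            profiles_summary = {
                "distances": agg.distances.tolist(),
                "mean": agg.mean.tolist(),
                "sem": agg.sem.tolist(),
                "n_fibers": agg.n_fibers,
            }
            manifest.stage_counts["fibers_profiled"] = agg.n_fibers

    result = {
        "comparisons": comparisons,
        "profiles": profiles_summary,
        "manifest": dataclasses.asdict(manifest),
        "config": config_to_dict(cfg),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, records in (("control", control_records),
                              ("test", test_records)):
            path = out / f"cell_records_{name}.csv"
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                path, index=False)
            manifest.outputs[f"cell_records_{name}"] = str(path)
        write_json(result["comparisons"], out / "comparisons.json")
        manifest.outputs["comparisons"] = str(out / "comparisons.json")
        if profiles_summary is not None:
            write_json(profiles_summary, out / "fiber_profiles.json")
            manifest.outputs["fiber_profiles"] = str(out / "fiber_profiles.json")
        result["manifest"] = dataclasses.asdict(manifest)
        write_json(result["manifest"], out / "manifest.json")
    return result
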