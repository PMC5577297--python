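"""Study-condition experiments: self-contained drivers that regenerate the
synthetic data and measure what the pipeline recovers.

These functions are the computational core behind the analysis scripts and
the reproduction script; each one returns a plain dict of numbers computed
at run time.

Reported group means follow the per-cell convention: every cell contributes
once (its contact count, its mean contact area), matching how the imaging
experiments report "per cell" quantities.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .config import ExperimentConfig, load_config
from .pipeline import quantify_scene, truth_cell_records
from .profiles import FiberPath, aggregate_profiles, profile_along_fiber
from .quantify import (BlobCountConfig, count_cells_in_fields, relative_adhesion)
from .stats import compare_groups, percent_reduction
from .synthetic import (CHANNEL_ACTIN, CHANNEL_FASCIN, SceneSpec, control_spec,
                        generate_gradient_fiber_scene, generate_nuclei_field,
                        generate_scene, knockdown_spec)

__all__ = [
    "PRINTED_GROUP_MEANS",
    "printed_mean_reductions",
    "fa_recovery_experiment",
    "profile_recovery_experiment",
    "adhesion_recovery_experiment",
]

#: Published per-cell group means of the imaging study this pipeline
#: re-implements: (control mean, knockdown mean) per metric.
PRINTED_GROUP_MEANS = {
    "fc_count": (196.0, 125.0),
    "mean_fc_area_um2": (1.48, 1.19),
    "total_fc_area_um2": (304.0, 154.0),
}


def printed_mean_reductions() -> dict[str, float]:
    """Percent reductions recomputed from the published group means."""
    return {metric: percent_reduction(c, t)
            for metric, (c, t) in PRINTED_GROUP_MEANS.items()}


def _child_seeds(rng_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(rng_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def fa_recovery_experiment(n_cells_per_group: int = 50, rng_seed: int = 0,
                           cfg: ExperimentConfig | None = None,
                           oracle_mode: bool = False) -> dict:
    """Generate control and knockdown cells at the study conditions, run the
    full detection pipeline on each scene, and compare detected per-cell
    statistics with the generator truth.

    Scenes are processed one at a time (memory stays flat); all seeds derive
    from ``rng_seed``.
    """
    if cfg is None:
        cfg = load_config(None)
    cfg = dataclasses.replace(cfg, oracle_mode=oracle_mode)
    seeds = _child_seeds(rng_seed, 2 * n_cells_per_group)

    groups = {}
    for gi, (name, spec) in enumerate((("control", cfg.scene_control),
                                       ("knockdown", cfg.scene_test))):
        det_records, truth_records = [], []
        for i, seed in enumerate(seeds[gi * n_cells_per_group:
                                       (gi + 1) * n_cells_per_group]):
            scene_spec = dataclasses.replace(spec, rng_seed=seed)
            channels, truth = generate_scene(scene_spec)
            for rec in quantify_scene(channels, truth, cfg):
                det_records.append(dataclasses.replace(rec, cell_id=rec.cell_id
                                                       + 10000 * i))
            for rec in truth_cell_records(truth):
                truth_records.append(dataclasses.replace(rec, cell_id=rec.cell_id
                                                         + 10000 * i))
        groups[name] = {"detected": det_records, "truth": truth_records}

    def group_stats(records):
        counts = np.array([r.fc_count for r in records], dtype=float)
        areas = np.array([r.mean_fc_area_um2 for r in records], dtype=float)
        totals = np.array([r.total_fc_area_um2 for r in records], dtype=float)
        return {
            "mean_fc_count": float(counts.mean()),
            "mean_fc_area_um2": float(np.nanmean(areas)),
            "mean_total_fc_area_um2": float(totals.mean()),
            "n_cells": len(records),
        }

    out = {"n_cells_per_group": n_cells_per_group, "rng_seed": rng_seed,
           "oracle_mode": oracle_mode}
    for name in ("control", "knockdown"):
        out[name] = {"detected": group_stats(groups[name]["detected"]),
                     "truth": group_stats(groups[name]["truth"])}
    for kind in ("detected", "truth"):
        out[f"{kind}_count_reduction_pct"] = percent_reduction(
            out["control"][kind]["mean_fc_count"],
            out["knockdown"][kind]["mean_fc_count"])
        out[f"{kind}_total_area_reduction_pct"] = percent_reduction(
            out["control"][kind]["mean_total_fc_area_um2"],
            out["knockdown"][kind]["mean_total_fc_area_um2"])

    _, _, comparison = compare_groups(
        groups["control"]["detected"], groups["knockdown"]["detected"],
        "fc_count", n_boot=cfg.n_boot, seed=rng_seed)
    out["comparison_fc_count"] = dataclasses.asdict(comparison)
    return out


def profile_recovery_experiment(n_cells: int = 15, n_fibers_per_cell: int = 5,
                                rng_seed: int = 0, n_bins: int = 20) -> dict:
    """Noiseless stretched cells with opposite linear gradients on the two
    fiber channels; measures how well per-fiber profiles recover the
    generating slopes and whether the aggregated profiles are monotone."""
    base = control_spec(
        image_size=(256, 256), cell_radius_um=20.0,
        morphology_mode="stretched", fa_count_law=(0.0, 0.0),
        n_fibers_per_cell=n_fibers_per_cell,
        gradient_slopes=(-80.0, 80.0), fiber_base_intensity=(100.0, 20.0),
        background_level=0.0)
    profiles = []
    slope_errors = {0: [], 1: []}
    for seed in _child_seeds(rng_seed, n_cells):
        spec = dataclasses.replace(base, rng_seed=seed)
        channels, truth = generate_gradient_fiber_scene(spec, apply_noise=False)
        chans = [channels[CHANNEL_ACTIN], channels[CHANNEL_FASCIN]]
        for fib in truth.fibers:
            prof = profile_along_fiber(
                chans, FiberPath(fib.fiber_id, fib.cell_id, fib.vertices),
                n_bins=n_bins)
            profiles.append(prof)
            for ci, slope in ((0, base.gradient_slopes[0]),
                              (1, base.gradient_slopes[1])):
                fitted = float(np.polyfit(prof.bin_centers,
                                          prof.intensities[ci], 1)[0])
                slope_errors[ci].append(abs(fitted - slope) / abs(slope))
    agg = aggregate_profiles(profiles)
    return {
        "n_fibers": agg.n_fibers,
        "n_bins": n_bins,
        "max_slope_rel_error_actin": float(max(slope_errors[0])),
        "max_slope_rel_error_fascin": float(max(slope_errors[1])),
        "actin_monotone_decreasing": bool(np.all(np.diff(agg.mean[0]) < 0)),
        "fascin_monotone_increasing": bool(np.all(np.diff(agg.mean[1]) > 0)),
        "aggregated_mean": agg.mean.tolist(),
        "aggregated_sem": agg.sem.tolist(),
        "distances": agg.distances.tolist(),
    }


def adhesion_recovery_experiment(n_fields: int = 40, true_loss_pct: float = 17.0,
                                 mean_cells_per_field: float = 45.0,
                                 rng_seed: int = 0) -> dict:
    """Simulate the adherent-cell counting assay: nuclei-stained fields for a
    control and a depleted condition (true loss ``true_loss_pct``), counted
    by the blob detector, compared with :func:`relative_adhesion`.

    Per-field true cell numbers are Poisson distributed around the condition
    mean, the natural model for cells scattered over many fields.
    """
    spec = control_spec(image_size=(512, 512), nucleus_radius_um=2.5)
    blob_cfg = BlobCountConfig(nucleus_radius_um=2.5)
    seeds = _child_seeds(rng_seed, 2 * n_fields + 1)
    count_rng = np.random.default_rng(seeds[-1])
    groups = {}
    for gi, (name, mean) in enumerate((
            ("control", mean_cells_per_field),
            ("test", mean_cells_per_field * (1.0 - true_loss_pct / 100.0)))):
        images, true_counts = [], []
        for seed in seeds[gi * n_fields:(gi + 1) * n_fields]:
            n_true = int(count_rng.poisson(mean))
            img, pts = generate_nuclei_field(spec, n_true, rng_seed=seed)
            images.append(img)
            true_counts.append(len(pts))
        counted = count_cells_in_fields(images, blob_cfg)
        groups[name] = {"fields": counted, "true_counts": true_counts}
    res = relative_adhesion(groups["test"]["fields"], groups["control"]["fields"])
    return {
        "n_fields_per_group": n_fields,
        "true_loss_pct": true_loss_pct,
        "estimated_loss_pct": res.percent_lost,
        "estimated_se_pct": res.se_percent,
        "control_mean_count": float(np.mean([f.n_cells for f in
                                             groups["control"]["fields"]])),
        "test_mean_count": float(np.mean([f.n_cells for f in
                                          groups["test"]["fields"]])),
        "control_true_mean": float(np.mean(groups["control"]["true_counts"])),
        "test_true_mean": float(np.mean(groups["test"]["true_counts"])),
    }
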