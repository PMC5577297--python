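"""Fluorescence intensity profiles along stress-fiber polylines.

A fiber path is an ordered polyline whose first vertex is the actin-rich
center (ARC); the profile reports per-channel mean intensities in equal
arc-length bins of the normalized ARC-to-periphery distance. Sampling is
sub-pixel (default 0.25 px steps) with bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import RasterImage

__all__ = ["FiberPath", "FiberProfile", "AggregatedProfile",
           "profile_along_fiber", "aggregate_profiles"]


@dataclass(frozen=True)
class FiberPath:
    fiber_id: int
    cell_id: int
    vertices: np.ndarray  # (n, 2) float (row, col); first vertex = ARC

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError(f"vertices must be (n >= 2, 2), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @property
    def length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass(frozen=True)
class FiberProfile:
    """Binned per-channel intensity vs normalized ARC distance.

    ``distances`` is the bin coordinate pinned to run from 0 (ARC) to 1
    (periphery); ``bin_centers`` holds the mean normalized sample position
    actually averaged into each bin (use these for slope estimation);
    ``intensities`` has shape (n_channels, n_bins).
    """
    fiber_id: int
    distances: np.ndarray
    intensities: np.ndarray
    bin_centers: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_centers is None:
            object.__setattr__(self, "bin_centers", self.distances.copy())

    @property
    def n_bins(self) -> int:
        return int(self.distances.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.intensities.shape[0])


def profile_along_fiber(channels: list[RasterImage], path: FiberPath,
                        n_bins: int = 20, step_px: float = 0.25,
                        normalize: str = "none") -> FiberProfile:
    """Sample each channel along the path and average into equal-length bins.

    ``normalize="max"`` divides each channel's profile by its own maximum
    (per fiber); the default reports raw intensities.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not channels:
        raise ValueError("at least one channel is required")
    if normalize not in ("none", "max"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    shape = channels[0].shape
    for ch in channels[1:]:
        if ch.shape != shape or ch.pixel_size_um != channels[0].pixel_size_um:
            raise ValueError("channels must share shape and calibration")
    total = path.length_px
    if total < 2.0:
        raise ValueError(f"fiber path shorter than 2 px (length {total:.2f})")

    seg = np.diff(path.vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_samples = max(2, int(np.ceil(total / step_px)) + 1)
    t = np.linspace(0.0, total, n_samples)
    rows = np.interp(t, cum, path.vertices[:, 0])
    cols = np.interp(t, cum, path.vertices[:, 1])
    t_norm = t / total
    bin_idx = np.minimum((t_norm * n_bins).astype(int), n_bins - 1)

    profile = np.empty((len(channels), n_bins), dtype=np.float64)
    counts = np.bincount(bin_idx, minlength=n_bins).astype(np.float64)
    centers = np.bincount(bin_idx, weights=t_norm, minlength=n_bins) / counts
    for ci, ch in enumerate(channels):
        samples = ndimage.map_coordinates(
            ch.pixels.astype(np.float64), np.vstack([rows, cols]),
            order=1, mode="nearest")
        sums = np.bincount(bin_idx, weights=samples, minlength=n_bins)
        profile[ci] = sums / counts
        if normalize == "max":
            peak = profile[ci].max()
            if peak > 0:
                profile[ci] = profile[ci] / peak
    distances = np.linspace(0.0, 1.0, n_bins)
    return FiberProfile(path.fiber_id, distances, profile, centers)


@dataclass(frozen=True)
class AggregatedProfile:
    distances: np.ndarray     # (n_bins,)
    mean: np.ndarray          # (n_channels, n_bins)
    sem: np.ndarray           # (n_channels, n_bins)
    n_fibers: int
    bin_centers: np.ndarray = None  # type: ignore[assignment]


def aggregate_profiles(profiles: list[FiberProfile]) -> AggregatedProfile:
    """Per-bin arithmetic mean and SEM across fibers, per channel."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    n_bins = profiles[0].n_bins
    n_channels = profiles[0].n_channels
    for p in profiles[1:]:
        if p.n_bins != n_bins:
            raise ValueError(
                f"mixed bin counts: {p.n_bins} vs {n_bins}; re-bin first")
        if p.n_channels != n_channels:
            raise ValueError("profiles have different channel counts")
    stack = np.stack([p.intensities for p in profiles])  # (F, C, B)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros_like(mean)
    centers = np.mean([p.bin_centers for p in profiles], axis=0)
    return AggregatedProfile(profiles[0].distances.copy(), mean, sem, n, centers)
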