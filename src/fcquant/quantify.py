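"""Per-contact shape/intensity measurements, per-cell summaries, and
adherent-cell counting.

Shape descriptors are the standard moment set: area from the pixel count,
axes and eccentricity from the moment-equivalent ellipse (axis length =
4·sqrt(eigenvalue) of the coordinate covariance), orientation measured from
the +col axis in (-pi/2, pi/2]. All physical quantities carry the image
calibration (µm, µm²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.measure import regionprops

from .cells import ContactAssignment
from .image import LabelMap, RasterImage

__all__ = [
    "FocalContactRecord",
    "CellRecord",
    "FieldCount",
    "BlobCountConfig",
    "AdhesionResult",
    "shape_parameters",
    "per_cell_summary",
    "count_cells_in_fields",
    "relative_adhesion",
]

logger = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass(frozen=True)
class FocalContactRecord:
    """One segmented focal contact: shape parameters and fluorescence
    activities, with its cell assignment."""
    contact_id: int
    cell_id: int  # 0 = unassigned
    area_um2: float
    centroid_row: float
    centroid_col: float
    major_axis_um: float
    minor_axis_um: float
    eccentricity: float
    orientation_rad: float
    mean_intensity: float
    integrated_intensity: float
    center_intensity: float
    periphery_intensity: float
    specificity_ratio: float
    distance_to_cell_edge_um: float


@dataclass(frozen=True)
class CellRecord:
    """Per-cell aggregate of its focal contacts."""
    cell_id: int
    fc_count: int
    mean_fc_area_um2: float   # NaN when fc_count == 0
    total_fc_area_um2: float
    cell_area_um2: float


@dataclass(frozen=True)
class FieldCount:
    field_id: int
    n_cells: int


def _orientation_from_moments(coords: np.ndarray) -> float:
    """Major-axis angle from the +col axis, (-pi/2, pi/2], y-up convention
    (a horizontal line has orientation 0)."""
    r = coords[:, 0].astype(np.float64)
    c = coords[:, 1].astype(np.float64)
    mu_rr = np.mean((r - r.mean()) ** 2)
    mu_cc = np.mean((c - c.mean()) ** 2)
    mu_rc = np.mean((r - r.mean()) * (c - c.mean()))
    theta = 0.5 * math.atan2(-2.0 * mu_rc, mu_cc - mu_rr)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return theta


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= r * r


def shape_parameters(labels: LabelMap, image: RasterImage,
                     assignments: list[ContactAssignment] | None = None,
                     core_erosion_px: int = 1,
                     ring_width_px: int = 2) -> list[FocalContactRecord]:
    """Measure every labelled contact on the given intensity channel.

    ``assignments`` (from :func:`fcquant.cells.assign_contacts`) attaches
    cell ids and edge distances; without it contacts are reported
    unassigned. Center/periphery intensities use the same eroded-core /
    outside-ring definitions as the segmentation specificity filter.
    """
    if labels.shape != image.shape:
        raise ValueError("labels and image shapes differ")
    if labels.n_labels == 0:
        return []
    amap = {a.contact_id: a for a in (assignments or [])}
    px = image.pixel_size_um
    img = image.pixels.astype(np.float64)
    fg_all = labels.labels > 0
    core_structure = _disk(core_erosion_px)
    ring_structure = _disk(ring_width_px)
    records: list[FocalContactRecord] = []
    for prop in regionprops(labels.labels, intensity_image=img):
        cid = int(prop.label)
        coords = prop.coords
        n_px = coords.shape[0]
        mean_int = float(prop.intensity_mean)
        # exact: integrated = mean x pixel count
        integrated = mean_int * n_px

        sl = tuple(slice(max(0, s.start - ring_width_px - 1),
                         min(dim, s.stop + ring_width_px + 1))
                   for s, dim in zip(prop.slice, labels.shape))
        comp = labels.labels[sl] == cid
        core = ndimage.binary_erosion(comp, structure=core_structure)
        center_int = float(img[sl][core].mean() if core.any() else img[sl][comp].mean())
        ring = ndimage.binary_dilation(comp, structure=ring_structure) & ~fg_all[sl]
        periphery_int = float(img[sl][ring].mean()) if ring.any() else 0.0
        ratio = (center_int / periphery_int) if periphery_int > 0 else math.inf

        assigned = amap.get(cid)
        records.append(FocalContactRecord(
            contact_id=cid,
            cell_id=assigned.cell_id if assigned else UNASSIGNED,
            area_um2=n_px * px * px,
            centroid_row=float(prop.centroid[0]),
            centroid_col=float(prop.centroid[1]),
            major_axis_um=float(prop.axis_major_length) * px,
            minor_axis_um=float(prop.axis_minor_length) * px,
            eccentricity=float(prop.eccentricity),
            orientation_rad=_orientation_from_moments(coords),
            mean_intensity=mean_int,
            integrated_intensity=integrated,
            center_intensity=center_int,
            periphery_intensity=periphery_int,
            specificity_ratio=ratio,
            distance_to_cell_edge_um=(assigned.distance_to_cell_edge_um
                                      if assigned else float("nan")),
        ))
    return records


def per_cell_summary(records: list[FocalContactRecord], cells: LabelMap,
                     pixel_size_um: float) -> list[CellRecord]:
    """Aggregate contacts per cell: count, mean area, total area.

    Every cell present in the label map is reported, including cells with
    no contacts (mean area NaN). Unassigned contacts are excluded and their
    number logged.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n_unassigned = sum(1 for r in records if r.cell_id == UNASSIGNED)
    if n_unassigned:
        logger.info("excluding %d unassigned contacts from per-cell summary",
                    n_unassigned)
    cell_ids = [int(c) for c in np.unique(cells.labels) if c > 0]
    areas_px = {cid: int((cells.labels == cid).sum()) for cid in cell_ids}
    by_cell: dict[int, list[float]] = {cid: [] for cid in cell_ids}
    for r in records:
        if r.cell_id != UNASSIGNED and r.cell_id in by_cell:
            by_cell[r.cell_id].append(r.area_um2)
    out = []
    for cid in cell_ids:
        member = by_cell[cid]
        total = float(sum(member))
        out.append(CellRecord(
            cell_id=cid,
            fc_count=len(member),
            mean_fc_area_um2=(total / len(member)) if member else float("nan"),
            total_fc_area_um2=total,
            cell_area_um2=areas_px[cid] * pixel_size_um ** 2,
        ))
    return out


@dataclass(frozen=True)
class BlobCountConfig:
    """Laplacian-of-Gaussian nucleus counter settings."""
    nucleus_radius_um: float = 5.0
    threshold_rel: float = 0.1     # on the max-normalized image
    sigma_span: tuple[float, float] = (0.6, 1.5)  # relative to nominal sigma
    n_sigma: int = 5


def count_cells_in_fields(nuclei_images: list[RasterImage],
                          config: BlobCountConfig | None = None
                          ) -> list[FieldCount]:
    """Count stained nuclei per microscopic field with a LoG blob detector.

    The image is max-normalized before detection, so counts are invariant
    under intensity rescaling when the background is zero. A blank
    (constant) field counts zero cells.
    """
    if not nuclei_images:
        raise ValueError("no fields given")
    if config is None:
        config = BlobCountConfig()
    out: list[FieldCount] = []
    for field_id, image in enumerate(nuclei_images, start=1):
        img = image.pixels.astype(np.float64)
        lo, hi = float(img.min()), float(img.max())
        if hi <= lo:
            out.append(FieldCount(field_id, 0))
            continue
        norm = (img - lo) / (hi - lo)
        sigma0 = (config.nucleus_radius_um / image.pixel_size_um) / math.sqrt(2.0)
        blobs = blob_log(norm,
                         min_sigma=config.sigma_span[0] * sigma0,
                         max_sigma=config.sigma_span[1] * sigma0,
                         num_sigma=config.n_sigma,
                         threshold=config.threshold_rel)
        out.append(FieldCount(field_id, int(blobs.shape[0])))
    return out


@dataclass(frozen=True)
class AdhesionResult:
    percent_remaining: float
    percent_lost: float
    se_percent: float
    n_fields_test: int
    n_fields_control: int


def relative_adhesion(test_fields: list[FieldCount],
                      control_fields: list[FieldCount]) -> AdhesionResult:
    """Adherent cells remaining in the test condition relative to control.

    percent remaining = 100 x mean(test counts) / mean(control counts);
    percent lost = 100 - remaining. The standard error propagates the two
    field-mean SEMs through the ratio.
    """
    if len(test_fields) < 2 or len(control_fields) < 2:
        raise ValueError("need >= 2 fields per group")
    t = np.array([f.n_cells for f in test_fields], dtype=np.float64)
    c = np.array([f.n_cells for f in control_fields], dtype=np.float64)
    mc = c.mean()
    mt = t.mean()
    if mc == 0:
        raise ValueError("control mean count is zero")
    se_t = t.std(ddof=1) / math.sqrt(len(t))
    se_c = c.std(ddof=1) / math.sqrt(len(c))
    ratio = mt / mc
    se_ratio = ratio * math.sqrt((se_t / mt) ** 2 + (se_c / mc) ** 2) if mt > 0 else \
        se_t / mc
    return AdhesionResult(
        percent_remaining=100.0 * ratio,
        percent_lost=100.0 * (1.0 - ratio),
        se_percent=100.0 * se_ratio,
        n_fields_test=len(t),
        n_fields_control=len(c),
    )
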