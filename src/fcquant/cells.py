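"""Semi-automatic cell segmentation and contact-to-cell assignment.

"Semi-automatic" here means: the user marks one seed point per cell, the
boundary is found automatically by a seeded watershed on the smoothed,
inverted intensity, restricted to an Otsu foreground support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .image import LabelMap, RasterImage

__all__ = ["SeedPoint", "CellSegConfig", "segment_cells", "assign_contacts",
           "ContactAssignment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedPoint:
    """A user-supplied marker pixel identifying one cell."""
    cell_id: int
    row: int
    col: int


@dataclass(frozen=True)
class CellSegConfig:
    smoothing_sigma_px: float = 3.0
    connectivity: int = 8


def segment_cells(image: RasterImage, seeds: list[SeedPoint],
                  config: CellSegConfig | None = None) -> LabelMap:
    """Seeded watershed cell segmentation.

    The intensity image is Gaussian-smoothed, an Otsu threshold on the
    smoothed image defines the foreground support, and a marker-based
    watershed on the inverted smoothed intensity partitions the support
    among the seeds. A seed falling on background support yields an empty
    region (logged warning, not an error).
    """
    if config is None:
        config = CellSegConfig()
    if not seeds:
        raise ValueError("at least one seed point is required")
    rows, cols = image.shape
    ids = [s.cell_id for s in seeds]
    if len(set(ids)) != len(ids):
        raise ValueError("seed cell_ids must be unique")
    if len({(s.row, s.col) for s in seeds}) != len(seeds):
        raise ValueError("seed pixels must be pairwise distinct")
    for s in seeds:
        if s.cell_id < 1:
            raise ValueError(f"cell_id must be positive, got {s.cell_id}")
        if not (0 <= s.row < rows and 0 <= s.col < cols):
            raise ValueError(f"seed {s} outside image bounds {image.shape}")

    smoothed = gaussian(image.pixels.astype(np.float64), config.smoothing_sigma_px,
                        preserve_range=True)
    if np.ptp(smoothed) == 0:
        support = np.zeros(image.shape, dtype=bool)
    else:
        support = smoothed > threshold_otsu(smoothed)

    markers = np.zeros(image.shape, dtype=np.int32)
    for s in seeds:
        if not support[s.row, s.col]:
            logger.warning("seed for cell %d at (%d, %d) lies on background "
                           "support; its region may be empty",
                           s.cell_id, s.row, s.col)
        markers[s.row, s.col] = s.cell_id
    lab = watershed(-smoothed, markers=markers, mask=support,
                    connectivity=(1 if config.connectivity == 4 else 2))
    # keep seed pixels labelled even off-support (marker property)
    for s in seeds:
        if lab[s.row, s.col] == 0:
            lab[s.row, s.col] = s.cell_id
    return LabelMap(lab.astype(np.int32))


@dataclass(frozen=True)
class ContactAssignment:
    contact_id: int
    cell_id: int                    # 0 = unassigned
    distance_to_cell_edge_um: float  # NaN when unassigned


def assign_contacts(contacts: LabelMap, cells: LabelMap,
                    pixel_size_um: float) -> list[ContactAssignment]:
    """Assign each contact to the cell containing its centroid pixel.

    The reported distance is the Euclidean distance transform of the cell
    region evaluated at the (rounded) centroid, scaled to µm. A centroid
    outside all cells leaves the contact unassigned (cell_id 0).
    """
    if contacts.shape != cells.shape:
        raise ValueError(
            f"shape mismatch: contacts {contacts.shape} vs cells {cells.shape}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n = contacts.n_labels
    if n == 0:
        return []
    centroids = ndimage.center_of_mass(
        contacts.labels > 0, contacts.labels, range(1, n + 1))
    edts = {cid: ndimage.distance_transform_edt(cells.labels == cid)
            for cid in np.unique(cells.labels[cells.labels > 0])}
    out: list[ContactAssignment] = []
    for contact_id, (r, c) in enumerate(centroids, start=1):
        ri = int(round(r))
        ci = int(round(c))
        ri = min(max(ri, 0), contacts.shape[0] - 1)
        ci = min(max(ci, 0), contacts.shape[1] - 1)
        cell_id = int(cells.labels[ri, ci])
        if cell_id == 0:
            out.append(ContactAssignment(contact_id, 0, float("nan")))
        else:
            dist = float(edts[cell_id][ri, ci]) * pixel_size_um
            out.append(ContactAssignment(contact_id, cell_id, dist))
    return out
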