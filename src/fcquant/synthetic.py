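"""Synthetic podocyte-like fluorescence scenes with full ground truth.

Every downstream stage of the pipeline (segmentation, cell assignment,
quantification, fiber profiling, group statistics) is exercised against
scenes produced here, so each rendered object is recorded in a
:class:`SyntheticGroundTruth` table.

A scene contains, per cell:

* a smoothed star-convex cell footprint;
* elongated focal contacts rendered as anisotropic Gaussian spots placed in
  the peripheral band of the footprint, radially aligned;
* stress fibers — parallel chords in ``unstretched`` mode, radii converging
  into a single actin-rich center (ARC) in ``stretched`` mode — carrying
  linear, per-channel intensity gradients along their normalized length;
* a nucleus blob in a separate channel.

The half-peak contour of each contact's Gaussian spot is exactly the drawn
ellipse, so the recorded true area ``π·a·b`` is an analytic property of the
render. Noise is signal-dependent (Poisson with a camera gain) plus additive
Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .image import LabelMap, RasterImage, write_image, write_json, write_label_map

__all__ = [
    "SceneSpec",
    "SceneOvercrowdedError",
    "CellTruth",
    "ContactTruth",
    "FiberTruth",
    "SyntheticGroundTruth",
    "generate_scene",
    "generate_group",
    "generate_gradient_fiber_scene",
    "generate_nuclei_field",
    "truth_contact_label_map",
    "truth_cell_label_map",
    "control_spec",
    "knockdown_spec",
    "write_scene",
    "CHANNEL_CONTACT",
    "CHANNEL_ACTIN",
    "CHANNEL_FASCIN",
    "CHANNEL_NUCLEI",
]

CHANNEL_CONTACT = "talin-1"
CHANNEL_ACTIN = "F-actin"
CHANNEL_FASCIN = "fascin-1"
CHANNEL_NUCLEI = "nuclei"

#: Half-peak radius of a Gaussian in units of its sigma: exp(-r²/2σ²) = 1/2.
_HALF_PEAK_SIGMA = math.sqrt(2.0 * math.log(2.0))


class SceneOvercrowdedError(RuntimeError):
    """Raised when objects cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of one synthetic scene.

    Distribution "laws" are ``(mean, sd)`` pairs of a (truncated) normal.
    Defaults describe a single stretched-experiment control podocyte:
    roughly 196 talin-positive contacts of ~1.48 µm² each, imaged at
    0.2 µm/pixel with a contact-peak signal-to-noise ratio of about 10.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.2
    n_cells: int = 1
    fa_count_law: tuple[float, float] = (196.0, 15.0)
    fa_area_law_um2: tuple[float, float] = (1.48, 0.30)
    fa_elongation_law: tuple[float, float] = (3.0, 0.6)
    fa_peak_intensity: float = 1000.0
    morphology_mode: str = "unstretched"
    n_fibers_per_cell: int = 5
    gradient_slopes: tuple[float, float] = (-80.0, 80.0)
    fiber_base_intensity: tuple[float, float] = (100.0, 20.0)
    background_level: float = 100.0
    noise_poisson_gain: float = 9.0
    noise_gaussian_sd: float = 10.0
    cell_radius_um: float = 42.0
    nucleus_radius_um: float = 5.0
    nucleus_peak_intensity: float = 800.0
    rng_seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 8 or cols < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for name in ("fa_count_law", "fa_area_law_um2", "fa_elongation_law"):
            mean, sd = getattr(self, name)
            if not (np.isfinite(mean) and np.isfinite(sd) and sd >= 0):
                raise ValueError(f"{name} must have finite mean and sd >= 0")
        if self.fa_area_law_um2[0] <= 0:
            raise ValueError("fa_area_law_um2 mean must be > 0")
        if self.fa_elongation_law[0] < 1:
            raise ValueError("fa_elongation_law mean must be >= 1 (axis ratio)")
        if self.morphology_mode not in ("unstretched", "stretched"):
            raise ValueError(f"unknown morphology_mode {self.morphology_mode!r}")
        if self.n_cells < 0 or self.n_fibers_per_cell < 0:
            raise ValueError("counts must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        # Fiber gradients must stay non-negative over the whole fiber length.
        for base, slope in zip(self.fiber_base_intensity, self.gradient_slopes):
            if base < 0 or base + min(0.0, slope) < 0:
                raise ValueError(
                    f"fiber intensity law base={base}, slope={slope} goes negative")
        r_px = self.cell_radius_um / self.pixel_size_um
        if 2.4 * r_px > min(rows, cols):
            raise ValueError(
                f"cell radius {self.cell_radius_um} µm does not fit in image {self.image_size}")
        # grid capacity under the placement rule (centers >= 2.15 r apart,
        # 1.05 r margin to the border)
        nr = int((rows - 2.1 * r_px) // (2.15 * r_px)) + 1
        nc = int((cols - 2.1 * r_px) // (2.15 * r_px)) + 1
        if self.n_cells > max(0, nr) * max(0, nc):
            raise ValueError(
                f"image {self.image_size} cannot hold {self.n_cells} non-overlapping cells "
                f"of radius {self.cell_radius_um} µm")


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    footprint: np.ndarray          # boolean mask, image shape
    centroid: tuple[float, float]  # (row, col)
    arc: tuple[float, float] | None  # actin-rich center (stretched mode)


@dataclass(frozen=True)
class ContactTruth:
    contact_id: int
    cell_id: int
    center: tuple[float, float]    # (row, col), px
    semi_major_um: float
    semi_minor_um: float
    orientation_rad: float         # from the +col axis, in (-pi/2, pi/2]
    peak_intensity: float

    @property
    def area_um2(self) -> float:
        """True area: the half-peak ellipse of the rendered Gaussian spot."""
        return math.pi * self.semi_major_um * self.semi_minor_um


@dataclass(frozen=True)
class FiberTruth:
    fiber_id: int
    cell_id: int
    vertices: np.ndarray           # (n, 2) float (row, col); first vertex = ARC
    # per fiber channel: (intensity at start vertex, intensity at end vertex)
    endpoint_intensities: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    cells: list[CellTruth]
    contacts: list[ContactTruth]
    fibers: list[FiberTruth]
    rng_seed: int
    spec: SceneSpec


# --- low-level rendering -----------------------------------------------------


def _render_gaussian_spot(canvas: np.ndarray, center: tuple[float, float],
                          sigma_major: float, sigma_minor: float,
                          theta: float, peak: float) -> None:
    """Add an anisotropic Gaussian spot to ``canvas`` in place."""
    r0, c0 = center
    ext = int(math.ceil(4.0 * sigma_major)) + 1
    rows, cols = canvas.shape
    rlo, rhi = max(0, int(r0) - ext), min(rows, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(cols, int(c0) + ext + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    # major axis measured from the +col axis; row axis points down
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    canvas[rlo:rhi, clo:chi] += peak * np.exp(
        -(u ** 2 / (2.0 * sigma_major ** 2) + v ** 2 / (2.0 * sigma_minor ** 2)))


def _stamp_fiber(canvas: np.ndarray, vertices: np.ndarray, start_value: float,
                 end_value: float, half_width: float = 1.5,
                 step: float = 0.25) -> None:
    """Render a fiber as a thick polyline whose value varies linearly with
    normalized arc length; overlapping stamps keep the maximum value."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        return
    n_samples = max(2, int(math.ceil(total / step)) + 1)
    t = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts_r = np.interp(t, cum, vertices[:, 0])
    pts_c = np.interp(t, cum, vertices[:, 1])
    # unit tangent at each sample (piecewise-constant per segment)
    seg_idx = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg) - 1)
    tan_r = seg[seg_idx, 0] / seg_len[seg_idx]
    tan_c = seg[seg_idx, 1] / seg_len[seg_idx]

    rows, cols = canvas.shape
    rad = int(math.ceil(half_width))
    offs = [(dr, dc) for dr in range(-rad, rad + 1) for dc in range(-rad, rad + 1)
            if dr * dr + dc * dc <= half_width ** 2]
    for (dr, dc) in offs:
        rr = np.round(pts_r).astype(int) + dr
        cc = np.round(pts_c).astype(int) + dc
        # each painted pixel carries the value of its own projected arc
        # position, so the on-axis intensity is the exact linear law
        t_pix = np.clip(t + dr * tan_r + dc * tan_c, 0.0, total)
        values = start_value + (end_value - start_value) * (t_pix / total)
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        np.maximum.at(canvas, (rr[ok], cc[ok]), values[ok])


def _star_convex_footprint(shape: tuple[int, int], center: tuple[float, float],
                           radius_px: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize a smoothed random star-convex polygon footprint."""
    n_vert = 72
    theta = np.linspace(0.0, 2.0 * math.pi, n_vert, endpoint=False)
    r = np.full(n_vert, radius_px)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.04) * radius_px
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r = r + amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.55 * radius_px, 1.2 * radius_px)
    rr = center[0] + r * np.sin(theta)
    cc = center[1] + r * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    pr, pc = skdraw.polygon(rr, cc, shape=shape)
    mask[pr, pc] = True
    return mask


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = math.inf) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def _effective_radius(a: float, b: float, theta: float, phi: float) -> float:
    """Gaussian-spot footprint half-extent along direction ``phi``."""
    d = phi - theta
    return math.hypot(a * math.cos(d), b * math.sin(d))


def _place_contacts(band_coords: np.ndarray, n: int, a_px: np.ndarray,
                    b_px: np.ndarray, anchor: tuple[float, float],
                    rng: np.random.Generator,
                    orientation_jitter_sd: float = 0.15,
                    margin: float = 1.45) -> tuple[np.ndarray, np.ndarray]:
    """Place ``n`` radially aligned ellipse centers in the peripheral band.

    Enforces an anisotropic minimum center separation so that neighbouring
    spots remain resolvable discrete structures. Returns (centers, thetas).
    """
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    if band_coords.shape[0] == 0:
        raise SceneOvercrowdedError("peripheral band is empty; cell too small")
    centers = np.empty((n, 2))
    thetas = np.empty(n)
    placed = 0
    max_attempts = 300 * n + 1000
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise SceneOvercrowdedError(
                f"scene overcrowded: placed {placed}/{n} contacts "
                f"after {attempts} attempts")
        idx = rng.integers(0, band_coords.shape[0])
        cand = band_coords[idx] + rng.uniform(-0.5, 0.5, size=2)
        # radial orientation: along the ray from the anchor (ARC / centroid)
        radial = math.atan2(cand[0] - anchor[0], cand[1] - anchor[1])
        theta = radial + rng.normal(0.0, orientation_jitter_sd)
        theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
        if placed:
            d = centers[:placed] - cand
            dist = np.hypot(d[:, 0], d[:, 1])
            phi = np.arctan2(d[:, 0], d[:, 1])
            req = np.array([
                _effective_radius(a_px[placed], b_px[placed], theta, p)
                + _effective_radius(a_px[j], b_px[j], thetas[j], p)
                for j, p in enumerate(phi)
            ])
            if np.any(dist < margin * req):
                continue
        centers[placed] = cand
        thetas[placed] = theta
        placed += 1
    return centers, thetas


def _apply_noise(noiseless: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Camera model: Poisson shot noise at a given gain + Gaussian read noise."""
    gain = spec.noise_poisson_gain
    img = np.asarray(noiseless, dtype=np.float64)
    if gain > 0:
        img = gain * rng.poisson(img / gain).astype(np.float64)
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# --- scene generation --------------------------------------------------------


def generate_scene(spec: SceneSpec, *, apply_noise: bool = True
                   ) -> tuple[dict[str, RasterImage], SyntheticGroundTruth]:
    """Generate one scene: channels keyed by name, plus full ground truth.

    Channels: contact marker (talin-1), two fiber channels (F-actin and
    fascin-1, carrying the configured gradients in stretched mode), and a
    nuclei channel. Deterministic for a fixed ``spec.rng_seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.rng_seed)
    geom_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    shape = tuple(spec.image_size)
    px = spec.pixel_size_um
    radius_px = spec.cell_radius_um / px

    # -- cells ---------------------------------------------------------------
    cell_centers: list[np.ndarray] = []
    attempts = 0
    while len(cell_centers) < spec.n_cells:
        attempts += 1
        if attempts > 200 * max(1, spec.n_cells):
            raise SceneOvercrowdedError(
                f"scene overcrowded: placed {len(cell_centers)}/{spec.n_cells} cells")
        margin = 1.05 * radius_px
        cand = np.array([
            geom_rng.uniform(margin, shape[0] - margin),
            geom_rng.uniform(margin, shape[1] - margin),
        ])
        if all(np.hypot(*(cand - c)) >= 2.15 * radius_px for c in cell_centers):
            cell_centers.append(cand)

    cells: list[CellTruth] = []
    contacts: list[ContactTruth] = []
    fibers: list[FiberTruth] = []
    contact_ch = np.zeros(shape, dtype=np.float64)
    actin_ch = np.zeros(shape, dtype=np.float64)
    fascin_ch = np.zeros(shape, dtype=np.float64)
    nuclei_ch = np.zeros(shape, dtype=np.float64)

    for ci, center in enumerate(cell_centers, start=1):
        r_cell = radius_px * geom_rng.uniform(0.92, 1.05)
        footprint = _star_convex_footprint(shape, tuple(center), r_cell, geom_rng)
        edt = ndimage.distance_transform_edt(footprint)
        arc = None
        if spec.morphology_mode == "stretched":
            # ARC near the most interior point of the footprint
            flat = np.argmax(edt)
            arc_rc = np.unravel_index(flat, shape)
            arc = (float(arc_rc[0]), float(arc_rc[1]))
        anchor = arc if arc is not None else (float(center[0]), float(center[1]))

        # -- focal contacts --------------------------------------------------
        mean_n, sd_n = spec.fa_count_law
        n_fc = max(0, int(round(geom_rng.normal(mean_n, sd_n))) if sd_n > 0
                   else int(round(mean_n)))
        areas = np.array([
            _truncated_normal(geom_rng, *spec.fa_area_law_um2,
                              low=0.25 * spec.fa_area_law_um2[0])
            for _ in range(n_fc)])
        elong = np.array([
            _truncated_normal(geom_rng, *spec.fa_elongation_law, low=1.0,
                              high=spec.fa_elongation_law[0] + 4 * spec.fa_elongation_law[1])
            for _ in range(n_fc)])
        # area = pi * a * b, elongation = a / b  (semi-axes in µm)
        b_um = np.sqrt(areas / (math.pi * elong))
        a_um = b_um * elong
        a_px_arr = a_um / px
        b_px_arr = b_um / px

        band_depth = 0.30 * edt.max()
        band = (edt >= 2.0) & (edt <= max(band_depth, 3.0))
        band_coords = np.argwhere(band)
        centers_fc, thetas_fc = _place_contacts(
            band_coords, n_fc, a_px_arr, b_px_arr, anchor, geom_rng)
        for k in range(n_fc):
            contacts.append(ContactTruth(
                contact_id=len(contacts) + 1,
                cell_id=ci,
                center=(float(centers_fc[k, 0]), float(centers_fc[k, 1])),
                semi_major_um=float(a_um[k]),
                semi_minor_um=float(b_um[k]),
                orientation_rad=float(thetas_fc[k]),
                peak_intensity=spec.fa_peak_intensity,
            ))
            _render_gaussian_spot(
                contact_ch, tuple(centers_fc[k]),
                sigma_major=a_px_arr[k] / _HALF_PEAK_SIGMA,
                sigma_minor=b_px_arr[k] / _HALF_PEAK_SIGMA,
                theta=thetas_fc[k], peak=spec.fa_peak_intensity)

        # -- fibers ----------------------------------------------------------
        bases = spec.fiber_base_intensity
        slopes = spec.gradient_slopes
        for fi in range(spec.n_fibers_per_cell):
            if spec.morphology_mode == "stretched":
                ang = geom_rng.uniform(0.0, 2.0 * math.pi)
                end = _ray_exit(footprint, anchor, ang)
                verts = np.array([anchor, end])
                ep = tuple((float(b), float(b + s)) for b, s in zip(bases, slopes))
            else:
                # parallel chords across the footprint, constant intensity
                ang = 0.3 * math.pi  # one shared direction per scene mode
                offset = (fi - (spec.n_fibers_per_cell - 1) / 2.0) * (0.3 * r_cell)
                mid = np.array(anchor) + offset * np.array(
                    [math.cos(ang), -math.sin(ang)])
                e1 = _ray_exit(footprint, tuple(mid), ang + math.pi / 2.0)
                e2 = _ray_exit(footprint, tuple(mid), ang - math.pi / 2.0)
                verts = np.array([e1, e2])
                ep = tuple((float(b), float(b)) for b in bases)
            if np.hypot(*(verts[-1] - verts[0])) < 2.0:
                continue
            fibers.append(FiberTruth(
                fiber_id=len(fibers) + 1, cell_id=ci, vertices=verts,
                endpoint_intensities=ep))
            _stamp_fiber(actin_ch, verts, ep[0][0], ep[0][1])
            _stamp_fiber(fascin_ch, verts, ep[1][0], ep[1][1])

        # -- nucleus ---------------------------------------------------------
        nuc_center = anchor if arc is None else (float(center[0]), float(center[1]))
        sigma_n = (spec.nucleus_radius_um / px) / _HALF_PEAK_SIGMA
        _render_gaussian_spot(nuclei_ch, nuc_center, sigma_n, sigma_n, 0.0,
                              spec.nucleus_peak_intensity)

        cm = ndimage.center_of_mass(footprint)
        cells.append(CellTruth(ci, footprint, (float(cm[0]), float(cm[1])), arc))

    raw = {
        CHANNEL_CONTACT: contact_ch,
        CHANNEL_ACTIN: actin_ch,
        CHANNEL_FASCIN: fascin_ch,
        CHANNEL_NUCLEI: nuclei_ch,
    }
    channels: dict[str, RasterImage] = {}
    for name, arr in raw.items():
        img = arr + spec.background_level
        if apply_noise:
            img = _apply_noise(img, spec, noise_rng)
        channels[name] = RasterImage(img, px, name)

    truth = SyntheticGroundTruth(cells=cells, contacts=contacts, fibers=fibers,
                                 rng_seed=spec.rng_seed, spec=spec)
    return channels, truth


def _ray_exit(footprint: np.ndarray, start: tuple[float, float],
              angle: float) -> np.ndarray:
    """Last footprint point along a ray from ``start`` (row, col)."""
    dr, dc = math.sin(angle), math.cos(angle)
    rows, cols = footprint.shape
    last = np.array(start)
    t = 0.0
    while True:
        t += 1.0
        r = start[0] + t * dr
        c = start[1] + t * dc
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < rows and 0 <= ci < cols) or not footprint[ri, ci]:
            return last
        last = np.array([r, c])


def generate_gradient_fiber_scene(spec: SceneSpec, *, apply_noise: bool = True
                                  ) -> tuple[dict[str, RasterImage], SyntheticGroundTruth]:
    """Stretched-mode scene whose two fiber channels carry opposite linear
    gradients along each fiber's normalized ARC-to-periphery distance."""
    if spec.morphology_mode != "stretched":
        raise ValueError("gradient fiber scenes require morphology_mode='stretched'")
    s0, s1 = spec.gradient_slopes
    if s0 * s1 >= 0:
        raise ValueError(
            f"gradient_slopes must have opposite signs, got {spec.gradient_slopes}")
    spec.validate()  # rejects slopes that make intensities negative
    return generate_scene(spec, apply_noise=apply_noise)


def generate_group(spec_control: SceneSpec, spec_test: SceneSpec,
                   n_scenes_per_group: int, rng_seed: int,
                   *, apply_noise: bool = True):
    """Generate paired control/test scene lists with reproducibly derived seeds.

    The two specs are expected to differ only in their contact count/area
    laws (the knockdown phenotype); any other difference triggers a warning.
    """
    if n_scenes_per_group < 2:
        raise ValueError("n_scenes_per_group must be >= 2 for group statistics")
    allowed = {"fa_count_law", "fa_area_law_um2", "rng_seed"}
    for f in dataclasses.fields(SceneSpec):
        if f.name in allowed:
            continue
        if getattr(spec_control, f.name) != getattr(spec_test, f.name):
            warnings.warn(
                f"control and test specs differ in {f.name!r}; groups are meant "
                "to differ only in contact count/area laws", stacklevel=2)
    children = np.random.SeedSequence(rng_seed).spawn(2 * n_scenes_per_group)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    control = [generate_scene(dataclasses.replace(spec_control, rng_seed=s),
                              apply_noise=apply_noise)
               for s in seeds[:n_scenes_per_group]]
    test = [generate_scene(dataclasses.replace(spec_test, rng_seed=s),
                           apply_noise=apply_noise)
            for s in seeds[n_scenes_per_group:]]
    return control, test


def generate_nuclei_field(spec: SceneSpec, n_nuclei: int, rng_seed: int,
                          *, apply_noise: bool = True,
                          min_separation_factor: float = 3.0
                          ) -> tuple[RasterImage, np.ndarray]:
    """A field of well-separated nucleus blobs for adherent-cell counting.

    Returns the nuclei channel and the (n, 2) array of true centers.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    ss = np.random.SeedSequence(rng_seed)
    geom_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    shape = tuple(spec.image_size)
    px = spec.pixel_size_um
    rad_px = spec.nucleus_radius_um / px
    min_sep = min_separation_factor * rad_px
    margin = 1.5 * rad_px
    if n_nuclei > 0 and 2.0 * margin >= min(shape):
        raise SceneOvercrowdedError(
            f"nuclei of radius {spec.nucleus_radius_um} µm do not fit in "
            f"image {shape}")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 500 * max(1, n_nuclei):
            raise SceneOvercrowdedError(
                f"scene overcrowded: placed {len(centers)}/{n_nuclei} nuclei")
        cand = np.array([geom_rng.uniform(margin, shape[0] - margin),
                         geom_rng.uniform(margin, shape[1] - margin)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    canvas = np.zeros(shape, dtype=np.float64)
    sigma = rad_px / _HALF_PEAK_SIGMA
    for c in centers:
        _render_gaussian_spot(canvas, tuple(c), sigma, sigma, 0.0,
                              spec.nucleus_peak_intensity)
    img = canvas + spec.background_level
    if apply_noise:
        img = _apply_noise(img, spec, noise_rng)
    pts = np.array(centers).reshape(-1, 2)
    return RasterImage(img, px, CHANNEL_NUCLEI), pts


# --- truth rasterization (oracle mode) ---------------------------------------


def truth_contact_label_map(truth: SyntheticGroundTruth) -> LabelMap:
    """Rasterize every true contact's half-peak ellipse as a label map.

    Later contacts overwrite earlier ones where ellipses touch (rare by
    construction); labels are re-packed to 1..n.
    """
    shape = tuple(truth.spec.image_size)
    px = truth.spec.pixel_size_um
    lab = np.zeros(shape, dtype=np.int32)
    for ct in truth.contacts:
        rr, cc = skdraw.ellipse(
            ct.center[0], ct.center[1],
            ct.semi_minor_um / px, ct.semi_major_um / px,
            shape=shape, rotation=ct.orientation_rad)
        lab[rr, cc] = ct.contact_id
    return _repack(lab)


def truth_cell_label_map(truth: SyntheticGroundTruth) -> LabelMap:
    shape = tuple(truth.spec.image_size)
    lab = np.zeros(shape, dtype=np.int32)
    for cell in truth.cells:
        lab[cell.footprint] = cell.cell_id
    return LabelMap(lab)


def _repack(lab: np.ndarray) -> LabelMap:
    out = np.zeros_like(lab)
    for new, old in enumerate(np.unique(lab[lab > 0]), start=1):
        out[lab == old] = new
    return LabelMap(out)


# --- study-condition presets -------------------------------------------------


def control_spec(**overrides) -> SceneSpec:
    """Control-transfected stretched podocyte: ~196 ± 15 contacts of
    1.48 ± 0.30 µm² per cell."""
    base = dict(fa_count_law=(196.0, 15.0), fa_area_law_um2=(1.48, 0.30))
    base.update(overrides)
    return SceneSpec(**base)


def knockdown_spec(**overrides) -> SceneSpec:
    """Fascin-1 knockdown stretched podocyte: ~125 ± 12 contacts of
    1.19 ± 0.25 µm² per cell."""
    base = dict(fa_count_law=(125.0, 12.0), fa_area_law_um2=(1.19, 0.25))
    base.update(overrides)
    return SceneSpec(**base)


# --- on-disk scene format ----------------------------------------------------


def write_scene(channels: dict[str, RasterImage], truth: SyntheticGroundTruth,
                out_dir: str | Path) -> None:
    """Write channels as 16-bit TIFFs plus truth tables (CSV) and a JSON
    sidecar holding the full spec and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, img in channels.items():
        write_image(img, out / f"{name.replace('/', '_')}.tiff")
    write_label_map(truth_cell_label_map(truth), out / "cells_labels.tiff")

    import pandas as pd
    pd.DataFrame([{
        "contact_id": c.contact_id, "cell_id": c.cell_id,
        "center_row": c.center[0], "center_col": c.center[1],
        "semi_major_um": c.semi_major_um, "semi_minor_um": c.semi_minor_um,
        "orientation_rad": c.orientation_rad, "peak_intensity": c.peak_intensity,
        "area_um2": c.area_um2,
    } for c in truth.contacts]).to_csv(out / "truth_contacts.csv", index=False)
    pd.DataFrame([{
        "cell_id": c.cell_id, "centroid_row": c.centroid[0],
        "centroid_col": c.centroid[1],
        "arc_row": (c.arc[0] if c.arc else float("nan")),
        "arc_col": (c.arc[1] if c.arc else float("nan")),
    } for c in truth.cells]).to_csv(out / "truth_cells.csv", index=False)
    rows = []
    for f in truth.fibers:
        for vi, (r, c) in enumerate(f.vertices):
            rows.append({"fiber_id": f.fiber_id, "cell_id": f.cell_id,
                         "vertex_index": vi, "row": r, "col": c})
    pd.DataFrame(rows, columns=["fiber_id", "cell_id", "vertex_index",
                                "row", "col"]).to_csv(
        out / "truth_fibers.csv", index=False)
    spec_dict = dataclasses.asdict(truth.spec)
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in spec_dict.items()}
    write_json({"spec": spec_dict, "rng_seed": truth.rng_seed},
               out / "scene.json")
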