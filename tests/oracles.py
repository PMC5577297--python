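"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (per-pixel loops,
explicit enumeration) and shares no code with the package implementation
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]


def brute_local_stats(pixels: np.ndarray, radius: int):
    """Per-pixel mean/sd over a circular window with symmetric padding."""
    padded = np.pad(pixels.astype(np.float64), radius, mode="symmetric")
    rows, cols = pixels.shape
    offs = disk_offsets(radius)
    mean = np.empty((rows, cols))
    sd = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            vals = [padded[r + radius + dr, c + radius + dc] for dr, dc in offs]
            vals = np.array(vals)
            mean[r, c] = vals.mean()
            sd[r, c] = math.sqrt(max(0.0, (vals ** 2).mean() - vals.mean() ** 2))
    return mean, sd


def brute_sobel_magnitude(pixels: np.ndarray) -> np.ndarray:
    """Sobel magnitude via explicit 3x3 correlation, symmetric padding."""
    kr = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)
    kc = kr.T
    padded = np.pad(pixels.astype(np.float64), 1, mode="symmetric")
    rows, cols = pixels.shape
    gr = np.empty((rows, cols))
    gc = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            patch = padded[r:r + 3, c:c + 3]
            gr[r, c] = (patch * kr).sum()
            gc[r, c] = (patch * kc).sum()
    return np.hypot(gr, gc)


def brute_connected_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labelling; labels in raster-scan discovery order."""
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    current = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and mask[nr, nc] and labels[nr, nc] == 0):
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels


def brute_local_gradient_threshold(pixels: np.ndarray, window_radius: int,
                                   k: float, seed_percentile: float,
                                   connectivity: int) -> np.ndarray:
    """Reference for the gradient-seeded adaptive threshold: boolean mask."""
    mean, sd = brute_local_stats(pixels, window_radius)
    above = pixels.astype(np.float64) > mean + k * sd
    grad = brute_sobel_magnitude(pixels)
    seeds = grad > np.percentile(grad, seed_percentile)
    labels = brute_connected_components(above, connectivity)
    keep = np.zeros_like(above)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if (comp & seeds).any():
            keep |= comp
    return keep


def brute_specificity_mask(pixels: np.ndarray, fg: np.ndarray,
                           connectivity: int, core_erosion: int,
                           ring_width: int, ratio_min: float,
                           min_area: int) -> np.ndarray:
    """Reference for the center/periphery specificity filter: retained mask."""
    labels = brute_connected_components(fg, connectivity)
    core_offs = disk_offsets(core_erosion)
    ring_offs = disk_offsets(ring_width)
    rows, cols = fg.shape
    out = np.zeros_like(fg)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() < min_area:
            continue
        core_vals = []
        for r, c in np.argwhere(comp):
            inside = all(0 <= r + dr < rows and 0 <= c + dc < cols
                         and comp[r + dr, c + dc] for dr, dc in core_offs)
            if inside:
                core_vals.append(pixels[r, c])
        center = (np.mean(core_vals) if core_vals
                  else pixels[comp].astype(np.float64).mean())
        ring = np.zeros_like(fg)
        for r, c in np.argwhere(comp):
            for dr, dc in ring_offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and not fg[nr, nc]:
                    ring[nr, nc] = True
        if not ring.any() or pixels[ring].astype(np.float64).mean() == 0.0:
            ratio = math.inf
        else:
            ratio = center / pixels[ring].astype(np.float64).mean()
        if ratio >= ratio_min:
            out |= comp
    return out


def brute_moments(coords: np.ndarray):
    """Area, centroid, equivalent-ellipse axes (full lengths), eccentricity
    and orientation (from +col axis, y-up) from raw pixel coordinates."""
    r = coords[:, 0].astype(np.float64)
    c = coords[:, 1].astype(np.float64)
    n = len(r)
    rbar, cbar = r.mean(), c.mean()
    mu_rr = ((r - rbar) ** 2).mean()
    mu_cc = ((c - cbar) ** 2).mean()
    mu_rc = ((r - rbar) * (c - cbar)).mean()
    cov = np.array([[mu_rr, mu_rc], [mu_rc, mu_cc]])
    eigvals = np.linalg.eigvalsh(cov)
    lam_min, lam_max = float(eigvals[0]), float(eigvals[1])
    major = 4.0 * math.sqrt(max(lam_max, 0.0))
    minor = 4.0 * math.sqrt(max(lam_min, 0.0))
    ecc = math.sqrt(1.0 - lam_min / lam_max) if lam_max > 0 else 0.0
    theta = 0.5 * math.atan2(-2.0 * mu_rc, mu_cc - mu_rr)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return {"area_px": n, "centroid": (rbar, cbar), "major_px": major,
            "minor_px": minor, "eccentricity": ecc, "orientation": theta}


def brute_min_distance_to_outside(region: np.ndarray, point: tuple[int, int]) -> float:
    """Exhaustive min Euclidean distance from ``point`` to any non-region pixel."""
    best = math.inf
    rows, cols = region.shape
    pr, pc = point
    for r in range(rows):
        for c in range(cols):
            if not region[r, c]:
                best = min(best, math.hypot(r - pr, c - pc))
    return best


def brute_mwu_exact(a, b):
    """Exact two-sided Mann-Whitney p by direct enumeration over index splits."""
    a = list(map(float, a))
    b = list(map(float, b))
    combined = a + b
    n_a, n = len(a), len(a) + len(b)

    def midranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    ranks = midranks(combined)

    def u_min(idx_a):
        ra = sum(ranks[i] for i in idx_a)
        ua = ra - n_a * (n_a + 1) / 2.0
        return min(ua, n_a * (n - n_a) - ua)

    u_obs = u_min(range(n_a))
    hits = total = 0
    for subset in itertools.combinations(range(n), n_a):
        total += 1
        if u_min(subset) <= u_obs + 1e-9:
            hits += 1
    return u_obs, hits / total


def brute_pooled_t(a, b):
    """Pooled-variance two-sample t statistic by the textbook formula."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, na + nb - 2


def flood_fill_half_max(pixels: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected flood fill of the region above half the seed's blob maximum."""
    level = pixels.max() / 2.0
    mask = pixels >= level
    labels = brute_connected_components(mask, 8)
    lab = labels[seed]
    return labels == lab
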