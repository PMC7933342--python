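"""Brute-force reference implementations used as independent test oracles.

Everything here is written with explicit enumeration (loops, BFS, exhaustive
search) so it shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from skimage.morphology import skeletonize


# ---------------------------------------------------------------------------
# Grayscale morphology / filtering
# ---------------------------------------------------------------------------

def _reflect_index(i: int, n: int) -> int:
    # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def ball_offsets(radius: float):
    r = int(math.floor(radius))
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offs.append((dy, dx, math.sqrt(radius * radius - d2)))
    return offs


def gray_opening_ball(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a non-flat ball element, reflect borders."""
    offs = ball_offsets(radius)
    h, w = img.shape
    ero = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            ero[y, x] = min(
                img[_reflect_index(y + dy, h), _reflect_index(x + dx, w)] - hgt
                for dy, dx, hgt in offs
            )
    out = np.empty_like(ero)
    for y in range(h):
        for x in range(w):
            out[y, x] = max(
                ero[_reflect_index(y - dy, h), _reflect_index(x - dx, w)] + hgt
                for dy, dx, hgt in offs
            )
    return out


def median_disc(img: np.ndarray, radius: int) -> np.ndarray:
    """Disc median filter by explicit neighbourhood sorting, reflect borders."""
    h, w = img.shape
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = sorted(
                img[_reflect_index(y + dy, h), _reflect_index(x + dx, w)]
                for dy, dx in offs
            )
            n = len(vals)
            out[y, x] = (
                vals[n // 2] if n % 2 == 1 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            )
    return out


def otsu_threshold(values: np.ndarray, candidates: np.ndarray) -> float:
    """Threshold maximizing between-class variance, by exhaustive search."""
    best_t, best_v = candidates[0], -1.0
    values = values.ravel()
    for t in candidates:
        lo = values[values <= t]
        hi = values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS component labeling; connectivity 4/8 in 2D, 6/26 in 3D."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        if connectivity == 4:
            neigh = [(0, 1), (0, -1), (1, 0), (-1, 0)]
        else:
            neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dy, dx) != (0, 0)]
    else:
        if connectivity == 6:
            neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                     (0, 0, 1), (0, 0, -1)]
        else:
            neigh = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                     for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            p = queue.popleft()
            for off in neigh:
                q = tuple(pi + oi for pi, oi in zip(p, off))
                if all(0 <= qi < si for qi, si in zip(q, mask.shape)):
                    if mask[q] and not labels[q]:
                        labels[q] = current
                        queue.append(q)
    return labels


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

# 4-direction Crofton coefficients for the 16 two-by-two pixel configurations
_CROFTON4 = [
    0.0,
    math.pi / 4 * (1 + 1 / math.sqrt(2)),
    math.pi / (4 * math.sqrt(2)),
    math.pi / (2 * math.sqrt(2)),
    0.0,
    math.pi / 4 * (1 + 1 / math.sqrt(2)),
    0.0,
    math.pi / (4 * math.sqrt(2)),
    math.pi / 4,
    math.pi / 2,
    math.pi / (4 * math.sqrt(2)),
    math.pi / (4 * math.sqrt(2)),
    math.pi / 4,
    math.pi / 2,
    0.0,
    0.0,
]


def crofton_perimeter(mask: np.ndarray) -> float:
    """4-direction Crofton perimeter by explicit 2×2 window enumeration.

    Configuration code: bit 0 = (y, x), bit 1 = (y+1, x), bit 2 = (y, x+1),
    bit 3 = (y+1, x+1), scanned over the zero-padded image.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    h, w = padded.shape
    total = 0.0
    for y in range(h):
        for x in range(w):
            code = 0
            if padded[y, x]:
                code |= 1
            if y + 1 < h and padded[y + 1, x]:
                code |= 2
            if x + 1 < w and padded[y, x + 1]:
                code |= 4
            if y + 1 < h and x + 1 < w and padded[y + 1, x + 1]:
                code |= 8
            total += _CROFTON4[code]
    return total


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull; returns vertices in order."""
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) <= 2:
        return np.array(pts, dtype=float)
    start = min(pts)  # lowest row, then col
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross > 1e-12 or (
                abs(cross) <= 1e-12
                and (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
                > (candidate[0] - current[0]) ** 2
                + (candidate[1] - current[1]) ** 2
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return np.array(hull, dtype=float)


def polygon_area(vertices: np.ndarray) -> float:
    a = 0.0
    n = len(vertices)
    for i in range(n):
        y0, x0 = vertices[i]
        y1, x1 = vertices[(i + 1) % n]
        a += x0 * y1 - x1 * y0
    return abs(a) / 2.0


def polygon_perimeter(vertices: np.ndarray) -> float:
    p = 0.0
    n = len(vertices)
    for i in range(n):
        d = vertices[(i + 1) % n] - vertices[i]
        p += math.hypot(d[0], d[1])
    return p


def feret_max_bruteforce(points: np.ndarray) -> float:
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = points[i] - points[j]
            best = max(best, float(d @ d))
    return math.sqrt(best)


def feret_min_width(hull: np.ndarray) -> float:
    """Minimal caliper width: extent normal to each hull edge."""
    if len(hull) <= 2:
        return 0.0
    best = math.inf
    n = len(hull)
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        norm = math.hypot(e[0], e[1])
        if norm == 0:
            continue
        nvec = np.array([-e[1], e[0]]) / norm
        proj = hull @ nvec
        best = min(best, float(proj.max() - proj.min()))
    return best


def ellipse_closed_form(coords: np.ndarray):
    """2×2 covariance eigen-solution in closed form.

    Returns (major_len_px, minor_len_px, angle_deg, eccentricity) with the
    same moment conventions as the package (pixel-centre covariance plus the
    1/12 unit-square term, axis length 4·sqrt(eigenvalue)).
    """
    coords = np.asarray(coords, dtype=float)
    mr, mc = coords.mean(axis=0)
    srr = ((coords[:, 0] - mr) ** 2).mean() + 1 / 12
    scc = ((coords[:, 1] - mc) ** 2).mean() + 1 / 12
    src = ((coords[:, 0] - mr) * (coords[:, 1] - mc)).mean()
    tr, det = srr + scc, srr * scc - src * src
    disc = math.sqrt(max(0.0, tr * tr / 4 - det))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc  # major, minor
    if abs(src) > 1e-15:
        vr, vc = lam1 - scc, src
    elif srr >= scc:
        vr, vc = 1.0, 0.0
    else:
        vr, vc = 0.0, 1.0
    angle = math.degrees(math.atan2(-vr, vc)) % 180.0
    return (
        4 * math.sqrt(lam1),
        4 * math.sqrt(lam2),
        angle,
        math.sqrt(max(0.0, 1 - lam2 / lam1)),
    )


def bfs_skeleton_stats(mask: np.ndarray):
    """Branch/end points and length of the topological skeleton, by explicit
    neighbour enumeration (shares only the skeletonization primitive)."""
    skel = skeletonize(mask)
    if not skel.any():
        coords = np.argwhere(mask)
        centre = coords.mean(axis=0)
        k = int(np.argmin(((coords - centre) ** 2).sum(axis=1)))
        skel = np.zeros_like(mask)
        skel[tuple(coords[k])] = True
    pix = set(map(tuple, np.argwhere(skel)))
    n_branch = n_end = 0
    length = 0.0
    for (y, x) in pix:
        deg = 0
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) == (0, 0):
                    continue
                if (y + dy, x + dx) in pix:
                    deg += 1
                    if (dy, dx) in ((0, 1), (1, 0), (1, 1), (1, -1)):
                        length += math.hypot(dy, dx)
        if deg >= 3:
            n_branch += 1
        elif deg == 1:
            n_end += 1
    return skel, length, n_branch, n_end


def count_holes_bfs(mask: np.ndarray) -> int:
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    labels = flood_fill_components(~padded, connectivity=4)
    border = set()
    h, w = labels.shape
    for y in range(h):
        for x in range(w):
            if (y in (0, h - 1) or x in (0, w - 1)) and labels[y, x]:
                border.add(labels[y, x])
    return int(labels.max() - len(border))


def exact_edt(mask: np.ndarray) -> np.ndarray:
    """Distance of each foreground pixel to the nearest background pixel,
    by exhaustive search over the padded bounding box."""
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=float)
    for p in np.argwhere(padded):
        d2 = ((bg - p) ** 2).sum(axis=1)
        out[tuple(p)] = math.sqrt(float(d2.min()))
    return out[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# Full 2D descriptor oracle
# ---------------------------------------------------------------------------

def oracle_measure_2d(mask: np.ndarray, s: float) -> dict[str, float]:
    """All 32 descriptors from primitive enumeration, same definitions as
    the package's documented conventions."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    n = len(coords)
    area = n * s * s
    perim = crofton_perimeter(mask) * s

    corners = set()
    for (y, x) in coords:
        for dy in (-0.5, 0.5):
            for dx in (-0.5, 0.5):
                corners.add((y + dy, x + dx))
    corners = np.array(sorted(corners))
    hull = gift_wrap_hull(corners)
    convex_area = polygon_area(hull) * s * s
    convex_perim = polygon_perimeter(hull) * s

    major_px, minor_px, ell_angle, ecc = ellipse_closed_form(coords)
    major, minor = major_px * s, minor_px * s

    fmax = feret_max_bruteforce(hull if len(hull) > 2 else corners) * s
    fmin = feret_min_width(hull) * s

    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    bbox_h, bbox_w = (rmax - rmin + 1) * s, (cmax - cmin + 1) * s

    eq_diam = math.sqrt(4 * area / math.pi)
    skel, skel_len_px, n_branch, n_end = bfs_skeleton_stats(mask)
    edt = exact_edt(mask)
    tvals = [edt[p] for p in map(tuple, np.argwhere(skel))]
    centred = coords - coords.mean(axis=0)

    skel_len = skel_len_px * s
    return {
        "area_um2": area,
        "perimeter_um": perim,
        "convex_area_um2": convex_area,
        "convex_perimeter_um": convex_perim,
        "solidity": min(1.0, area / convex_area),
        "convexity": min(1.0, convex_perim / perim),
        "circularity": min(1.0, 4 * math.pi * area / perim**2),
        "roundness": min(1.0, 4 * area / (math.pi * major**2)),
        "aspect_ratio": major / minor,
        "major_axis_um": major,
        "minor_axis_um": minor,
        "ellipse_angle_deg": ell_angle,
        "feret_max_um": fmax,
        "feret_min_um": fmin,
        "equivalent_diameter_um": eq_diam,
        "extent": area / (bbox_h * bbox_w),
        "bbox_width_um": bbox_w,
        "bbox_height_um": bbox_h,
        "compactness": eq_diam / fmax,
        "eccentricity": ecc,
        "interfacial_density_per_um": perim / area,
        "skeleton_length_um": skel_len,
        "n_branch_points": float(n_branch),
        "n_end_points": float(n_end),
        "n_holes": float(count_holes_bfs(mask)),
        "mean_thickness_um": 2 * float(np.mean(tvals)) * s,
        "max_thickness_um": 2 * float(np.max(tvals)) * s,
        "elongation": 1 - minor / major,
        "radius_of_gyration_um": math.sqrt(float((centred**2).sum(axis=1).mean())) * s,
        "feret_circularity": min(1.0, 4 * area / (math.pi * fmax**2)),
        "branch_density_per_um": n_branch / skel_len if skel_len > 0 else 0.0,
    }


def random_blob(rng: np.random.Generator, max_pixels: int = 200) -> np.ndarray:
    """Random 8-connected pixel blob grown by biased accretion."""
    n_target = int(rng.integers(3, max_pixels + 1))
    pix = {(0, 0)}
    frontier = [(0, 0)]
    while len(pix) < n_target and frontier:
        y, x = frontier[int(rng.integers(0, len(frontier)))]
        dy, dx = [(0, 1), (0, -1), (1, 0), (-1, 0)][int(rng.integers(0, 4))]
        p = (y + dy, x + dx)
        if p not in pix:
            pix.add(p)
            frontier.append(p)
    coords = np.array(sorted(pix))
    coords -= coords.min(axis=0)
    mask = np.zeros(coords.max(axis=0) + 1, dtype=bool)
    mask[tuple(coords.T)] = True
    return mask
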