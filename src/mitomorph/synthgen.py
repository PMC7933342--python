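"""Synthetic fluorescence-microscopy data with ground-truth morphology labels.

Generates 2D micrograph-like images and 3D stack-like volumes containing
objects of the four mitochondrial morphology classes:

* **network** — branched trees of tubes, area >= 5 µm² (2D) or volume
  >= 1.2 µm³ (3D), always containing at least one skeleton branch point in 2D;
* **unbranched** — single tubes of uniform thickness (width 0.3–0.5 µm),
  area 1–4 µm², aspect ratio >= 2, no branch point;
* **swollen** — near-circular ellipses (axis ratio <= 1.35), area 1–4 µm²,
  roundness >= 0.7;
* **punctate** — small discs, area 0.3–1 µm² (the lower bound keeps them
  above the 0.30 µm² particle-size filter).

Rendered images follow a standard fluorescence model: per-object signal,
Gaussian PSF blur, constant background plus a linear gradient, Poisson shot
noise and additive Gaussian read noise.  Electron-microscopy-like volumes
invert the contrast (dark objects on a bright background).  All outputs are
bit-reproducible given the seed carried in the generation settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .descriptors import (
    DESCRIPTOR_NAMES_2D,
    DESCRIPTOR_NAMES_3D,
    measure_mask_2d,
    measure_voxels_3d,
    skeleton_stats,
    _ellipse_fit,
)


class MorphologyClass(str, Enum):
    """The four mitochondrial morphology phenotypes."""

    NETWORK = "network"
    UNBRANCHED = "unbranched"
    SWOLLEN = "swollen"
    PUNCTATE = "punctate"


#: Canonical class order used for stratification, vote tie-breaks and reports.
CLASS_ORDER = (
    MorphologyClass.NETWORK,
    MorphologyClass.UNBRANCHED,
    MorphologyClass.SWOLLEN,
    MorphologyClass.PUNCTATE,
)
CLASS_NAMES = tuple(c.value for c in CLASS_ORDER)


class CapacityError(RuntimeError):
    """Raised when objects cannot be placed into the requested image."""


def _as_class(cls) -> MorphologyClass:
    try:
        return MorphologyClass(cls)
    except ValueError as exc:
        raise ValueError(
            f"unknown morphology class {cls!r}; expected one of {CLASS_NAMES}"
        ) from exc


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec2D:
    """Conditions for a synthetic 2D widefield-like micrograph."""

    n_per_class: int = 5
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (768, 768)
    psf_sigma_px: float = 1.0
    background_level: float = 20.0
    gradient_amplitude: float = 10.0
    poisson_scale: float = 1.0
    gaussian_noise_sd: float = 2.0
    min_object_gap_px: int = 3
    seed: int = 0
    #: peak object signal above background, in intensity units
    signal_amplitude: float = 100.0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small")
        for name in ("psf_sigma_px", "background_level", "gradient_amplitude",
                     "poisson_scale", "gaussian_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_object_gap_px < 1:
            raise ValueError("min_object_gap_px must be >= 1")


@dataclass
class SynthSpec3D(SynthSpec2D):
    """Conditions for a synthetic 3D confocal- or EM-like stack."""

    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)  # (x, y, z)
    n_slices: int = 50
    modality: str = "confocal"
    n_per_class: int = 3
    image_shape: tuple[int, int] = (384, 384)

    def validate(self) -> None:
        super().validate()
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel dimensions must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.modality not in ("confocal", "em"):
            raise ValueError("modality must be 'confocal' or 'em'")


@dataclass
class GroundTruth:
    """Label image (0 = background) plus the class of every label."""

    label_map: np.ndarray
    class_of_label: dict[int, MorphologyClass] = field(default_factory=dict)

    def validate(self) -> None:
        labels = np.unique(self.label_map)
        labels = labels[labels > 0]
        expected = np.arange(1, len(labels) + 1)
        if not np.array_equal(labels, expected):
            raise ValueError("labels must be consecutive positive integers")
        missing = [int(l) for l in labels if int(l) not in self.class_of_label]
        if missing:
            raise ValueError(f"labels without a class: {missing}")


# ---------------------------------------------------------------------------
# 2D object geometry
# ---------------------------------------------------------------------------

def _rasterize_capsules(segments, radius_um, pixel_size_um):
    """Union of thick line segments ('capsules'); coordinates in µm."""
    s = pixel_size_um
    pts = np.concatenate([np.asarray(seg) for seg in segments])
    lo = pts.min(axis=0) - radius_um - 2 * s
    hi = pts.max(axis=0) + radius_um + 2 * s
    shape = np.maximum(np.ceil((hi - lo) / s).astype(int), 1)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    centres = np.stack([(rr + 0.5) * s + lo[0], (cc + 0.5) * s + lo[1]], axis=-1)
    mask = np.zeros(tuple(shape), dtype=bool)
    for p, q in segments:
        p, q = np.asarray(p, float), np.asarray(q, float)
        pq = q - p
        denom = float(pq @ pq)
        rel = centres - p
        if denom == 0:
            d2 = (rel**2).sum(axis=-1)
        else:
            t = np.clip((rel @ pq) / denom, 0.0, 1.0)
            d2 = ((rel - t[..., None] * pq) ** 2).sum(axis=-1)
        mask |= d2 <= radius_um**2
    return _crop(mask)


def _rasterize_ellipse(a_um, b_um, angle, pixel_size_um):
    s = pixel_size_um
    half = max(a_um, b_um) + 2 * s
    n = int(np.ceil(2 * half / s))
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    y = (rr + 0.5) * s - half
    x = (cc + 0.5) * s - half
    ct, st = np.cos(angle), np.sin(angle)
    u = x * ct + y * st
    v = -x * st + y * ct
    mask = (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0
    return _crop(mask)


def _crop(mask):
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return mask[tuple(slice(a, b) for a, b in zip(lo, hi))]


def _make_punctate(rng, s):
    # fission fragments sit low in the <= 1 µm² class: small discs also keep
    # the perimeter-to-area ratio (2/r) clearly above that of network tubes
    area = rng.uniform(0.32, 0.70)
    r = np.sqrt(area / np.pi)
    return _rasterize_ellipse(r, r, 0.0, s)


def _make_swollen(rng, s):
    area = rng.uniform(1.2, 3.7)
    q = rng.uniform(1.02, 1.35)  # major/minor axis ratio, keeps roundness >= 0.7
    a = np.sqrt(area * q / np.pi)
    b = a / q
    return _rasterize_ellipse(a, b, rng.uniform(0, np.pi), s)


def _make_unbranched(rng, s):
    width = rng.uniform(0.30, 0.50)
    area = rng.uniform(1.3, min(3.7, 7.0 * width))
    length = area / width
    theta = rng.uniform(0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    bend = rng.uniform(-0.08, 0.08) * length  # gentle curvature
    p0 = np.zeros(2)
    p1 = 0.5 * length * d + bend * perp
    p2 = length * d
    return _rasterize_capsules([(p0, p1), (p1, p2)], width / 2.0, s)


def _make_network(rng, s):
    width = rng.uniform(0.35, 0.50)
    target_area = rng.uniform(5.3, 7.5)
    n_seg = int(rng.integers(3, 6))
    seg_len = target_area / width / n_seg
    theta = rng.uniform(0, 2 * np.pi)

    def unit(a):
        return np.array([np.cos(a), np.sin(a)])

    p0 = np.zeros(2)
    trunk_end = p0 + seg_len * unit(theta)
    segments = [(p0, trunk_end)]
    # two children from the trunk end guarantee a degree-3 junction
    for sign in (1.0, -1.0):
        a = theta + sign * rng.uniform(0.5, 1.2)
        segments.append((trunk_end, trunk_end + seg_len * unit(a)))
    # optional extra segments extend existing tips
    while len(segments) < n_seg:
        base = segments[int(rng.integers(1, len(segments)))][1]
        a = rng.uniform(0, 2 * np.pi)
        segments.append((base, base + seg_len * unit(a)))
    return _rasterize_capsules(segments, width / 2.0, s)


def _generate_object_2d(cls: MorphologyClass, pixel_size_um: float, rng) -> np.ndarray:
    """Draw one object and verify its class-defining geometry (with retries)."""
    s = pixel_size_um
    for _ in range(40):
        if cls is MorphologyClass.PUNCTATE:
            mask = _make_punctate(rng, s)
            if 0.28 <= mask.sum() * s * s <= 1.0:
                return mask
        elif cls is MorphologyClass.SWOLLEN:
            mask = _make_swollen(rng, s)
            area = mask.sum() * s * s
            major, minor, _, _ = _ellipse_fit(np.argwhere(mask).astype(float))
            roundness = 4.0 * mask.sum() / (np.pi * major**2)
            if 1.0 <= area <= 4.0 and roundness >= 0.70:
                return mask
        elif cls is MorphologyClass.UNBRANCHED:
            mask = _make_unbranched(rng, s)
            area = mask.sum() * s * s
            _, _, n_branch, _ = skeleton_stats(mask)
            major, minor, _, _ = _ellipse_fit(np.argwhere(mask).astype(float))
            if 1.0 <= area <= 4.0 and n_branch == 0 and major / minor >= 2.0:
                return mask
        else:  # network
            mask = _make_network(rng, s)
            area = mask.sum() * s * s
            _, _, n_branch, _ = skeleton_stats(mask)
            if area >= 5.0 and n_branch >= 1:
                return mask
    raise RuntimeError(f"could not draw a valid {cls.value} object")


def make_object_geometry(cls, pixel_size_um: float, rng_seed: int) -> np.ndarray:
    """Binary mask (tight crop) of one object of the given morphology class."""
    cls = _as_class(cls)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    rng = np.random.default_rng(rng_seed)
    return _generate_object_2d(cls, pixel_size_um, rng)


# ---------------------------------------------------------------------------
# 3D object geometry
# ---------------------------------------------------------------------------

def _rasterize_3d(predicate, lo, hi, voxel_size_um):
    vx, vy, vz = voxel_size_um
    steps = np.array([vz, vy, vx])
    shape = np.maximum(np.ceil((hi - lo) / steps).astype(int), 1)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack(
        [
            (zz + 0.5) * vz + lo[0],
            (yy + 0.5) * vy + lo[1],
            (xx + 0.5) * vx + lo[2],
        ],
        axis=-1,
    )
    mask = predicate(pts)
    if not mask.any():
        raise RuntimeError("degenerate 3D rasterization")
    return _crop(mask)


def _capsules_3d(segments, radius_um, voxel_size_um):
    pts = np.concatenate([np.asarray(seg) for seg in segments])
    margin = radius_um + 2 * max(voxel_size_um)
    lo, hi = pts.min(axis=0) - margin, pts.max(axis=0) + margin

    def pred(grid):
        out = np.zeros(grid.shape[:-1], dtype=bool)
        for p, q in segments:
            p, q = np.asarray(p, float), np.asarray(q, float)
            pq = q - p
            denom = float(pq @ pq)
            rel = grid - p
            if denom == 0:
                d2 = (rel**2).sum(axis=-1)
            else:
                t = np.clip((rel @ pq) / denom, 0.0, 1.0)
                d2 = ((rel - t[..., None] * pq) ** 2).sum(axis=-1)
            out |= d2 <= radius_um**2
        return out

    return _rasterize_3d(pred, lo, hi, voxel_size_um)


def _ellipsoid_3d(semi_axes_um, voxel_size_um):
    a = np.asarray(semi_axes_um, float)  # (z, y, x) semi-axes
    margin = 2 * max(voxel_size_um)
    lo, hi = -a - margin, a + margin

    def pred(grid):
        return ((grid / a) ** 2).sum(axis=-1) <= 1.0

    return _rasterize_3d(pred, lo, hi, voxel_size_um)


def _generate_object_3d(cls: MorphologyClass, voxel_size_um, rng) -> np.ndarray:
    """One 3D object; coordinates (z, y, x), voxel_size_um given as (x, y, z)."""
    vol_per_voxel = float(np.prod(voxel_size_um))
    for _ in range(40):
        if cls is MorphologyClass.PUNCTATE:
            r = rng.uniform(0.25, 0.32)
            mask = _ellipsoid_3d((r, r, r), voxel_size_um)
            if mask.sum() * vol_per_voxel <= 0.16:
                return mask
        elif cls is MorphologyClass.SWOLLEN:
            vol = rng.uniform(0.4, 1.2)
            q1, q2 = rng.uniform(1.0, 1.18, size=2)
            c = (3.0 * vol / (4.0 * np.pi * q1 * q1 * q2 * q2 * q2)) ** (1 / 3)
            axes = np.array([c, c * q2, c * q1 * q2])
            mask = _ellipsoid_3d(tuple(rng.permutation(axes)), voxel_size_um)
            if 0.3 <= mask.sum() * vol_per_voxel <= 1.5:
                return mask
        elif cls is MorphologyClass.UNBRANCHED:
            r = rng.uniform(0.15, 0.25)
            length = rng.uniform(1.5, 3.0)
            theta = rng.uniform(0, 2 * np.pi)
            dz = rng.uniform(-0.25, 0.25)
            d = np.array([dz, np.sin(theta), np.cos(theta)])
            d /= np.linalg.norm(d)
            mask = _capsules_3d([(np.zeros(3), length * d)], r, voxel_size_um)
            if mask.sum() * vol_per_voxel <= 0.8:
                return mask
        else:  # network: branched tube tree
            r = rng.uniform(0.15, 0.22)
            target_vol = rng.uniform(1.3, 2.2)
            n_seg = int(rng.integers(3, 6))
            seg_len = max(0.8, target_vol / (np.pi * r * r) / n_seg)

            def unit(rng):
                theta = rng.uniform(0, 2 * np.pi)
                dz = rng.uniform(-0.35, 0.35)
                d = np.array([dz, np.sin(theta), np.cos(theta)])
                return d / np.linalg.norm(d)

            p0 = np.zeros(3)
            trunk_end = p0 + seg_len * unit(rng)
            segments = [(p0, trunk_end)]
            for _k in range(2):
                segments.append((trunk_end, trunk_end + seg_len * unit(rng)))
            while len(segments) < n_seg:
                base = segments[int(rng.integers(1, len(segments)))][1]
                segments.append((base, base + seg_len * unit(rng)))
            mask = _capsules_3d(segments, r, voxel_size_um)
            if mask.sum() * vol_per_voxel >= 1.2 and mask.shape[0] * voxel_size_um[2] <= 4.0:
                return mask
    raise RuntimeError(f"could not draw a valid 3D {cls.value} object")


def make_object_geometry_3d(cls, voxel_size_um, rng_seed: int) -> np.ndarray:
    """Binary voxel mask (tight crop, (z, y, x)) of one 3D object."""
    cls = _as_class(cls)
    if any(v <= 0 for v in voxel_size_um):
        raise ValueError("voxel dimensions must be > 0")
    rng = np.random.default_rng(rng_seed)
    return _generate_object_3d(cls, tuple(voxel_size_um), rng)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _place_objects(masks, classes, shape, gap, rng):
    """Place tight masks into a label image with pairwise gap >= ``gap`` px.

    Placement keeps padded bounding boxes disjoint, which guarantees the gap.
    """
    label_map = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    order = np.argsort([-m.sum() for m in masks], kind="stable")  # big first
    for idx in order:
        mask = masks[idx]
        mshape = mask.shape
        if any(m >= s for m, s in zip(mshape, shape)):
            raise CapacityError(
                f"a {classes[idx].value} object of size {mshape} does not fit "
                f"into image of shape {shape}"
            )
        for _ in range(500):
            origin = tuple(
                int(rng.integers(0, s - m + 1)) for s, m in zip(shape, mshape)
            )
            pad_sl = tuple(
                slice(max(0, o - gap), min(s, o + m + gap))
                for o, m, s in zip(origin, mshape, shape)
            )
            if occupied[pad_sl].any():
                continue
            sl = tuple(slice(o, o + m) for o, m in zip(origin, mshape))
            label_map[sl][mask] = idx + 1
            occupied[sl] = True
            break
        else:
            raise CapacityError(
                f"could not place a {classes[idx].value} object after 500 tries; "
                "increase the image size or reduce n_per_class"
            )
    return label_map


def _object_seeds(rng, n):
    return rng.integers(0, 2**31 - 1, size=n)


def _make_scene_masks(spec, rng, make_one):
    masks, classes = [], []
    for cls in CLASS_ORDER:
        for _ in range(spec.n_per_class):
            masks.append(make_one(cls, rng))
            classes.append(cls)
    return masks, classes


def _apply_noise(signal, spec, rng, invert=False):
    shape = signal.shape
    # linear background gradient along a random direction of the last two axes
    rows = np.linspace(0.0, 1.0, shape[-2])[:, None]
    cols = np.linspace(0.0, 1.0, shape[-1])[None, :]
    w = rng.uniform(0.0, 1.0)
    ramp = w * rows + (1.0 - w) * cols
    background = spec.background_level + spec.gradient_amplitude * ramp
    if invert:
        img = background + spec.signal_amplitude - signal
    else:
        img = background + signal
    img = np.maximum(img, 0.0)
    if spec.poisson_scale > 0:
        img = rng.poisson(img * spec.poisson_scale).astype(np.float64) / spec.poisson_scale
    if spec.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=shape)
    return np.maximum(img, 0.0)


def render_image(spec: SynthSpec2D) -> tuple[np.ndarray, GroundTruth]:
    """Render a 2D micrograph; returns (intensity image, ground truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masks, classes = _make_scene_masks(
        spec, rng, lambda cls, r: _generate_object_2d(cls, spec.pixel_size_um, r)
    )
    label_map = _place_objects(masks, classes, spec.image_shape, spec.min_object_gap_px, rng)
    signal = np.zeros(spec.image_shape, dtype=np.float64)
    for lab in range(1, len(masks) + 1):
        amp = spec.signal_amplitude * rng.uniform(0.85, 1.15)
        signal[label_map == lab] = amp
    if spec.psf_sigma_px > 0:
        signal = ndi.gaussian_filter(signal, spec.psf_sigma_px)
    img = _apply_noise(signal, spec, rng)
    truth = GroundTruth(label_map, {i + 1: c for i, c in enumerate(classes)})
    truth.validate()
    return img, truth


def render_volume(spec: SynthSpec3D) -> tuple[np.ndarray, GroundTruth]:
    """Render a 3D stack ((z, y, x)); returns (intensity stack, ground truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masks, classes = _make_scene_masks(
        spec, rng, lambda cls, r: _generate_object_3d(cls, spec.voxel_size_um, r)
    )
    vz = spec.voxel_size_um[2]
    tallest = max(m.shape[0] for m in masks) * vz
    depth_um = spec.n_slices * vz
    if depth_um < tallest:
        raise ValueError(
            f"stack depth {depth_um:.2f} µm cannot hold the tallest object "
            f"({tallest:.2f} µm); increase n_slices"
        )
    shape = (spec.n_slices, *spec.image_shape)
    label_map = _place_objects(masks, classes, shape, spec.min_object_gap_px, rng)
    signal = np.zeros(shape, dtype=np.float64)
    for lab in range(1, len(masks) + 1):
        amp = spec.signal_amplitude * rng.uniform(0.85, 1.15)
        signal[label_map == lab] = amp
    if spec.psf_sigma_px > 0:
        signal = ndi.gaussian_filter(signal, spec.psf_sigma_px)
    img = _apply_noise(signal, spec, rng, invert=(spec.modality == "em"))
    truth = GroundTruth(label_map, {i + 1: c for i, c in enumerate(classes)})
    truth.validate()
    return img, truth


# ---------------------------------------------------------------------------
# Object tables
# ---------------------------------------------------------------------------

def sample_object_table(spec: SynthSpec2D | SynthSpec3D) -> pd.DataFrame:
    """Descriptor table of clean (pre-noise) generated objects.

    One row per object with its true class and the full descriptor suite
    (32 columns for a 2D spec, 8 for a 3D spec), computed directly on the
    noise-free object masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    is_3d = isinstance(spec, SynthSpec3D)
    rows = []
    for cls in CLASS_ORDER:
        for _ in range(spec.n_per_class):
            if is_3d:
                mask = _generate_object_3d(cls, spec.voxel_size_um, rng)
                desc = measure_voxels_3d(mask, spec.voxel_size_um)
            else:
                mask = _generate_object_2d(cls, spec.pixel_size_um, rng)
                desc = measure_mask_2d(mask, spec.pixel_size_um)
            rows.append({"true_class": cls.value, **desc})
    names = DESCRIPTOR_NAMES_3D if is_3d else DESCRIPTOR_NAMES_2D
    return pd.DataFrame(rows, columns=["true_class", *names])
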