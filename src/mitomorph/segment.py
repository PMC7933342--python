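"""Segmentation: pixel classification, thresholding, particle extraction,
morphological erosion and 3D connected-component labeling.

2D particle analysis uses 8-connectivity and discards objects below a
minimum area (default 0.30 µm²); 3D labeling defaults to face-only
(connectivity-6) adjacency.  A trainable random-forest pixel classifier on a
Gaussian-family feature stack (raw intensity, Gaussian smoothings, gradient
magnitudes, Laplacians and difference-of-Gaussians at a fixed sigma ladder)
provides intensity-robust segmentation; Otsu thresholding is available as a
fully automated fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier
from skimage.filters import threshold_otsu

from .preprocess import Image2D

DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0)

#: annotation mask codes for pixel-classifier training
ANNOT_UNLABELED = 0
ANNOT_MITO = 1
ANNOT_BACKGROUND = 2


# ---------------------------------------------------------------------------
# Object containers
# ---------------------------------------------------------------------------

@dataclass
class MitoObject2D:
    """One segmented 2D mitochondrial object."""

    label: int
    pixel_coords: np.ndarray  # (N, 2) array of (row, col)
    pixel_size_um: float
    descriptors: dict | None = None
    true_class: str | None = None
    predicted_class: str | None = None

    @property
    def area_um2(self) -> float:
        return len(self.pixel_coords) * self.pixel_size_um**2

    @property
    def centroid(self) -> tuple[float, float]:
        c = np.asarray(self.pixel_coords).mean(axis=0)
        return float(c[0]), float(c[1])


@dataclass
class MitoObject3D:
    """One segmented 3D mitochondrial object."""

    label: int
    voxel_coords: np.ndarray  # (N, 3) array of (z, row, col)
    voxel_size_um: tuple[float, float, float]  # (x, y, z)
    descriptors: dict | None = None
    true_class: str | None = None
    predicted_class: str | None = None

    @property
    def volume_um3(self) -> float:
        vx, vy, vz = self.voxel_size_um
        return len(self.voxel_coords) * vx * vy * vz


@dataclass
class LabelMap:
    """Integer label image/stack, 0 = background, labels consecutive 1..K."""

    labels: np.ndarray
    scale_um: float | tuple[float, float, float]
    connectivity: int | None = None

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class PixelClassifierModel:
    """Random-forest pixel classifier over a fixed Gaussian feature stack."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    sigmas: tuple[float, ...]
    classes: tuple[str, str] = ("background", "mito")
    training_meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature stack and pixel classification
# ---------------------------------------------------------------------------

def build_feature_stack(
    img: Image2D, sigmas=DEFAULT_SIGMAS
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-pixel feature volume (H, W, F) plus the ordered feature names."""
    sigmas = tuple(float(s) for s in sigmas)
    if not sigmas or any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be non-empty and positive")
    pix = img.pixels
    feats = [pix]
    names = ["raw"]
    smoothed = {}
    for s in sigmas:
        smoothed[s] = ndi.gaussian_filter(pix, s, mode="reflect")
        feats.append(smoothed[s])
        names.append(f"gaussian_{s:g}")
    for s in sigmas:
        feats.append(ndi.gaussian_gradient_magnitude(pix, s, mode="reflect"))
        names.append(f"gradmag_{s:g}")
    for s in sigmas:
        feats.append(ndi.gaussian_laplace(pix, s, mode="reflect"))
        names.append(f"laplacian_{s:g}")
    for s1, s2 in zip(sigmas[:-1], sigmas[1:]):
        feats.append(smoothed[s1] - smoothed[s2])
        names.append(f"dog_{s1:g}_{s2:g}")
    return np.stack(feats, axis=-1), tuple(names)


def train_pixel_classifier(
    images: list[Image2D],
    annotation_masks: list[np.ndarray],
    sigmas=DEFAULT_SIGMAS,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifierModel:
    """Fit the pixel classifier from sparse tri-state annotation masks.

    Annotation masks use 0 = unlabeled, 1 = mito, 2 = background; both
    classes must be represented.
    """
    if len(images) != len(annotation_masks):
        raise ValueError("images and annotation_masks length mismatch")
    X_parts, y_parts = [], []
    names = None
    for im, ann in zip(images, annotation_masks):
        ann = np.asarray(ann)
        if ann.shape != im.pixels.shape:
            raise ValueError("annotation mask shape mismatch")
        stack, names = build_feature_stack(im, sigmas)
        sel = ann != ANNOT_UNLABELED
        X_parts.append(stack[sel])
        y_parts.append((ann[sel] == ANNOT_MITO).astype(int))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("annotations must contain both mito and background pixels")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    return PixelClassifierModel(
        forest=forest,
        feature_names=names,
        sigmas=tuple(float(s) for s in sigmas),
        training_meta={"n_annotated_pixels": int(len(y)), "seed": int(seed)},
    )


def classify_pixels(img: Image2D, model: PixelClassifierModel) -> np.ndarray:
    """Binary mito mask from the pixel classifier (argmax class per pixel)."""
    stack, names = build_feature_stack(img, model.sigmas)
    if names != model.feature_names:
        raise ValueError("feature configuration does not match the trained model")
    flat = stack.reshape(-1, stack.shape[-1])
    pred = model.forest.predict(flat)
    return pred.reshape(img.pixels.shape).astype(bool)


def threshold_segment(
    img: Image2D, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Global-threshold segmentation (``mask = img > threshold``)."""
    if method == "otsu":
        t = threshold_otsu(img.pixels)
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        t = float(level)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img.pixels > t


# ---------------------------------------------------------------------------
# Particle extraction, erosion, labeling
# ---------------------------------------------------------------------------

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def extract_objects_2d(
    mask: np.ndarray, pixel_size_um: float, min_area_um2: float = 0.30
) -> list[MitoObject2D]:
    """8-connected components of a binary mask, filtered by minimum area.

    Surviving objects are relabeled consecutively in original label order.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_STRUCT_8)
    objects = []
    px_area = pixel_size_um**2
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) * px_area >= min_area_um2:
            objects.append(
                MitoObject2D(
                    label=len(objects) + 1,
                    pixel_coords=coords,
                    pixel_size_um=pixel_size_um,
                )
            )
    return objects


def default_erosion_element(ndim: int) -> np.ndarray:
    """Smallest standard element: 3×3 cross in 2D, 6-connected cross in 3D."""
    return ndi.generate_binary_structure(ndim, 1)


def erode_mask(
    mask: np.ndarray, element: np.ndarray | None = None, iterations: int = 1
) -> np.ndarray:
    """Binary erosion; the result is always a subset of the input."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if element is None:
        element = default_erosion_element(mask.ndim)
    return ndi.binary_erosion(mask, structure=element, iterations=iterations)


def label_3d(
    stack: np.ndarray,
    connectivity: int = 6,
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> tuple[LabelMap, list[MitoObject3D]]:
    """Connected-component labeling of a binary stack (z, y, x).

    ``connectivity`` is 6 (faces only, the default) or 26 (faces, edges and
    corners).
    """
    stack = np.asarray(stack, dtype=bool)
    if stack.ndim != 3:
        raise ValueError("label_3d expects a 3D stack")
    if connectivity == 6:
        structure = ndi.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndi.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndi.label(stack, structure=structure)
    objects = [
        MitoObject3D(
            label=lab,
            voxel_coords=np.argwhere(labels == lab),
            voxel_size_um=tuple(voxel_size_um),
        )
        for lab in range(1, n + 1)
    ]
    lmap = LabelMap(labels.astype(np.int32), tuple(voxel_size_um), connectivity)
    return lmap, objects


def downsample_em(img: Image2D, factor: int = 5) -> Image2D:
    """Bilinear downsampling by an integer factor (EM pre-compression).

    Output pixel (i, j) samples the input at the physical centre of the
    corresponding factor×factor block; the pixel size scales by the factor.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    h, w = img.pixels.shape
    oh, ow = h // factor, w // factor
    if oh < 2 or ow < 2:
        raise ValueError("downsampled image would be smaller than 2×2")
    rr = (np.arange(oh) + 0.5) * factor - 0.5
    cc = (np.arange(ow) + 0.5) * factor - 0.5
    grid = np.meshgrid(rr, cc, indexing="ij")
    out = ndi.map_coordinates(
        img.pixels, np.stack(grid), order=1, mode="nearest"
    )
    return Image2D(out, img.pixel_size_um * factor)
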