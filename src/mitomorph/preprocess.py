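"""The fixed 2D preprocessing chain applied to micrographs before segmentation.

The chain, in order: rolling-ball background subtraction (ball radius 10 px),
unsharp masking (radius 1 px, weight 0.60), contrast-limited adaptive
histogram equalization (256 bins), and a disc median filter (radius 2 px).
All stages operate on floating-point intensities with reflect border
handling, are deterministic, and carry the physical pixel size through
unchanged.

The rolling-ball step is implemented exactly as grayscale opening with a
non-flat ball structuring element (height sqrt(r² - d²) at in-plane distance
d), subtracted from the input.  The unsharp mask follows the
(I - w·G_σ(I)) / (1 - w) convention with σ equal to the radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist


@dataclass
class Image2D:
    """A single-channel 2D image with a physical scale."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("Image2D requires a non-empty 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        return Image2D(pixels, self.pixel_size_um)


@dataclass
class PreprocessConfig:
    rollingball_radius_px: float = 10.0
    unsharp_radius_px: float = 1.0
    unsharp_weight: float = 0.60
    clahe_bins: int = 256
    clahe_block_px: int = 127
    clahe_max_slope: float = 3.0
    median_radius_px: int = 2

    def validate(self) -> None:
        if self.rollingball_radius_px <= 0 or self.unsharp_radius_px <= 0:
            raise ValueError("filter radii must be > 0")
        if not 0 < self.unsharp_weight < 1:
            raise ValueError("unsharp_weight must be in (0, 1)")
        if self.clahe_bins < 2:
            raise ValueError("clahe_bins must be >= 2")
        if self.clahe_block_px < 3:
            raise ValueError("clahe_block_px must be >= 3")
        if self.median_radius_px < 1:
            raise ValueError("median_radius_px must be >= 1")


def _ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball of the given radius."""
    r = int(np.floor(radius))
    yy, xx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    d2 = yy.astype(float) ** 2 + xx.astype(float) ** 2
    footprint = d2 <= radius**2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius**2 - d2[footprint])
    return footprint, heights


def subtract_background(img: Image2D, radius_px: float = 10.0) -> Image2D:
    """Rolling-ball background subtraction.

    Returns ``img - opening(img)`` where the opening uses a non-flat ball
    structuring element of the given radius; the result is pointwise in
    ``[0, img]``.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    footprint, heights = _ball_element(radius_px)
    eroded = ndi.grey_erosion(
        img.pixels, footprint=footprint, structure=heights, mode="reflect"
    )
    opened = ndi.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="reflect"
    )
    out = np.clip(img.pixels - opened, 0.0, None)
    return img.with_pixels(out)


def unsharp_mask(img: Image2D, radius_px: float = 1.0, weight: float = 0.60) -> Image2D:
    """Sharpen: ``(I - w·G_σ(I)) / (1 - w)`` with σ = radius, clipped at 0."""
    if not 0 < weight < 1:
        raise ValueError("weight must be in (0, 1)")
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    blurred = ndi.gaussian_filter(img.pixels, sigma=radius_px, mode="reflect")
    out = (img.pixels - weight * blurred) / (1.0 - weight)
    return img.with_pixels(np.clip(out, 0.0, None))


def clahe(
    img: Image2D,
    bins: int = 256,
    block_px: int = 127,
    max_slope: float = 3.0,
) -> Image2D:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise equalization with the per-bin histogram count clipped at
    ``max_slope`` times the uniform level, bilinearly interpolated between
    tiles.  The output is rescaled to span the input's intensity range, so
    it never leaves the input bounds.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if block_px < 3:
        raise ValueError("block_px must be >= 3")
    if max_slope <= 0:
        raise ValueError("max_slope must be > 0")
    pix = img.pixels
    lo, hi = float(pix.min()), float(pix.max())
    if hi == lo:
        return img.with_pixels(pix.copy())
    norm = (pix - lo) / (hi - lo)
    # skimage's clip_limit is the clipped fraction of the tile pixel count per
    # bin; max_slope times the uniform level (1/bins) expresses the slope cap
    clip_limit = min(1.0, max_slope / bins)
    out01 = equalize_adapthist(
        norm, kernel_size=block_px, clip_limit=clip_limit, nbins=bins
    )
    return img.with_pixels(out01 * (hi - lo) + lo)


def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(-radius, radius + 1), np.arange(-radius, radius + 1), indexing="ij"
    )
    return yy**2 + xx**2 <= radius**2


def median_filter(img: Image2D, radius_px: int = 2) -> Image2D:
    """Disc median filter (neighbourhood d <= radius, reflect borders)."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    out = ndi.median_filter(
        img.pixels, footprint=_disc_footprint(int(radius_px)), mode="reflect"
    )
    return img.with_pixels(out)


def merge_channels(a: Image2D, b: Image2D, policy: str = "max") -> Image2D:
    """Merge two mitochondrial-marker channels into one image.

    ``max`` (default) keeps the stronger membrane signal at each pixel;
    ``sum`` adds the channels.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("channel shapes differ")
    if policy == "max":
        return a.with_pixels(np.maximum(a.pixels, b.pixels))
    if policy == "sum":
        return a.with_pixels(a.pixels + b.pixels)
    raise ValueError(f"unknown merge policy {policy!r}")


_STAGES = (
    ("subtract_background", lambda im, c: subtract_background(im, c.rollingball_radius_px)),
    ("unsharp_mask", lambda im, c: unsharp_mask(im, c.unsharp_radius_px, c.unsharp_weight)),
    ("clahe", lambda im, c: clahe(im, c.clahe_bins, c.clahe_block_px, c.clahe_max_slope)),
    ("median_filter", lambda im, c: median_filter(im, c.median_radius_px)),
)


def preprocess_pipeline(img: Image2D, cfg: PreprocessConfig | None = None) -> Image2D:
    """Run the four-stage chain in its fixed order."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = img
    for name, fn in _STAGES:
        try:
            out = fn(out, cfg)
        except Exception as exc:
            raise RuntimeError(f"preprocessing stage '{name}' failed: {exc}") from exc
    return out
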