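"""Reading digitized mammograms, tag-artifact removal, and breast-region masking.

A digitized film mammogram is a bright breast on a dark film background, often
with a high-intensity patient-identification tag in one corner.  The pipeline
here is: remove the tag, then derive the breast mask by grayscale erosion +
Gaussian blur followed by Kittler–Illingworth minimum-error thresholding, and
keep the largest connected foreground component.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .thresholds import (DegenerateHistogramError, build_histogram,
                         min_error_threshold)

__all__ = [
    "GrayImage",
    "BreastMask",
    "load_image",
    "save_image",
    "save_mask",
    "crop_tag",
    "background_mask",
]


@dataclass(frozen=True)
class GrayImage:
    """2-D non-negative integer intensity raster with declared bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("image smaller than 16x16 pixels")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if px.min() < 0:
            raise ValueError("negative intensities")
        if px.max() > (1 << self.bit_depth) - 1:
            raise ValueError(
                f"intensity {px.max()} exceeds {self.bit_depth}-bit range")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "pixels", px.astype(dtype))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_level(self) -> int:
        return (1 << self.bit_depth) - 1

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels=pixels, bit_depth=self.bit_depth)


@dataclass(frozen=True)
class BreastMask:
    """Binary breast-region raster aligned to a GrayImage."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def breast_area(self) -> int:
        return int(self.mask.sum())


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.max() <= 4095:
        return 12
    return 16


def load_image(path, bit_depth: int | None = None, as_gray: bool = False) -> GrayImage:
    """Load a single-channel TIFF/PNG/PGM raster.

    Multi-channel images are rejected unless ``as_gray`` asks for a luminance
    conversion.  ``bit_depth`` overrides the depth inferred from the dtype /
    value range (16-bit containers commonly hold 12-bit data).
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not as_gray:
            raise ValueError(
                f"{path}: multi-channel image; pass as_gray=True to convert")
        arr = np.round(arr[..., :3].mean(axis=2)).astype(arr.dtype)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path}: floating-point images are not supported")
    depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
    return GrayImage(pixels=arr, bit_depth=depth)


def save_image(image: GrayImage, path) -> None:
    iio.imwrite(path, image.pixels)


def save_mask(mask: BreastMask, path) -> None:
    """Persist a binary mask as 8-bit PNG with values 0/255."""
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# tag removal
# ---------------------------------------------------------------------------

def _auto_tag_mask(image: GrayImage, max_area_frac: float) -> np.ndarray:
    """Bright 8-connected component touching an image corner, smaller than
    ``max_area_frac`` of the image, with mean intensity above the global
    minimum-error threshold."""
    hist = build_histogram(image)
    try:
        level = min_error_threshold(hist)
    except DegenerateHistogramError:
        return np.zeros_like(image.pixels, dtype=bool)
    step = (1 << image.bit_depth) / hist.n_levels
    intensity_thresh = (level + 1) * step - 1
    bright = image.pixels > intensity_thresh
    labels, n = ndi.label(bright, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(bright)
    h, w = bright.shape
    corners = [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]
    areas = ndi.sum_labels(bright, labels, index=np.arange(1, n + 1))
    tag = np.zeros_like(bright)
    max_area = max_area_frac * bright.size
    for (r, c) in corners:
        lab = labels[r, c]
        if lab > 0 and areas[lab - 1] < max_area:
            tag |= labels == lab
    return tag


def crop_tag(image: GrayImage, policy="auto",
             max_area_frac: float = 0.05) -> GrayImage:
    """Remove a patient-identification tag artifact.

    ``policy`` is ``"auto"`` (detect a bright corner component) or an explicit
    rectangle ``(row0, col0, row1, col1)`` (half-open).  Removal replaces the
    tag pixels with the film-background level (image minimum) so downstream
    masks exclude the region while geometry is preserved.
    """
    px = image.pixels.copy()
    background = int(px.min())
    if policy == "auto":
        tag = _auto_tag_mask(image, max_area_frac)
        if not tag.any():
            return image
        px[tag] = background
        return image.with_pixels(px)
    r0, c0, r1, c1 = policy
    if not (0 <= r0 < r1 <= image.height and 0 <= c0 < c1 <= image.width):
        raise ValueError(f"crop rectangle {policy} outside image bounds")
    if (r1 - r0) * (c1 - c0) > 0.5 * px.size:
        raise ValueError("crop rectangle would remove more than half the image")
    px[r0:r1, c0:c1] = background
    return image.with_pixels(px)


# ---------------------------------------------------------------------------
# breast-region extraction
# ---------------------------------------------------------------------------

def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2


def background_mask(image: GrayImage, erosion_radius: int | None = None,
                    blur_sigma: float | None = None) -> BreastMask:
    """Extract the breast region.

    The working image is a grayscale erosion (disk footprint) followed by a
    Gaussian blur; the Kittler–Illingworth minimum-error threshold on its
    256-bin histogram separates breast from film background, and the largest
    connected foreground component (holes filled) is kept.

    Defaults scale linearly with image height: erosion radius 5 px and blur
    sigma 4 px at 1000-px height, floored at 1.
    """
    scale = image.height / 1000.0
    if erosion_radius is None:
        erosion_radius = max(1, int(round(5 * scale)))
    if blur_sigma is None:
        blur_sigma = max(0.5, 4.0 * scale)
    if erosion_radius < 1:
        raise ValueError("erosion_radius must be >= 1")
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be > 0")

    work = ndi.grey_erosion(image.pixels, footprint=_disk(erosion_radius))
    work = ndi.gaussian_filter(work.astype(np.float64), sigma=blur_sigma)
    work = np.clip(np.round(work), 0, image.max_level).astype(image.pixels.dtype)
    working = image.with_pixels(work)

    hist = build_histogram(working)
    if hist.n_nonzero_levels < 2:
        raise DegenerateHistogramError(
            "near-constant image: breast/background threshold undefined")
    level = min_error_threshold(hist)
    step = (1 << image.bit_depth) / hist.n_levels
    intensity_thresh = (level + 1) * step - 1
    fg = work > intensity_thresh
    if not fg.any():
        raise DegenerateHistogramError("no foreground found")

    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    breast = labels == keep
    breast = ndi.binary_fill_holes(breast)
    return BreastMask(mask=breast)
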