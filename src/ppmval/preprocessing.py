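"""Image conversion into the registration input space.

Specimen snapshots are reduced to their HSV saturation channel (tissue
regions are strongly chromatic against a gray work surface, which brings
the intensity levels closer to the histology rendering), histology images
to luminance, and both are resized to the fixed 256x192 registration grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "SpecimenImage",
    "GrayImage",
    "REG_WIDTH",
    "REG_HEIGHT",
    "to_saturation_gray",
    "to_luminance_gray",
    "resize_input",
    "foreground_mask",
]

REG_WIDTH = 256
REG_HEIGHT = 192

# Rec. 709 luma coefficients.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class SpecimenImage:
    """An RGB snapshot of the specimen; role 'S_O' (plain) or 'S_POI' (with dots)."""

    pixels: np.ndarray
    role: str = "S_O"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("specimen image must be an RGB raster (H, W, 3)")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("specimen image must be non-empty")
        if self.role not in ("S_O", "S_POI"):
            raise ValueError("role must be 'S_O' or 'S_POI'")


@dataclass
class GrayImage:
    """A single-channel raster with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("gray image must be a non-empty 2-D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("gray image must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("gray image intensities must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _rgb_unit(pixels: np.ndarray) -> np.ndarray:
    """RGB raster as float in [0, 1] regardless of integer/float input."""
    if np.issubdtype(pixels.dtype, np.integer):
        return pixels.astype(np.float64) / np.iinfo(pixels.dtype).max
    return pixels.astype(np.float64)


def to_saturation_gray(img: SpecimenImage) -> GrayImage:
    """HSV saturation channel, S = (max - min) / max with S = 0 where max = 0."""
    rgb = _rgb_unit(img.pixels)
    return GrayImage(pixels=rgb2hsv(rgb)[..., 1])


def to_luminance_gray(pixels: np.ndarray) -> GrayImage:
    """Rec. 709 luminance of an RGB raster."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("luminance conversion requires an RGB raster (H, W, 3)")
    return GrayImage(pixels=_rgb_unit(pixels) @ _LUMA)


def resize_input(
    img: GrayImage, width: int = REG_WIDTH, height: int = REG_HEIGHT
) -> GrayImage:
    """Resample to the fixed registration grid (aspect ratio not preserved).

    Downsampling is anti-aliased (Gaussian prefilter + bilinear); an input
    already at the target size is returned unchanged, bit-exact.
    """
    if min(img.shape) < 1:
        raise ValueError("cannot resize an empty image")
    if img.shape == (height, width):
        return GrayImage(pixels=img.pixels.copy())
    shrinking = img.shape[0] > height or img.shape[1] > width
    out = resize(
        img.pixels,
        (height, width),
        order=1,
        mode="reflect",
        anti_aliasing=shrinking,
        preserve_range=True,
    )
    return GrayImage(pixels=np.clip(out, 0.0, 1.0))


def foreground_mask(img: GrayImage, threshold: float | None = None) -> np.ndarray:
    """Binary foreground: Otsu threshold, holes filled, largest 4-connected blob.

    ``threshold`` overrides Otsu when given.  Raises on blank (constant)
    images, where no foreground can be defined.
    """
    px = img.pixels
    if threshold is None:
        if np.ptp(px) < 1e-12:
            raise ValueError("blank image: cannot derive a foreground threshold")
        threshold = float(threshold_otsu(px))
    binary = px > threshold
    if not binary.any():
        raise ValueError("thresholding produced an empty foreground")
    filled = ndimage.binary_fill_holes(binary)
    labels = measure.label(filled, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
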