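"""Image and mask I/O for en-face OCT-A slabs.

Widefield OCT-A en-face images arrive as 8-bit (occasionally 16-bit)
single-channel PNG/TIFF rasters; low-quality regions that were manually
cropped out are painted pure white in the "cropped" variant of an image.
This module reads and writes those rasters, derives elimination masks
from white paint, and enforces geometric consistency between an image
and its masks.

Coordinate convention: row-major, origin at the top-left corner,
0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "RetinalImage",
    "EliminationMask",
    "SegmentationMask",
    "read_image",
    "read_mask",
    "write_mask",
    "derive_elimination_mask",
]

MIN_IMAGE_SIDE = 32

#: Luminance weights used when collapsing RGB input to a single channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RetinalImage:
    """A 2D en-face full-retina slab: intensities on the [0, 255] scale.

    Parameters
    ----------
    pixels
        2D float array of intensities in [0, 255].
    pixel_pitch_mm
        Physical side length of one pixel in millimetres, if known
        (a 1900 px montage spanning ~24 mm gives ~0.0126 mm/px).
    """

    pixels: np.ndarray
    pixel_pitch_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image too small: {h}x{w}, need at least "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie within [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class EliminationMask:
    """Indicator of manually cropped-out (excluded) regions.

    ``excluded`` is True where the image was judged unusable (movement or
    shadow artifacts) and must not contribute to segmentation or metrics.
    An all-False mask is the "raw image" case.
    """

    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.ndim != 2:
            raise ValueError("elimination mask must be 2D")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "EliminationMask":
        return cls(np.zeros(shape, dtype=bool))

    @property
    def area(self) -> int:
        """Number of eliminated pixels (Area_eliminated)."""
        return int(self.excluded.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.excluded.shape


@dataclass
class SegmentationMask:
    """Binary non-perfusion map: True marks non-perfused pixels."""

    nonperfusion: np.ndarray

    def __post_init__(self) -> None:
        self.nonperfusion = np.asarray(self.nonperfusion, dtype=bool)
        if self.nonperfusion.ndim != 2:
            raise ValueError("segmentation mask must be 2D")

    @property
    def area(self) -> int:
        """Number of non-perfusion pixels (Area_nonperfusion)."""
        return int(self.nonperfusion.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.nonperfusion.shape


def _check_same_shape(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch ({what}): {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_pitch_mm: float | None = None) -> RetinalImage:
    """Read a PNG/TIFF raster as a :class:`RetinalImage`.

    RGB(A) input is converted to luminance; 16-bit input is rescaled to
    the [0, 255] range.  If a YAML sidecar ``<stem>.yaml`` exists next to
    the file and carries ``pixel_pitch_mm``, it is picked up unless the
    argument overrides it.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises various decode errors
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit input
        arr = arr * (255.0 / arr.max())
    if pixel_pitch_mm is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            pixel_pitch_mm = meta.get("pixel_pitch_mm")
    return RetinalImage(arr, pixel_pitch_mm=pixel_pitch_mm)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 binary raster as a boolean array (True = foreground)."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_mask(mask: SegmentationMask | EliminationMask | np.ndarray,
               path: str | Path) -> None:
    """Write a binary mask as a lossless 0/255 8-bit raster (PNG/TIFF).

    ``read_mask(write_mask(m))`` round-trips bitwise.
    """
    if isinstance(mask, SegmentationMask):
        arr = mask.nonperfusion
    elif isinstance(mask, EliminationMask):
        arr = mask.excluded
    else:
        arr = np.asarray(mask, dtype=bool)
    out = (arr.astype(np.uint8)) * 255
    Image.fromarray(out, mode="L").save(Path(path))


def write_image(image: RetinalImage, path: str | Path) -> None:
    """Write an image as an 8-bit raster (rounded to nearest integer)."""
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# Elimination-mask derivation
# ---------------------------------------------------------------------------

def derive_elimination_mask(
    image: RetinalImage,
    white_value: float = 255.0,
    tolerance: float = 0.0,
    min_region_px: int = 100,
) -> EliminationMask:
    """Derive the eliminated-region mask from white paint in a cropped image.

    Pixels with ``|intensity - white_value| <= tolerance`` are candidate
    eliminated pixels, but only connected regions (8-connectivity) of at
    least ``min_region_px`` pixels are kept: saturated vessel pixels can
    reach 255 too, and isolated bright dots must not be flagged.
    """
    if not 0 <= white_value <= 255:
        raise ValueError("white_value must be in [0, 255]")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    candidate = np.abs(image.pixels - white_value) <= tolerance
    if min_region_px > 1 and candidate.any():
        labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(labels.ravel())
            keep = areas >= min_region_px
            keep[0] = False
            candidate = keep[labels]
    return EliminationMask(candidate)
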