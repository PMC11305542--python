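"""The VMseg segmentation pipeline.

Non-perfusion (capillary dropout) appears on en-face OCT-A as regions
that are simultaneously *homogeneous* (low spatial variance — no vessel
texture) and *dark* (low decorrelation signal).  A single global
intensity threshold fails on widefield montages because brightness falls
off from the macula to the periphery, so the pipeline keys on local
variance instead:

1.  min-max normalize the image to [0, 255];
2.  edge-preserving bilateral pre-filter (9 px window, sigma 40);
3.  local-variance map per kernel size (3/5/7 px windows), averaged
    over the configured sizes;
4.  rescale the variance map to [0, 255] so homogeneous areas are LOW,
    then force pixels that are bright in the normalized image to 255
    (the vessel override — bright pixels are flow, never dropout);
5.  second bilateral pass on the modified map;
6.  grayscale closing then opening with a 5-px cross kernel, iterated;
7.  binarize: candidate non-perfusion where the map value falls
    strictly below the variance threshold;
8.  fill interior holes of each connected component and drop components
    smaller than the size threshold (250 px).

Eliminated (cropped-out) pixels are forced to 255 in the modified map
before filtering/morphology so they can never seed non-perfusion, and
are subtracted from the final mask.

The whole pipeline is deterministic: identical inputs give bit-identical
masks.  All processing happens at the full input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_bilateral

from .imgio import EliminationMask, RetinalImage, SegmentationMask, _check_same_shape

__all__ = [
    "VMsegParams",
    "VarianceMap",
    "CROSS_KERNEL_5",
    "normalize_image",
    "bilateral_smooth",
    "local_variance_map",
    "combine_variance_maps",
    "modify_variance_map",
    "morphology_clean",
    "binarize",
    "fill_and_filter",
    "segment",
]

ALLOWED_KERNEL_SIZES = (3, 5, 7)

#: 5-px cross-shaped structuring element used by the morphology stage.
CROSS_KERNEL_5 = np.zeros((5, 5), dtype=bool)
CROSS_KERNEL_5[2, :] = True
CROSS_KERNEL_5[:, 2] = True


@dataclass(frozen=True)
class VMsegParams:
    """Tunable pipeline parameters.

    Defaults are the optimum found on the development set of the original
    study: variance map averaged over 3- and 5-px windows, binarized at a
    variance threshold of 17, vessel override at a normalized intensity
    of 75, one morphology iteration, 250-px minimum component size.
    """

    kernel_sizes: tuple[int, ...] = (3, 5)
    variance_threshold: float = 17.0
    intensity_threshold: float = 75.0
    morph_iterations: int = 1
    size_threshold_px: int = 250
    bilateral_diameter: int = 9
    bilateral_sigma: float = 40.0

    def __post_init__(self) -> None:
        ks = tuple(sorted(set(int(k) for k in self.kernel_sizes)))
        if not ks or any(k not in ALLOWED_KERNEL_SIZES for k in ks):
            raise ValueError(
                f"kernel_sizes must be a nonempty subset of {ALLOWED_KERNEL_SIZES}"
            )
        object.__setattr__(self, "kernel_sizes", ks)
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be in [0, 255]")
        if not 0 < self.variance_threshold:
            raise ValueError("variance_threshold must be > 0")
        if self.morph_iterations < 0:
            raise ValueError("morph_iterations must be >= 0")
        if self.size_threshold_px < 1:
            raise ValueError("size_threshold_px must be >= 1")

    def to_dict(self) -> dict:
        return {
            "kernel_sizes": list(self.kernel_sizes),
            "variance_threshold": self.variance_threshold,
            "intensity_threshold": self.intensity_threshold,
            "morph_iterations": self.morph_iterations,
            "size_threshold_px": self.size_threshold_px,
            "bilateral_diameter": self.bilateral_diameter,
            "bilateral_sigma": self.bilateral_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VMsegParams":
        d = dict(d)
        if "kernel_sizes" in d:
            d["kernel_sizes"] = tuple(d["kernel_sizes"])
        return cls(**d)


@dataclass
class VarianceMap:
    """Local-variance image. ``stage`` is 'raw' (non-negative variance
    units) or 'modified' (rescaled to [0, 255], vessel override applied)."""

    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("variance map must be 2D")
        if self.stage not in ("raw", "modified"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "raw" and self.values.min() < 0:
            raise ValueError("raw variance map must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# Stage 1-2: normalization and bilateral pre-filtering
# ---------------------------------------------------------------------------

def normalize_image(image: RetinalImage) -> RetinalImage:
    """Min-max rescale intensities to [0, 255]; constant images map to 0."""
    px = image.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        # clip absorbs float overshoot at the extremes
        out = np.clip((px - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return RetinalImage(out, pixel_pitch_mm=image.pixel_pitch_mm)


def bilateral_smooth(
    image: RetinalImage,
    diameter: int = 9,
    sigma: float = 40.0,
) -> RetinalImage:
    """Edge-preserving bilateral filter (window ``diameter`` px, intensity
    and spatial sigmas both ``sigma``, intensity sigma on the 0-255 scale)."""
    if diameter < 3 or diameter % 2 == 0:
        raise ValueError("diameter must be odd and >= 3")
    out = _bilateral(image.pixels, diameter, sigma)
    return RetinalImage(out, pixel_pitch_mm=image.pixel_pitch_mm)


def _bilateral(values: np.ndarray, diameter: int, sigma: float) -> np.ndarray:
    """Bilateral filter on a float array in [0, 255]."""
    scaled = np.clip(values, 0.0, 255.0) / 255.0
    out = denoise_bilateral(
        scaled,
        win_size=diameter,
        sigma_color=sigma / 255.0,
        sigma_spatial=sigma,
        mode="reflect",
    )
    return np.clip(out * 255.0, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Stage 3: local variance
# ---------------------------------------------------------------------------

def local_variance_map(image: RetinalImage | np.ndarray, window: int) -> VarianceMap:
    """Population variance of each ``window`` x ``window`` neighborhood.

    Computed as E[X^2] - E[X]^2 with uniform box filters and reflect
    padding at the borders; tiny negative values from floating-point
    cancellation are clipped to 0.
    """
    if window not in ALLOWED_KERNEL_SIZES:
        raise ValueError(f"window must be one of {ALLOWED_KERNEL_SIZES}")
    px = image.pixels if isinstance(image, RetinalImage) else np.asarray(image, float)
    mean = ndimage.uniform_filter(px, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(px * px, size=window, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return VarianceMap(var, stage="raw")


def combine_variance_maps(maps: list[VarianceMap]) -> VarianceMap:
    """Pixelwise mean of raw variance maps (e.g. windows 3 and 5)."""
    if not maps:
        raise ValueError("need at least one variance map")
    for m in maps:
        if m.stage != "raw":
            raise ValueError("can only combine raw variance maps")
        _check_same_shape(m.values, maps[0].values, "variance maps")
    return VarianceMap(np.mean([m.values for m in maps], axis=0), stage="raw")


# ---------------------------------------------------------------------------
# Stage 4: modified variance map (rescale + vessel override)
# ---------------------------------------------------------------------------

def rescale_variance(vmap: VarianceMap) -> np.ndarray:
    """Min-max rescale a raw variance map to [0, 255].

    Orientation: homogeneous (low-variance) areas end LOW, textured areas
    HIGH — the orientation under which candidate non-perfusion is selected
    *below* the variance threshold.  A constant map rescales to all zeros.
    """
    v = vmap.values
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) * (255.0 / (hi - lo))


def modify_variance_map(
    vmap: VarianceMap,
    original: RetinalImage,
    intensity_threshold: float,
) -> VarianceMap:
    """Rescale the raw variance map to [0, 255] and apply the vessel
    override: pixels whose *normalized original* intensity is >=
    ``intensity_threshold`` are set to 255, so bright (flow) pixels can
    never be classified as non-perfusion regardless of local variance."""
    _check_same_shape(vmap.values, original.pixels, "variance map vs image")
    out = rescale_variance(vmap)
    out[original.pixels >= intensity_threshold] = 255.0
    return VarianceMap(out, stage="modified")


# ---------------------------------------------------------------------------
# Stage 5-6: second bilateral pass + grayscale morphology
# ---------------------------------------------------------------------------

def morphology_clean(
    vmap: VarianceMap,
    kernel: np.ndarray = CROSS_KERNEL_5,
    iterations: int = 1,
) -> VarianceMap:
    """Grayscale closing then opening with the cross kernel.

    ``iterations`` follows the usual iterated-morphology semantics:
    closing with N iterations dilates N times then erodes N times
    (equivalent to closing with an N-fold dilated kernel), and likewise
    for opening.  ``iterations=0`` returns the input unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if vmap.stage != "modified":
        raise ValueError("morphology operates on the modified variance map")
    v = vmap.values
    if iterations == 0:
        return VarianceMap(v.copy(), stage="modified")
    for _ in range(iterations):  # closing: dilate^N ...
        v = ndimage.grey_dilation(v, footprint=kernel, mode="reflect")
    for _ in range(iterations):  # ... then erode^N
        v = ndimage.grey_erosion(v, footprint=kernel, mode="reflect")
    for _ in range(iterations):  # opening: erode^N ...
        v = ndimage.grey_erosion(v, footprint=kernel, mode="reflect")
    for _ in range(iterations):  # ... then dilate^N
        v = ndimage.grey_dilation(v, footprint=kernel, mode="reflect")
    return VarianceMap(np.clip(v, 0.0, 255.0), stage="modified")


# ---------------------------------------------------------------------------
# Stage 7-8: binarization, hole filling and size filtering
# ---------------------------------------------------------------------------

def binarize(vmap: VarianceMap, variance_threshold: float) -> SegmentationMask:
    """Candidate non-perfusion = modified map value strictly below the
    variance threshold (low variance and dark)."""
    if not 0 < variance_threshold < 255:
        raise ValueError("variance_threshold must be in (0, 255)")
    if vmap.stage != "modified":
        raise ValueError("binarize operates on the modified variance map")
    return SegmentationMask(vmap.values < variance_threshold)


def fill_and_filter(mask: SegmentationMask, size_threshold_px: int = 250) -> SegmentationMask:
    """Fill interior holes of each connected component and drop small ones.

    Foreground components use 8-connectivity; holes are background regions
    not 4-connected to the frame border.  Filled components with area
    below ``size_threshold_px`` are removed (area >= threshold is kept).
    Idempotent.
    """
    if size_threshold_px < 1:
        raise ValueError("size_threshold_px must be >= 1")
    m = mask.nonperfusion
    # binary_fill_holes with the default cross structure = 4-connected background
    filled = ndimage.binary_fill_holes(m)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return SegmentationMask(filled)
    areas = np.bincount(labels.ravel())
    keep = areas >= size_threshold_px
    keep[0] = False
    return SegmentationMask(keep[labels])


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def segment(
    image: RetinalImage,
    elim: EliminationMask | None = None,
    params: VMsegParams | None = None,
) -> SegmentationMask:
    """Run the full VMseg pipeline on one image.

    Parameters
    ----------
    image
        The en-face slab (raw or cropped).
    elim
        Eliminated-region mask; ``None`` means nothing is excluded.
    params
        Pipeline parameters; defaults to the published optimum.

    Returns
    -------
    SegmentationMask
        Binary non-perfusion map, guaranteed disjoint from ``elim``.
    """
    params = params or VMsegParams()
    if elim is None:
        elim = EliminationMask.empty(image.shape)
    _check_same_shape(image.pixels, elim.excluded, "image vs elimination mask")

    norm = normalize_image(image)
    smooth = bilateral_smooth(norm, params.bilateral_diameter, params.bilateral_sigma)
    combined = combine_variance_maps(
        [local_variance_map(smooth, k) for k in params.kernel_sizes]
    )
    modified = modify_variance_map(combined, norm, params.intensity_threshold)
    # eliminated pixels can never seed non-perfusion
    modified.values[elim.excluded] = 255.0
    smoothed = VarianceMap(
        _bilateral(modified.values, params.bilateral_diameter, params.bilateral_sigma),
        stage="modified",
    )
    cleaned = morphology_clean(smoothed, CROSS_KERNEL_5, params.morph_iterations)
    binary = binarize(cleaned, params.variance_threshold)
    final = fill_and_filter(binary, params.size_threshold_px)
    return SegmentationMask(final.nonperfusion & ~elim.excluded)
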