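"""Synthetic widefield OCT-A phantoms with known non-perfusion ground truth.

A phantom emulates the image statistics the segmentation pipeline keys
on, not retinal anatomy:

* a speckled background (perfused tissue) whose brightness falls off
  radially from the center of the frame to the periphery, the montage
  artifact that defeats global thresholding on widefield images;
* bright curvilinear vessels, drawn as biased random walks with
  occasional branching, 1-4 px wide, until a target areal density is
  reached — these create the high-variance texture of perfused retina;
* smooth dark dropout patches (irregular, sinusoid-perturbed ellipses)
  where vessels are erased and noise amplitude collapses — the
  homogeneous, dark signature of capillary non-perfusion;
* an optional white-painted sector standing in for manually eliminated
  low-quality areas.

All randomness flows from the single explicit seed in the config; the
same config yields bit-identical samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imgio import EliminationMask, RetinalImage, SegmentationMask, write_image, write_mask

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_suite"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of one synthetic sample.

    Intensities are on the 8-bit [0, 255] scale, lengths in pixels.
    """

    size: int = 512
    n_patches: int = 3
    patch_radius_range: tuple[float, float] = (30.0, 60.0)
    vessel_density: float = 0.25
    speckle_sigma: float = 30.0
    gradient_strength: float = 0.25
    elim_fraction: float = 0.05
    seed: int = 0
    background_intensity: float = 140.0
    patch_intensity: float = 40.0
    patch_sigma: float = 4.0
    vessel_intensity: float = 235.0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if not 0 <= self.elim_fraction < 0.5:
            raise ValueError("elim_fraction must be in [0, 0.5)")
        if self.patch_radius_range[0] < 8:
            raise ValueError("patch radii must be >= 8 px")
        if not 0 <= self.gradient_strength <= 1:
            raise ValueError("gradient_strength must be in [0, 1]")
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")


@dataclass
class PhantomSample:
    """A generated phantom: image, ground-truth dropout mask, elimination
    mask, the config that produced it, and the generator's analytic
    bookkeeping of total patch area (pre-rasterization)."""

    image: RetinalImage
    truth: SegmentationMask
    elim: EliminationMask
    config: PhantomConfig
    analytic_patch_area: float


# number of sinusoidal harmonics perturbing each patch boundary
_N_HARMONICS = 3
_HARMONIC_AMP = 0.12


def _patch_boundary(rng: np.random.Generator, radius: float):
    """Random irregular-ellipse boundary r(theta) and its analytic area."""
    amps = rng.uniform(0.03, _HARMONIC_AMP, size=_N_HARMONICS)
    phases = rng.uniform(0, 2 * np.pi, size=_N_HARMONICS)
    orders = np.arange(2, 2 + _N_HARMONICS)

    def r_of_theta(theta: np.ndarray) -> np.ndarray:
        pert = sum(a * np.sin(k * theta + p) for a, k, p in zip(amps, orders, phases))
        return radius * (1.0 + pert)

    # area = 1/2 ∫ r(θ)² dθ = π R² (1 + Σ a²/2) for pure sinusoids
    analytic_area = np.pi * radius**2 * (1.0 + 0.5 * float(np.sum(amps**2)))
    return r_of_theta, analytic_area


def _rasterize_patch(size: int, cy: float, cx: float, r_of_theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return rho < r_of_theta(theta)


def _disk_offsets(width: int) -> np.ndarray:
    """Pixel offsets of a stamped disk for a vessel of the given width."""
    r = width / 2.0
    n = int(np.ceil(r))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    sel = yy**2 + xx**2 <= r**2 + 1e-9
    return np.stack([yy[sel], xx[sel]], axis=1)


def _draw_vessels(rng: np.random.Generator, size: int, density: float) -> np.ndarray:
    """Biased random walks with branching until the target density."""
    mask = np.zeros((size, size), dtype=bool)
    target = int(density * size * size)
    offsets = {w: _disk_offsets(w) for w in (1, 2, 3, 4)}
    max_strokes = 10_000
    strokes = 0
    while mask.sum() < target and strokes < max_strokes:
        strokes += 1
        stack = [(
            rng.uniform(0, size), rng.uniform(0, size),
            rng.uniform(0, 2 * np.pi), int(rng.integers(60, 220)),
        )]
        width = int(rng.integers(1, 5))
        off = offsets[width]
        while stack:
            y, x, ang, steps = stack.pop()
            for _ in range(steps):
                ang += rng.normal(0.0, 0.15)
                y += np.sin(ang)
                x += np.cos(ang)
                if not (0 <= y < size and 0 <= x < size):
                    break
                pts = off + np.array([int(y), int(x)])
                ok = ((pts[:, 0] >= 0) & (pts[:, 0] < size)
                      & (pts[:, 1] >= 0) & (pts[:, 1] < size))
                mask[pts[ok, 0], pts[ok, 1]] = True
                if rng.random() < 0.008:  # branch
                    stack.append((y, x, ang + rng.choice([-1.0, 1.0]) * 0.7,
                                  steps // 2))
    return mask


def _elim_region(size: int, fraction: float) -> np.ndarray:
    """A white-painted strip along the top border with the requested area."""
    mask = np.zeros((size, size), dtype=bool)
    if fraction > 0:
        rows = max(1, int(round(fraction * size)))
        mask[:rows, :] = True
    return mask


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom sample; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    s = config.size

    # radial brightness falloff: 1 at center -> 1-strength at the corner
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    r_norm = np.hypot(yy - c, xx - c) / np.hypot(c, c)
    gradient = 1.0 - config.gradient_strength * r_norm**2

    image = config.background_intensity * gradient + rng.normal(
        0.0, config.speckle_sigma, size=(s, s))

    vessels = _draw_vessels(rng, s, config.vessel_density)
    vessel_img = config.vessel_intensity * gradient + rng.normal(0.0, 8.0, size=(s, s))
    image = np.where(vessels, np.maximum(image, vessel_img), image)

    elim = _elim_region(s, config.elim_fraction)

    # place non-overlapping dropout patches clear of the eliminated strip
    truth = np.zeros((s, s), dtype=bool)
    analytic_area = 0.0
    placed: list[tuple[float, float, float]] = []
    elim_rows = int(round(config.elim_fraction * s)) if config.elim_fraction > 0 else 0
    for _ in range(config.n_patches):
        lo, hi = config.patch_radius_range
        for attempt in range(200):
            radius = rng.uniform(lo, hi)
            margin = 1.25 * radius + 2  # bounding circle incl. boundary jitter
            if margin + elim_rows >= s - margin:
                continue  # patch cannot fit this frame
            cy = rng.uniform(margin + elim_rows, s - margin)
            cx = rng.uniform(margin, s - margin)
            if all(np.hypot(cy - py, cx - px) > margin + 1.25 * pr + 2
                   for py, px, pr in placed):
                break
        else:
            raise RuntimeError("could not place dropout patches (geometry infeasible)")
        r_of_theta, a = _patch_boundary(rng, radius)
        patch = _rasterize_patch(s, cy, cx, r_of_theta)
        truth |= patch
        analytic_area += a
        placed.append((cy, cx, radius))

        # dropout: dark, nearly noise-free, vessels erased; soft 1.5-px blend
        alpha = ndimage.gaussian_filter(patch.astype(float), sigma=1.5)
        patch_img = config.patch_intensity * gradient + rng.normal(
            0.0, config.patch_sigma, size=(s, s))
        image = alpha * patch_img + (1.0 - alpha) * image

    image[elim] = 255.0
    image = np.clip(np.rint(image), 0, 255)  # emulate 8-bit storage

    return PhantomSample(
        image=RetinalImage(image),
        truth=SegmentationMask(truth & ~elim),
        elim=EliminationMask(elim),
        config=config,
        analytic_patch_area=analytic_area,
    )


def generate_suite(
    n: int,
    config: PhantomConfig | None = None,
    base_seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with seeds ``base_seed .. base_seed+n-1``.

    Patch counts vary from sample to sample (1 to ``2*n_patches - 1``,
    drawn from each sample's own seed) so that a suite spans a range of
    ground-truth non-perfusion indexes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PhantomConfig()
    samples = []
    for i in range(n):
        seed = base_seed + i
        count_rng = np.random.default_rng(seed)
        n_patches = int(count_rng.integers(1, max(2, 2 * config.n_patches)))
        cfg = replace(config, seed=seed, n_patches=n_patches)
        samples.append(generate_phantom(cfg))
    return samples


def write_suite(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write image/truth/elim PNG triplets plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        stem = f"phantom_{i:03d}"
        write_image(s.image, out_dir / f"{stem}.png")
        write_mask(s.truth, out_dir / f"{stem}_truth.png")
        write_mask(s.elim, out_dir / f"{stem}_elim.png")
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(s.config).items()}
        manifest.append({"id": stem, "config": cfg,
                         "analytic_patch_area": s.analytic_patch_area})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
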