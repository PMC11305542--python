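# Methods

## Model and assumptions

Non-perfusion on an OCT-A en-face full-retina slab is modeled as the
conjunction of two local properties: **low spatial variance** (perfused
retina is textured by bright capillaries; dropout is homogeneous) and **low
intensity** (dropout carries little decorrelation signal). The pipeline makes
no anatomical assumptions beyond this; it is a texture detector. It assumes a
single 2D 8-bit grayscale slab — no multi-depth slabs, no montage stitching,
no device-specific metadata.

The center-to-periphery brightness gradient of widefield photomontages is the
reason variance is used instead of a global intensity threshold: variance is
computed in small (3–7 px) windows and is unaffected by smooth large-scale
brightness changes.

## Pipeline parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `kernel_sizes` | window sizes of the variance maps that are averaged | `{3, 5}` | subsets of {3, 5, 7} px |
| `variance_threshold` | binarization cut on the modified [0–255] variance map | 17 | strict `<`; tuned range 10–30 step 0.5 |
| `intensity_threshold` | vessel override: normalized intensity at/above which a pixel is forced to 255 | 75 | tuned range 50–100 step 1 |
| `morph_iterations` | iterations of grayscale closing-then-opening | 1 | 0 = skip; tuned range 0–4 |
| `size_threshold_px` | minimum filled component area kept | 250 px | components of exactly 250 px are kept |
| `bilateral_diameter` / `bilateral_sigma` | bilateral filter window and sigmas | 9 px / 40 | same values for both passes |

Defaults are the development-set optimum of the original study and are not
re-tuned here. The physical area of 250 px depends on pixel pitch, which is
configurable (`pixel_pitch_mm`) and never hard-coded.

## Numerical choices

* **Variance estimator**: population variance (divide by *n*) via
  E[X²] − E[X]², computed with uniform box filters, reflect padding at
  borders; negative floating-point residue is clipped to 0. Equivalence with
  a double-loop two-pass variance is enforced to 1e-6 in the tests.
* **Map orientation**: the rescaled variance map assigns LOW values to
  homogeneous areas and HIGH to textured ones, and binarization selects
  strictly *below* the threshold. This is the only orientation consistent
  with the vessel override pushing flow pixels to 255.
* **Vessel override** compares the *normalized, pre-bilateral* image against
  the intensity threshold, with ties (`>=`) resolved toward vessel.
* **Bilateral filter**: scikit-image `denoise_bilateral` on the [0,1] scale
  with `sigma_color = 40/255`, `sigma_spatial = 40`, `win_size = 9`, which
  reproduces the usual opencv parameterization `bilateralFilter(d=9, 40, 40)`.
  The second pass reuses the first pass's parameters.
* **Morphology**: grayscale closing then opening with a 5-px cross kernel.
  `N` iterations use iterated-dilation/erosion semantics (closing = dilate^N
  then erode^N), the convention of opencv's `morphologyEx`, under which the
  iteration count has a real effect (literal re-application of closing would
  be idempotent and the parameter inert). `iterations=0` is the identity.
* **Hole filling**: background flood fill from the frame border with
  4-connectivity; foreground components use 8-connectivity (the standard
  duality). The size filter keeps filled areas `>= size_threshold_px`.
* **Eliminated pixels** are forced to 255 in the modified variance map before
  the second bilateral pass and morphology, so they can never seed
  non-perfusion, and the final mask is intersected with the complement of the
  elimination mask — the output is disjoint from it by construction.
* **Tie-breaking in the grid search** (paper-silent, fixed for
  reproducibility): smallest variance threshold, then smallest intensity
  threshold, then fewest morphology iterations, then grid order of kernel
  combinations.
* **Degenerate inputs**: constant images normalize to all-zero (whole frame
  segmented as one homogeneous dark region); a constant variance map
  rescales to all-zero; NPI raises when the eliminated area covers the frame;
  Dice of two empty masks is defined as 1.0 (perfect agreement on absence).

## Design choices where the method description was open

* Dice counts exclude eliminated pixels, mirroring their exclusion from the
  NPI denominator, so both metrics are computed over the same evaluable
  region.
* The grid search evaluates the full Cartesian product of the four parameter
  axes; 1-D marginal curves through the optimum are derived from it (these
  subsume coordinate-wise sweeps). The search caches every stage that does
  not depend on the parameter being varied — normalization, the first
  bilateral pass and the per-window variance maps per kernel combination,
  the override + second bilateral per intensity threshold, morphology per
  iteration count — which makes the exhaustive search tractable while
  remaining exactly equivalent to running the pipeline end to end at every
  grid point (asserted in the tests).
* The morphology iteration range spans 0–4: reported optimization results
  cover 0 even though the protocol section states 1–4, and 0 (skip) is the
  natural lower end.
* Robustness subsets are drawn image-wise, without replacement, from an
  explicit seed recorded in the output table.
* Elimination masks can be supplied as files or derived from pure-white paint
  in cropped images; derivation keeps only white regions ≥ 100 px (8-connected)
  so saturated vessel pixels are not mistaken for paint.

## The phantom generator

The generator emulates the image *statistics* the algorithm keys on, not
retinal anatomy:

* speckled background (mean 140, sigma 30) under a radial brightness falloff
  (25% center→corner) — the montage artifact that defeats global thresholds;
* bright (≈235) curvilinear vessels drawn as biased random walks with
  branching, 1–4 px wide, to a 25% areal density — the high-variance texture
  of perfused retina;
* dropout patches: irregular sinusoid-perturbed ellipses (radius 30–60 px by
  default), dark (≈40) and nearly noise-free (sigma 4), vessels erased,
  blended with a 1.5-px soft edge; patch count varies across a suite so
  ground-truth NPI spans a range;
* a white strip (5% of the frame) standing in for manually eliminated areas.

All randomness flows from one explicit seed; identical configs give
bit-identical samples, and the rasterized patch area matches the generator's
analytic bookkeeping within 2%.

What the phantoms do **not** emulate: OCT-A decorrelation physics, projection
and motion artifacts, signal-strength variation, real vascular branching
morphology, or graders' annotation variability. Passing the phantom suite
therefore demonstrates that the implementation behaves as specified on images
with the assumed statistics (high dropout contrast); it does not certify
clinical performance, which in the original study was measured on private
images (test-set mean Dice 0.683 ± 0.175) that are not available here.

## Problem sizes used in tests and the acceptance script

Phantom-suite recovery uses 20 samples at the native 512-px default; grid
search and robustness analyses use 256-px phantoms, 3–6 images, and a reduced
3 × 3 × 3 × 2 grid bracketing the default optimum, with pipeline-generated
ground truth (which makes the optimum sharp and the expected recovery exact).
These sizes were chosen so the full chain — generation, segmentation, search,
resampling — runs end to end in minutes on a single core while still
exercising every stage at realistic signal-to-noise.

## Known limitations

* The variance threshold operates on a per-image min–max rescaled map, so its
  meaning depends on the image's own variance range; images lacking any
  high-variance structure will rescale noise to the full range.
* Raw (uncropped) clinical images with large artifacts are expected to
  segment poorly — in the original study raw-image Dice was ~0.45 versus
  ~0.70 for cropped images; artifact cropping (or an elimination mask) is
  effectively part of the method.
* The 250-px size filter is resolution-dependent; at other pixel pitches it
  should be rescaled by the user.
* `spearman` requires non-constant series of length ≥ 3; suites of phantoms
  with identical geometry will fail that precondition by design.
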