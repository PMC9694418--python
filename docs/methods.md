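# Methods

This note documents the model, the numerical choices, the synthetic data
and the known limits of the detector. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Model and procedure

The detector treats a grayscale MR slice as a function sampled on a
regular grid and asks a purely geometric question: *where does a
piecewise-linear approximation of this function fail to be smooth?* The
pipeline is

1. **Rescale + γ-correct.** Intensities are min-max rescaled to [0,1]
   (a constant slice maps to all zeros) and transformed pointwise,
   G = I^γ. With γ = 4 the transform is a contrast gate: tissue around
   0.35 drops to ≈0.015 while bright structures stay near 1. Crucially it
   also reshapes *texture*: the local noise amplitude is scaled by the
   derivative γ·I^(γ−1), ≈ 3.4 near I = 0.95 but ≈ 0.17 at I = 0.35. A
   heterogeneous bright lesion therefore keeps producing strong local
   gradients after correction while normal tissue becomes quiet. γ = 1/8
   inverts the logic for T2 slices whose cerebrospinal fluid is bright:
   all bright structure is compressed towards 1 and stops attracting the
   estimator.
2. **P1 interpolation and downsampling.** The corrected image defines a
   continuous piecewise-linear function on the pixel-grid triangulation
   (pixel (i, j), 1-based, sits at node (x, y) = (j−1, i−1); nodes are
   numbered column-major, k = (j−1)m + i). The adaptive loop starts from a
   uniform coarse triangulation of the same rectangle with the largest
   structured count not exceeding the target N_t (default 1200; a 283×295
   slice gives exactly 24×25 cells = 1200 triangles). Coarse nodes need
   not coincide with pixels; nodal values are obtained by evaluating the
   pixel-grid interpolant.
3. **Indicator.** Per triangle, η_T = ‖G(Ĩ) − ∇Ĩ‖_{L²(T)} where the
   recovered gradient G is the area-weighted average of the constant
   element gradients over each vertex star. Inside a triangle G is
   interpolated linearly from its three nodal values, making the squared
   integrand quadratic; the three-edge-midpoint rule integrates it
   exactly. The rough one-ring recovery is intentional — the goal is to
   flag the *extent* of a rapidly varying region, not to localize its
   edges sharply — so no superconvergent patch recovery is used.
4. **Marking.** Indicators are sorted and the threshold is
   cref · η_(t) with t = ⌈p·N_t⌉. The package anchors the rank at the
   **largest** end by default (threshold = cref times the p-quantile from
   the top): with p = 0.25, cref = 0.6 this marks roughly the strongest
   third of the mesh. The alternative literal ascending reading
   (`MarkingConfig(anchor="smallest")`) anchors the threshold at the 25th
   percentile; because cref < 1 that marks at least 75% of all triangles
   every iteration, i.e. near-uniform refinement. The selective anchor is
   the one consistent with the reference behavior of this method (a
   1200-triangle start mesh growing by only a few hundred nodes over
   several iterations) and with the requirement that refinement
   concentrate on anomalies; both readings are implemented and tested.
5. **Refinement.** Newest-vertex bisection with recursive conformity
   closure. Initial refinement edges are the cell diagonals, so the
   uniform mesh is compatible and every element is right isosceles;
   bisection then reproduces right isosceles triangles forever and the
   minimum angle stays at 45°. For general meshes the standard NVB bound
   (minimum angle never below half the initial) is asserted over ten
   rounds of random marking.
6. **Stopping.** The loop ends when max_T η_T falls below `eta_stop` or
   after `max_iter` (default 8) refinement passes. No absolute threshold
   is prescribed by the method, so the default is relative: 5% of the
   first iteration's maximum, with a 1e−12 absolute floor so a uniform
   image (η ≡ 0) terminates immediately without refining. If the loop
   never refines anything, the binary map is empty by definition — "no
   triangle was ever singled out" must not degenerate into "every
   triangle is minimal".
7. **Binary map.** Triangles with area ≤ (1 + rel_tol)·min area are
   selected and rasterized. Bisection produces an exact area ladder
   A₀/2^k, and marking under pixel noise is stochastic, so individual
   triangles lag one or two generations behind their neighbours inside a
   uniformly flagged region. The pipeline therefore selects the four
   deepest generations (rel_tol = 7.5) — at the default problem scale all
   of them are at or below ~1 px² — and rasterizes in "cover" mode: a
   pixel is painted when its center lies within signed edge distance
   −0.5 of a selected triangle (the triangle dilated by half a pixel,
   approximating pixel-square overlap). Measured on phantoms, selecting a
   single generation with center sampling leaves ~7–30% single-pixel
   holes inside detected regions, and erosion amplifies every hole into a
   13×13 void; the two robustness choices together close those gaps
   (region coverage goes to >99.9%) without thickening thin structures by
   more than ~1 px. Strict center containment and single-generation
   selection remain available (`raster_mode="center"`, rel_tol < 1) and
   are the contracts the rasterizer is tested against.
8. **Post-processing and decision.** Six binary erosions with the 3×3
   all-ones kernel (border = background) remove thin curves — notably the
   cortex outline — and isolated specks, while compact blobs wider than
   ~13 px survive. The slice is *healthy* if less than 1% of all m·n
   pixels remain white (the unambiguous denominator), *affected*
   otherwise; surviving 8-connected components are reported with
   bounding boxes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ / γ_alt | 4 / 0.125 | contrast exponents (T1-like / bright-CSF T2) |
| N_t | 1200 | coarse-mesh triangle target |
| p, cref | 0.25, 0.60 | marking quantile and threshold factor |
| max_iter | 8 | refinement passes (area ladder bottoms out sub-pixel) |
| eta_stop | 5% of iter-1 max | relative stopping threshold |
| rel_tol | 7.5 | minimal-area window (four ladder generations) |
| raster_mode | cover | half-pixel-dilated rasterization |
| erosions | 6 | erosion passes (0–6) |
| decision threshold | 1% | white fraction separating healthy/affected |

γ selection is manual by default. An opt-in heuristic
(`auto_gamma`) switches to γ_alt when more than 30% of the pixels inside
the brain bounding box exceed intensity 0.8 — the signature of bright
CSF; it is a convenience of this implementation, not part of the method.

## Synthetic phantoms

`zzdetect.synthetic` generates 200×200 geometric phantoms: an elliptic
bright cortex ring (intensity 0.85, width 7 px, semi-axes 88×80 px)
around smooth interior tissue (0.35 ± 0.04 low-frequency modulation) on an
exactly black background, optionally a compact bright lesion (radius
9.5–13% of image width, intensity 0.92–0.98) and a ventricle-like bright
ellipse (31×17 px, 0.92) mimicking T2 CSF contrast. Additive Gaussian
noise (σ = 0.02) is applied inside the brain only; the background stays
exactly black, emulating display-windowed exports whose air region is
clipped. This matters: the power map I^(1/8) has unbounded slope at 0, so
noise on a truly black background would dominate the indicator under the
corrective γ — a behavior windowed MR exports do not show. Partial-volume
effects are modelled by a 1-px Gaussian blur before noise.

The lesion radius range sits above the geometric floor imposed by the
decision rule itself: after six erosions a disk of radius r keeps
π(r−6)² pixels, which crosses 1% of a 200×200 image only for r ≳ 17 px
(8.5% of width). Smaller lesions are invisible to the 1% rule *by
construction*, regardless of the estimator.

What the phantoms do **not** model: anatomy (gyri, ventricles beyond a
single ellipse, skull), acquisition physics (bias fields, Rician noise,
partial Fourier artifacts), multi-slice context, and tumor appearance
diversity (rim-enhancing, infiltrative, dark necrotic cores). Passing the
phantom cohort therefore shows that the numerical chain — γ gating,
indicator concentration, ladder selection, erosion decision — works as
designed on bright compact lesions; it does not certify clinical
performance. Dark lesions are supported by the generator but are hard for
the γ = 4 path by design (tissue is crushed to ≈0.015, leaving almost no
contrast to a dark core), matching the method's stated bias towards
bright anomalies.

## Numerical choices and degenerate inputs

* Marking ties are resolved by plain `>=` comparison on raw values, so
  equal indicators are treated alike; if all indicators are equal, every
  triangle is marked (the adaptive loop suppresses the all-zero case
  before marking).
* Point-in-triangle tests are inclusive with a signed-area epsilon of
  1e−9 in pixel units; rasterization of a selected set is a union, so
  pixels on shared edges are white whenever any incident triangle is
  selected.
* A constant raw image rescales to all zeros and exits the loop at once:
  healthy, empty mask.
* The general `resample` clamps target nodes to the source bounding box
  and falls back to nearest-node values for points the point-locator
  cannot place (logged); the adaptive loop itself always re-evaluates the
  original image interpolant at new nodes, which is exact and
  unambiguous. Resampling from the previous coarse field instead is not
  offered because it accumulates interpolation error with no benefit at
  image resolution.
* Confusion-matrix metrics raise on undefined denominators instead of
  returning NaN; the folder evaluator reports `None` for a metric whose
  class is empty rather than failing the whole run.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on
200×200 phantoms (final meshes of ~30–50k triangles, ≈0.5–1 s per slice),
40-phantom cohorts for detection statistics and 10-phantom cohorts for
the γ-switch experiment; indicator and rasterization oracles run on
meshes of ≤50 and ≤1500 triangles respectively. These sizes were chosen
to exercise every mechanism at full fidelity while keeping a complete
verification run in the low minutes on a single core.

## Known limitations

* Slice-level decision only; no 3-D aggregation across slices.
* The 1% rule ties minimum detectable lesion size to image area (see
  above) — small lesions require lowering the decision threshold or the
  erosion count.
* γ must match the acquisition contrast; the automatic selection
  heuristic is simplistic and off by default.
* The marking threshold is quantile-anchored, so some refinement happens
  even in healthy slices (the cortex always attracts the estimator);
  robustness to that comes entirely from the erosion stage.
* Headline numbers on the public Kaggle MR collection are reproducible
  through `zzdetect evaluate` on a local download but are not part of the
  shipped verification, which is phantom-based.
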