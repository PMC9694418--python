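# zzdetect

Unsupervised detection of anomalous regions (tumors) in single brain-MR
slices, built on adaptive linear finite elements driven by a
Zienkiewicz–Zhu gradient-recovery error indicator, with γ-correction
pre-processing and morphological post-processing.

The package is for people who want a fully transparent, training-free
baseline for slice-level tumor screening: every step is a classical
numerical or image-processing primitive, every parameter has a physical
meaning, and the whole decision path — from pixel intensities to the
healthy/affected label and the lesion bounding box — can be inspected.

## Method

An m×n slice is rescaled to [0,1] and transformed pointwise, G = I^γ
(default γ = 4, which crushes mid-gray tissue towards black while keeping
bright structures bright; γ = 1/8 is the complementary setting for
T2-weighted slices with bright cerebrospinal fluid). The image is read as a
continuous piecewise-linear (P1) function on the pixel-grid triangulation,

    I(x) = Σ_k I_k φ_k(x),

then resampled onto a coarse uniform triangulation (default N_t = 1200
triangles). On each triangle T the Zienkiewicz–Zhu indicator

    η_T = ‖ G(Ĩ) − ∇Ĩ ‖_{L²(T)}

measures the distance between the element-wise constant gradient ∇Ĩ and
its recovered nodal field G, an area-weighted average over each vertex
star:

    G_k = Σ_{T ∋ k} (|T| / |T_k|) ∇Ĩ|_T ,   |T_k| = Σ_{T ∋ k} |T|.

Triangles whose indicator reaches cref · η_(t) (t = ⌈p·N_t⌉, defaults
p = 0.25, cref = 0.60) are marked and bisected (newest-vertex bisection
with conformity closure, which keeps the triangulation conforming and
isotropic — the minimum angle never degrades below half its initial
value). After the loop terminates, the smallest triangles sit where the
intensity varies most; rasterizing them yields a binary map b, which is
eroded six times with the 3×3 all-ones kernel. If less than 1% of pixels
stay white the slice is labelled *healthy*, otherwise *affected*, and the
surviving 8-connected components localize the lesion.

## Worked example

`examples/01_detect_single_slice.py` builds a 200×200 synthetic slice with
a bright lesion of radius 22 px centred at (row 110, col 90) and runs the
detector:

```
ground truth      : affected, lesion rows 88-132, cols 68-112
prediction        : affected
white fraction    : 0.0297 (healthy below 0.01)
largest region    : rows 91-129, cols 72-109, 1018 px
final mesh        : 45942 triangles
```

2.97% of pixels survive the six erosions — far above the 1% rule — so the
slice is called affected, and the largest surviving component reproduces
the lesion's bounding box to within a few pixels. The other examples show
the refinement log (`02`), the bright-CSF confounder and its γ = 1/8
correction (`03`), and cohort evaluation (`04`).

The same pipeline is available from the shell:

```sh
zzdetect simulate --healthy 5 --affected 5 --out cohort/
zzdetect detect cohort/affected/phantom_005.png --out results/
zzdetect evaluate cohort/ --out report.json
```

`evaluate` also accepts the `yes/`/`no/` folder layout used by the public
brain-MRI tumor-detection collection on Kaggle, so the full-dataset
experiment can be replicated by pointing it at a local download.

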