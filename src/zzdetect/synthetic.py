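"""Brain-like phantom slices with known ground truth.

The phantoms are geometric, not anatomical: an elliptic bright cortex ring
around smooth gray interior tissue on an exactly black background, optionally
a compact bright (or dark) lesion blob and a ventricle-like bright structure
mimicking T2 cerebrospinal-fluid contrast.  That is sufficient because the
detector responds only to intensity-gradient structure.  Two modelling
choices matter:

* Additive Gaussian noise is applied inside the brain only and the
  background stays exactly black, emulating display-windowed MR exports
  whose air region is clipped to zero.  Noise on a truly black background
  would explode under the brightening gamma = 1/8 transform (the power map
  has infinite slope at zero) in a way real exported slices do not show.
* Lesions carry the same pixel noise as the rest of the brain; under
  gamma = 4 that texture is amplified (d/dI I^4 = 4 I^3 is large near 1), so
  the indicator keeps firing throughout the lesion area, not only on its
  rim -- the mechanism the detector relies on for real heterogeneous tumors.

All randomness flows through one seeded generator, so a spec generates a
bitwise-reproducible image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .binmap import BinaryMask
from .errors import InputError
from .postprocess import AFFECTED, HEALTHY
from .preprocess import GrayImage

__all__ = ["LesionSpec", "PhantomSpec", "generate", "generate_cohort", "Cohort"]


@dataclass
class LesionSpec:
    """Compact circular lesion: center (row, col), radius in pixels, peak
    intensity (bright >= 0.9 or dark <= 0.05)."""

    center: tuple[float, float]
    radius: float
    intensity: float = 0.95


@dataclass
class PhantomSpec:
    """Geometry and contrast of one phantom slice.

    Intensities follow typical T1-like contrast on [0, 1]: black air, ~0.35
    interior tissue with a low-frequency modulation, a ~0.85 cortex ring.
    ``csf_intensity``/``csf_axes`` switch on a central bright ventricle-like
    ellipse (the T2 bright-CSF confounder).
    """

    m: int = 200
    n: int = 200
    cortex_intensity: float = 0.85
    cortex_axes: tuple[float, float] = (88.0, 80.0)  # (semi-ry, semi-rx), pixels
    cortex_width: float = 7.0
    tissue_intensity: float = 0.35
    tissue_modulation: float = 0.04
    modulation_scale: float = 15.0
    lesion: Optional[LesionSpec] = None
    csf_bright: bool = False
    csf_intensity: float = 0.92
    csf_axes: tuple[float, float] = (31.0, 17.0)
    noise_sigma: float = 0.02
    smoothing_sigma: float = 1.0
    seed: int = 0


def _ellipse_mask(m: int, n: int, center: tuple[float, float], ry: float, rx: float) -> np.ndarray:
    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]
    return ((rows - center[0]) / ry) ** 2 + ((cols - center[1]) / rx) ** 2 <= 1.0


def generate(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask, str]:
    """Render one phantom; returns (image, lesion ground truth, label).

    The ground truth marks exactly the pixel centers within the lesion
    radius (all black for healthy phantoms); the label is consistent with
    lesion presence.  Deterministic for a fixed spec.
    """
    m, n = spec.m, spec.n
    if m < 16 or n < 16:
        raise InputError("phantom must be at least 16x16")
    center = ((m - 1) / 2.0, (n - 1) / 2.0)
    ry, rx = spec.cortex_axes
    w = spec.cortex_width
    outer = _ellipse_mask(m, n, center, ry, rx)
    inner = _ellipse_mask(m, n, center, ry - w, rx - w)

    rng = np.random.default_rng(spec.seed)
    base = np.zeros((m, n))
    modulation = ndimage.gaussian_filter(rng.standard_normal((m, n)), spec.modulation_scale)
    scale = np.abs(modulation).max()
    if scale > 0:
        modulation *= spec.tissue_modulation / scale
    base[inner] = spec.tissue_intensity + modulation[inner]
    base[outer & ~inner] = spec.cortex_intensity

    if spec.csf_bright:
        csf = _ellipse_mask(m, n, center, spec.csf_axes[0], spec.csf_axes[1])
        base[csf] = spec.csf_intensity

    truth = np.zeros((m, n), dtype=np.uint8)
    if spec.lesion is not None:
        les = spec.lesion
        r = les.radius
        if r <= 0:
            raise InputError("lesion radius must be positive")
        # strict containment inside the inner cortex ellipse
        norm = ((les.center[0] - center[0]) / (ry - w - r)) ** 2 + (
            (les.center[1] - center[1]) / (rx - w - r)
        ) ** 2
        if ry - w - r <= 0 or rx - w - r <= 0 or norm >= 1.0:
            raise InputError("lesion does not fit strictly inside the cortex")
        rows = np.arange(m)[:, None]
        cols = np.arange(n)[None, :]
        disk = (rows - les.center[0]) ** 2 + (cols - les.center[1]) ** 2 <= r**2
        base[disk] = les.intensity
        truth[disk] = 1

    img = ndimage.gaussian_filter(base, spec.smoothing_sigma)
    if spec.noise_sigma > 0:
        brain = img > 0.02  # noise models tissue texture; exported air stays black
        noise = rng.normal(0.0, spec.noise_sigma, size=(m, n))
        img = img + noise * brain
    img = np.clip(img, 0.0, 1.0)
    label = AFFECTED if spec.lesion is not None else HEALTHY
    return GrayImage(img), BinaryMask(truth), label


@dataclass
class Cohort:
    """A reproducible labeled phantom set."""

    images: list[GrayImage]
    truths: list[BinaryMask]
    labels: list[str]
    specs: list[PhantomSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def _random_spec(rng: np.random.Generator, affected: bool, csf_bright: bool, base: PhantomSpec) -> PhantomSpec:
    """Draw one phantom spec from the documented parameter ranges."""
    spec = replace(base, seed=int(rng.integers(0, 2**31 - 1)), csf_bright=csf_bright)
    center = ((spec.m - 1) / 2.0, (spec.n - 1) / 2.0)
    if affected:
        radius = float(rng.uniform(0.095, 0.13)) * spec.n
        ry_in = spec.cortex_axes[0] - spec.cortex_width - radius - 2.0
        rx_in = spec.cortex_axes[1] - spec.cortex_width - radius - 2.0
        # uniform offset within 70% of the shrunken inner ellipse
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = 0.7 * np.sqrt(rng.uniform(0.0, 1.0))
        lesion_center = (
            center[0] + rad * ry_in * np.sin(ang),
            center[1] + rad * rx_in * np.cos(ang),
        )
        spec = replace(
            spec,
            lesion=LesionSpec(
                center=lesion_center,
                radius=radius,
                intensity=float(rng.uniform(0.92, 0.98)),
            ),
        )
    return spec


def generate_cohort(
    n_healthy: int,
    n_affected: int,
    seed: int = 0,
    csf_bright: bool = False,
    base: PhantomSpec | None = None,
) -> Cohort:
    """Generate ``n_healthy`` + ``n_affected`` phantoms reproducibly.

    Affected phantoms carry one bright lesion with radius drawn from
    9.5-13% of the image width, placed uniformly inside the brain;
    ``csf_bright`` adds the T2-like bright ventricle structure to every
    phantom (used for the gamma = 1/8 scenario).
    """
    if n_healthy < 0 or n_affected < 0:
        raise InputError("cohort counts must be >= 0")
    base = base if base is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = Cohort(images=[], truths=[], labels=[], specs=[])
    flags = [False] * n_healthy + [True] * n_affected
    for affected in flags:
        spec = _random_spec(rng, affected, csf_bright, base)
        img, truth, label = generate(spec)
        cohort.images.append(img)
        cohort.truths.append(truth)
        cohort.labels.append(label)
        cohort.specs.append(spec)
    return cohort
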