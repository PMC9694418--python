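"""Image loading, [0,1] rescaling and gamma correction.

MR export slices arrive as 8-bit PNG/JPEG, sometimes RGB.  They are collapsed
to luminance, min-max rescaled to [0,1] and then passed through a pointwise
power transform G = I**gamma.  With the default gamma = 4 the transform
crushes mid-gray tissue towards black while keeping bright structures bright,
which is what lets the error indicator single out lesions; gamma = 1/8 is the
complementary setting for T2-weighted slices whose cerebrospinal fluid is
bright and would otherwise be mistaken for an anomaly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigError, InputError

__all__ = ["GrayImage", "GammaConfig", "load_gray", "to_gray_image", "gamma_correct", "select_gamma"]

# Rec. 601 luminance weights, the convention PIL's "L" mode uses.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """An m x n grid of intensities in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("GrayImage requires a 2-D array")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise InputError(f"image must be at least 2x2, got {m}x{n}")
        if np.any(~np.isfinite(self.values)):
            raise InputError("image contains non-finite values")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise InputError("intensities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class GammaConfig:
    """Gamma-correction settings.

    gamma: exponent applied by default (4 darkens midtones).
    gamma_alt: exponent for bright-CSF T2 slices (1/8 brightens/flattens).
    auto: opt-in heuristic switching gamma -> gamma_alt when the bright
        fraction inside the brain bounding box exceeds the cutoff.  Off by
        default: the exponent choice is a user decision.
    """

    gamma: float = 4.0
    gamma_alt: float = 0.125
    auto: bool = False
    bright_threshold: float = 0.8
    bright_fraction_cutoff: float = 0.3

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gamma_alt <= 0:
            raise ConfigError("gamma exponents must be positive")
        if not (0 < self.bright_threshold < 1):
            raise ConfigError("bright_threshold must lie in (0, 1)")
        if not (0 < self.bright_fraction_cutoff < 1):
            raise ConfigError("bright_fraction_cutoff must lie in (0, 1)")


def _rescale(raw: np.ndarray) -> np.ndarray:
    lo = raw.min()
    hi = raw.max()
    if hi - lo <= 0:
        # a constant slice carries no edges; map it to black
        return np.zeros_like(raw, dtype=np.float64)
    return (raw - lo) / (hi - lo)


def to_gray_image(raw: np.ndarray) -> GrayImage:
    """Collapse channels to luminance and min-max rescale to [0, 1]."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[:, :, :3]
        if raw.shape[2] == 3:
            raw = raw @ _LUMA
        elif raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raise InputError(f"unsupported channel count {raw.shape[2]}")
    elif raw.ndim != 2:
        raise InputError("expected a 2-D or 3-D image array")
    if raw.size == 0:
        raise InputError("zero-sized image")
    return GrayImage(_rescale(raw))


def load_gray(path) -> GrayImage:
    """Read PNG/JPEG/BMP/TIFF, gray-convert and rescale so min->0, max->1."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            raw = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    return to_gray_image(raw)


def gamma_correct(img: GrayImage, cfg: GammaConfig | float) -> GrayImage:
    """Pointwise power transform G = I**gamma.

    Monotone nondecreasing, fixes 0 and 1; gamma > 1 darkens, gamma < 1
    brightens every intermediate intensity.
    """
    gamma = cfg.gamma if isinstance(cfg, GammaConfig) else float(cfg)
    if gamma <= 0:
        raise ConfigError("gamma must be positive")
    return GrayImage(np.power(img.values, gamma))


def select_gamma(img: GrayImage, cfg: GammaConfig) -> float:
    """Return the exponent to use for ``img``.

    With ``cfg.auto`` off (the default) this is simply ``cfg.gamma``.  With
    it on, the fraction of pixels brighter than ``bright_threshold`` inside
    the brain bounding box (the tight box around pixels above a small floor)
    is compared against ``bright_fraction_cutoff``; a high bright fraction is
    the signature of a T2 slice with bright CSF and selects ``gamma_alt``.
    """
    if not cfg.auto:
        return cfg.gamma
    v = img.values
    fg = v > 0.05
    if not fg.any():
        return cfg.gamma
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    box = v[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    bright_fraction = float((box > cfg.bright_threshold).mean())
    return cfg.gamma_alt if bright_fraction > cfg.bright_fraction_cutoff else cfg.gamma
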