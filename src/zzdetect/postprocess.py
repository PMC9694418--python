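"""Morphological post-processing and the healthy/affected decision.

The raw binary map traces every rapidly varying structure, including the
cortex outline and scattered noise.  Repeated binary erosion with the 3x3
all-ones structuring element (a pixel stays white only if its whole 3x3
neighbourhood is white; outside the image counts as background) removes thin
curves and specks while compact lesion blobs survive.  If afterwards less
than a threshold fraction of pixels (default 1%) is white the slice is
labelled healthy, otherwise affected, and the surviving 8-connected white
components are reported as candidate lesion regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .binmap import BinaryMask
from .errors import InputError

__all__ = ["Region", "DetectionResult", "erode", "classify", "HEALTHY", "AFFECTED"]

HEALTHY = "healthy"
AFFECTED = "affected"

_KERNEL = np.ones((3, 3), dtype=bool)


@dataclass
class Region:
    """Inclusive bounding box of one connected white component."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    pixels: int

    def intersects_box(self, row_min: int, row_max: int, col_min: int, col_max: int) -> bool:
        return not (
            self.row_max < row_min
            or row_max < self.row_min
            or self.col_max < col_min
            or col_max < self.col_min
        )

    def to_dict(self) -> dict:
        return {
            "row_min": self.row_min,
            "row_max": self.row_max,
            "col_min": self.col_min,
            "col_max": self.col_max,
            "pixels": self.pixels,
        }


@dataclass
class DetectionResult:
    """Final label, post-processed mask and lesion candidate regions."""

    label: str
    mask: BinaryMask
    white_fraction: float
    regions: list[Region] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "white_fraction": self.white_fraction,
            "regions": [r.to_dict() for r in self.regions],
        }


def erode(mask: BinaryMask, iterations: int = 6) -> BinaryMask:
    """Binary erosion with the 3x3 ones kernel, border treated as background.

    Anti-extensive and composable: erode(erode(x, a), b) == erode(x, a + b).
    """
    if iterations < 0:
        raise InputError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.values.copy())
    out = ndimage.binary_erosion(
        mask.values.astype(bool), structure=_KERNEL, iterations=iterations, border_value=0
    )
    return BinaryMask(out.astype(np.uint8))


def classify(mask: BinaryMask, threshold: float = 0.01) -> DetectionResult:
    """Label healthy iff the white fraction is below ``threshold``.

    The fraction is computed over all m*n pixels.  Regions are the
    8-connected components of the white set, reported regardless of label so
    near-threshold cases stay inspectable.
    """
    if not (0 <= threshold <= 1):
        raise InputError("threshold must lie in [0, 1]")
    wf = mask.white_fraction
    label = HEALTHY if wf < threshold else AFFECTED
    labeled, ncomp = ndimage.label(mask.values, structure=_KERNEL)
    regions = []
    for sl_idx, sl in enumerate(ndimage.find_objects(labeled), start=1):
        if sl is None:
            continue
        count = int((labeled[sl] == sl_idx).sum())
        regions.append(
            Region(
                row_min=sl[0].start,
                row_max=sl[0].stop - 1,
                col_min=sl[1].start,
                col_max=sl[1].stop - 1,
                pixels=count,
            )
        )
    regions.sort(key=lambda r: r.pixels, reverse=True)
    return DetectionResult(label=label, mask=mask, white_fraction=wf, regions=regions)
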