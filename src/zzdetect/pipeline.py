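"""End-to-end detection pipeline and folder evaluation.

detect: gamma-correct -> adaptive Z2 refinement -> minimal-area binary map
-> erosion -> 1% decision.  evaluate: run detect over a labeled image set
and tally the confusion metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import metrics as metrics_mod
from .binmap import BinaryMask, minimal_area_triangles, rasterize
from .errors import ConfigError, InputError
from .estimator import AdaptResult, MarkingConfig, adapt
from .postprocess import AFFECTED, HEALTHY, DetectionResult, classify, erode
from .preprocess import GammaConfig, GrayImage, gamma_correct, load_gray, select_gamma
from .synthetic import Cohort

__all__ = ["PipelineConfig", "PipelineOutput", "detect_image", "detect_file", "evaluate_cohort", "evaluate_dir"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, serializable bundle of every pipeline parameter.

    Defaults are the reference settings of the method: gamma = 4 (with 1/8
    as the bright-CSF alternative), a 1200-triangle coarse mesh, marking
    parameters p = 0.25 and cref = 0.60, up to 8 adaptive iterations, 6
    erosion passes and a 1% white-pixel decision rule.  ``min_area_rel_tol``
    (window of the minimal-area selection on the bisection area ladder) and
    ``raster_mode`` control how the final mesh is turned into pixels.
    """

    gamma: float = 4.0
    gamma_alt: float = 0.125
    auto_gamma: bool = False
    bright_threshold: float = 0.8
    bright_fraction_cutoff: float = 0.3
    nt: int = 1200
    p: float = 0.25
    cref: float = 0.60
    eta_stop: float | None = None
    max_iter: int = 8
    anchor: str = "largest"
    min_area_rel_tol: float = 7.5
    raster_mode: str = "cover"
    erosions: int = 6
    decision_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erosions < 0 or self.erosions > 6:
            raise ConfigError("erosions must lie in 0..6")
        if not (0 <= self.decision_threshold <= 1):
            raise ConfigError("decision_threshold must lie in [0, 1]")
        # delegate range checks to the component configs
        self.gamma_config()
        self.marking_config()

    def gamma_config(self) -> GammaConfig:
        return GammaConfig(
            gamma=self.gamma,
            gamma_alt=self.gamma_alt,
            auto=self.auto_gamma,
            bright_threshold=self.bright_threshold,
            bright_fraction_cutoff=self.bright_fraction_cutoff,
        )

    def marking_config(self) -> MarkingConfig:
        return MarkingConfig(
            p=self.p,
            cref=self.cref,
            eta_stop=self.eta_stop,
            max_iter=self.max_iter,
            anchor=self.anchor,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineOutput:
    """DetectionResult plus the intermediate artifacts useful for inspection."""

    result: DetectionResult
    gamma_used: float
    raw_mask: BinaryMask
    adapt_result: AdaptResult
    corrected: GrayImage | None = None


def detect_image(img: GrayImage, cfg: PipelineConfig | None = None) -> PipelineOutput:
    """Run the full pipeline on an in-memory grayscale image."""
    cfg = cfg if cfg is not None else PipelineConfig()
    gamma = select_gamma(img, cfg.gamma_config())
    corrected = gamma_correct(img, gamma)
    ar = adapt(corrected, nt=cfg.nt, cfg=cfg.marking_config())
    if ar.history:
        selected = minimal_area_triangles(ar.areas, rel_tol=cfg.min_area_rel_tol)
    else:
        # the loop stopped before refining anything (e.g. a uniform image
        # with eta == 0): no triangle was ever singled out, so the map is
        # empty rather than "every triangle is minimal"
        selected = np.empty(0, dtype=np.int64)
    raw = rasterize(ar.mesh, selected, img.m, img.n, mode=cfg.raster_mode)
    eroded = erode(raw, iterations=cfg.erosions)
    result = classify(eroded, threshold=cfg.decision_threshold)
    return PipelineOutput(
        result=result, gamma_used=gamma, raw_mask=raw, adapt_result=ar, corrected=corrected
    )


def write_diagnostics(out: PipelineOutput, out_dir, stem: str) -> None:
    """Write inspection figures: the gamma-corrected interpolant, the final
    mesh colored by triangle area (log scale) and the raw binary map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mesh = out.adapt_result.mesh
    corrected = (
        out.corrected.values if out.corrected is not None else np.zeros(out.raw_mask.values.shape)
    )
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))
    axes[0].imshow(corrected, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title(f"gamma-corrected input (gamma={out.gamma_used:g})")
    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    pc = axes[1].tripcolor(tri, np.log10(out.adapt_result.areas.values), cmap="viridis")
    axes[1].invert_yaxis()
    axes[1].set_aspect("equal")
    axes[1].set_title(f"final mesh, log10 area ({mesh.num_triangles} triangles)")
    fig.colorbar(pc, ax=axes[1], shrink=0.8)
    axes[2].imshow(out.raw_mask.values, cmap="gray", vmin=0, vmax=1)
    axes[2].set_title(f"binary map (white {out.raw_mask.white_fraction:.2%})")
    for ax in (axes[0], axes[2]):
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_dir / f"{stem}_diagnostics.png", dpi=110)
    plt.close(fig)


def detect_file(path, cfg: PipelineConfig | None = None, out_dir=None, diagnostics: bool = False) -> PipelineOutput:
    """Load an image file, run detection, optionally write artifacts.

    Artifacts: the post-processed mask and raw binary map as PNG, the
    detection record (label, white fraction, regions, per-iteration log) as
    JSON; with ``diagnostics`` also the inspection figure from
    :func:`write_diagnostics`.
    """
    img = load_gray(path)
    out = detect_image(img, cfg)
    if out_dir is not None:
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(path).stem
        Image.fromarray(out.result.mask.to_png_array()).save(out_dir / f"{stem}_mask.png")
        Image.fromarray(out.raw_mask.to_png_array()).save(out_dir / f"{stem}_binmap.png")
        record = out.result.to_dict()
        record["gamma_used"] = out.gamma_used
        record["iterations"] = out.adapt_result.history
        (out_dir / f"{stem}_detection.json").write_text(json.dumps(record, indent=2) + "\n")
        if diagnostics:
            write_diagnostics(out, out_dir, stem)
    return out


def evaluate_cohort(cohort: Cohort, cfg: PipelineConfig | None = None) -> dict:
    """Detect every phantom in a cohort and report confusion metrics.

    The per-image records (label, prediction, white fraction, largest
    region) ride along under "records".
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    preds = []
    records = []
    for idx, (img, truth, label) in enumerate(zip(cohort.images, cohort.truths, cohort.labels)):
        out = detect_image(img, cfg)
        preds.append(out.result.label)
        rec = {
            "index": idx,
            "truth": label,
            "prediction": out.result.label,
            "white_fraction": out.result.white_fraction,
            "gamma_used": out.gamma_used,
        }
        if out.result.regions:
            rec["largest_region"] = out.result.regions[0].to_dict()
        records.append(rec)
    rep = metrics_mod.report(metrics_mod.confusion(preds, cohort.labels))
    rep["records"] = records
    return rep


def evaluate_dir(root, cfg: PipelineConfig | None = None) -> dict:
    """Evaluate a directory tree with class subfolders.

    ``root`` must contain ``affected/`` (or ``yes/``) and ``healthy/`` (or
    ``no/``) image folders -- the layout public brain-MR collections ship
    with.  Empty classes make the per-class metrics None, not an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"no such directory: {root}")
    folders = {AFFECTED: ("affected", "yes"), HEALTHY: ("healthy", "no")}
    preds, truths, records = [], [], []
    exts = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
    for label, names in folders.items():
        for name in names:
            sub = root / name
            if not sub.is_dir():
                continue
            for path in sorted(sub.iterdir()):
                if path.suffix.lower() not in exts:
                    continue
                out = detect_file(path, cfg)
                preds.append(out.result.label)
                truths.append(label)
                records.append(
                    {
                        "file": str(path),
                        "truth": label,
                        "prediction": out.result.label,
                        "white_fraction": out.result.white_fraction,
                    }
                )
    if not preds:
        raise InputError(f"no class folders with images found under {root}")
    rep = metrics_mod.report(metrics_mod.confusion(preds, truths))
    rep["records"] = records
    return rep
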