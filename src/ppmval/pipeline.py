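"""End-to-end orchestration: preprocess, register, transfer labels, report.

A run consumes the four images of a case (S_O, S_POI, H_O, annotated H_A)
plus parameters, and produces a run directory with every intermediate
artifact, the metrics, the tissue-label report, an overlay figure, and a
JSON log of all parameters and seeds.  Any stage failure aborts the run
with the failing stage named; partial outputs are kept.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import io as ppmio
from .label_extraction import (
    POISet,
    detect_pois,
    extract_labels,
    rasterize_poi_areas,
    warp_poi_mask,
)
from .preprocessing import (
    REG_HEIGHT,
    REG_WIDTH,
    GrayImage,
    SpecimenImage,
    resize_input,
    to_luminance_gray,
    to_saturation_gray,
)
from .registration import RegistrationConfig, estimate_ddf

logger = logging.getLogger("ppmval")

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline", "evaluate_cohort"]


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    s_o_path: str
    s_poi_path: str
    h_o_path: str
    annotation_path: str
    legend_path: str
    out_dir: str
    poi_radius: float = 6.0
    min_dot_area: int = 5
    bins: int = 32
    smoothness: float = 0.05
    levels: int = 3
    seed: int = 0
    histology_fixed: bool = True   # fixed = histology, moving = specimen (default)

    def validate(self) -> None:
        for name in ("s_o_path", "s_poi_path", "h_o_path", "annotation_path", "legend_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        if self.poi_radius <= 0:
            raise ValueError("poi_radius must be positive")
        if self.bins < 2:
            raise ValueError("bins must be at least 2")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = ppmio.read_json(path)
        data.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scale_pois(pois: POISet, src_shape: tuple[int, int],
                dst_shape: tuple[int, int]) -> POISet:
    sy = dst_shape[0] / src_shape[0]
    sx = dst_shape[1] / src_shape[1]
    centers = pois.centers * np.array([sx, sy])
    return POISet(centers=centers, radius=pois.radius * 0.5 * (sx + sy))


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute preprocessing -> registration -> label extraction; return the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = (REG_HEIGHT, REG_WIDTH)

    try:
        config.validate()
    except Exception as e:
        raise PipelineError("config", e) from e

    stage = "preprocessing"
    try:
        s_o = SpecimenImage(pixels=ppmio.read_rgb(config.s_o_path), role="S_O")
        s_poi = SpecimenImage(pixels=ppmio.read_rgb(config.s_poi_path), role="S_POI")
        h_o_rgb = ppmio.read_rgb(config.h_o_path)
        so_sat = to_saturation_gray(s_o)
        ho_gray = to_luminance_gray(h_o_rgb)
        moving = resize_input(so_sat)
        fixed = resize_input(ho_gray)
        if not config.histology_fixed:
            fixed, moving = moving, fixed
        ppmio.write_gray(out / "so_sat.png", so_sat.pixels)
        ppmio.write_gray(out / "ho_gray.png", ho_gray.pixels)
        ppmio.write_gray(out / "moving.png", moving.pixels)
        ppmio.write_gray(out / "fixed.png", fixed.pixels)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "registration"
    try:
        reg_cfg = RegistrationConfig(
            bins=config.bins,
            smoothness=config.smoothness,
            levels=config.levels,
            seed=config.seed,
        )
        result = estimate_ddf(fixed, moving, reg_cfg)
        ppmio.write_ddf(out / "ddf.tif", result.field)
        ppmio.write_gray(out / "warped.png", result.warped.pixels)
        ppmio.write_json(out / "metrics.json", result.metrics())
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "label_extraction"
    try:
        annotation = ppmio.read_annotation(config.annotation_path, config.legend_path)
        pois = detect_pois(
            s_poi, s_o, radius=config.poi_radius, min_area=config.min_dot_area
        )
        ppmio.write_pois(out / "pois.csv", pois)
        grid_pois = _scale_pois(pois, s_poi.pixels.shape[:2], grid)
        poi_mask = rasterize_poi_areas(grid_pois, grid)
        warped_mask = warp_poi_mask(poi_mask, result.field)
        if annotation.labels.shape != grid:
            labels = resize(
                annotation.labels, grid, order=0, preserve_range=True,
                anti_aliasing=False,
            ).astype(annotation.labels.dtype)
            annotation = dataclasses.replace(annotation, labels=labels)
        report = extract_labels(warped_mask, annotation, pois=grid_pois)
        ppmio.write_indexed(out / "poi_mask.png", poi_mask)
        ppmio.write_indexed(out / "warped_mask.png", warped_mask)
        ppmio.write_label_report(out / "labels.csv", out / "labels.json", report)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "reporting"
    try:
        _write_overlay(out, fixed, moving, result.warped, warped_mask)
        ppmio.write_json(
            out / "run_log.json",
            {"config": dataclasses.asdict(config), "converged": result.converged},
        )
    except Exception as e:
        raise PipelineError(stage, e) from e

    logger.info("run complete: %s", out)
    return out


def _write_overlay(out: Path, fixed: GrayImage, moving: GrayImage,
                   warped: GrayImage, warped_mask: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, (img, title) in zip(
        axes,
        [
            (np.dstack([moving.pixels, fixed.pixels, moving.pixels]), "before (moving/fixed)"),
            (np.dstack([warped.pixels, fixed.pixels, warped.pixels]), "after (warped/fixed)"),
            (fixed.pixels, "measurement areas on fixed"),
        ],
    ):
        if img.ndim == 2:
            ax.imshow(img, cmap="gray")
            ys, xs = np.nonzero(warped_mask)
            ax.scatter(xs, ys, s=0.3, c="red")
        else:
            ax.imshow(img)
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "overlay.png", dpi=110)
    plt.close(fig)


def evaluate_cohort(run_dirs: Sequence[str | Path],
                    out_csv: str | Path | None = None) -> pd.DataFrame:
    """Collect per-run metrics and append median and IQR summary rows."""
    if len(run_dirs) == 0:
        raise ValueError("need at least one run directory")
    rows = []
    for d in run_dirs:
        m = ppmio.read_json(Path(d) / "metrics.json")
        rows.append(
            {
                "run": str(d),
                "dice_before": m["dice_before"],
                "dice_after": m["dice_after"],
                "mi_before": m["mi_before"],
                "mi_after": m["mi_after"],
            }
        )
    df = pd.DataFrame(rows)
    metric_cols = ["dice_before", "dice_after", "mi_before", "mi_after"]
    med = df[metric_cols].median()
    q1 = df[metric_cols].quantile(0.25)
    q3 = df[metric_cols].quantile(0.75)
    summary = pd.DataFrame(
        [
            {"run": "median", **med.to_dict()},
            {"run": "iqr", **(q3 - q1).to_dict()},
        ]
    )
    table = pd.concat([df, summary], ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
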