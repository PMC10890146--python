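"""File-format plumbing for the CLI and pipeline.

Conventions (documented in the README):

* depth frames: 16-bit grayscale PNG, value = depth in 0.1 mm steps,
  0 = invalid pixel; or delimited text (``.txt``/``.csv``) in mm;
* plane model / rigid transform / metrics: JSON;
* displacement fields: 2-plane float32 TIFF (plane 0 = u, plane 1 = v)
  with a JSON sidecar recording shape and the backward-warp convention;
* point pairs: CSV with columns xc, yc, zc, xp, yp, zp (mm);
* annotation maps: indexed 8-bit PNG plus a JSON legend;
* masks and gray images: 8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .label_extraction import AnnotationMap, POISet, TissueLabelReport
from .plane_calibration import DepthFrame, PlaneModel
from .projector_calibration import PointPair, RigidTransform
from .registration import DisplacementField

DEPTH_SCALE = 10.0  # png counts per mm


# -- depth frames -----------------------------------------------------------

def write_depth_frame(path: str | Path, frame: DepthFrame) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        counts = np.round(frame.values * DEPTH_SCALE).astype(np.int64)
        counts = np.clip(counts, 1, 65535)
        counts[~frame.valid_mask] = 0
        Image.fromarray(counts.astype(np.uint16)).save(path)
    else:
        vals = np.where(frame.valid_mask, frame.values, np.nan)
        np.savetxt(path, vals, fmt="%.6f", delimiter=",")


def read_depth_frame(path: str | Path) -> DepthFrame:
    path = Path(path)
    if path.suffix.lower() == ".png":
        counts = np.asarray(Image.open(path), dtype=np.float64)
        mask = counts > 0
        return DepthFrame(values=np.where(mask, counts / DEPTH_SCALE, 0.0), valid_mask=mask)
    vals = np.loadtxt(path, delimiter=",")
    mask = np.isfinite(vals)
    return DepthFrame(values=np.where(mask, vals, 0.0), valid_mask=mask)


# -- JSON models ------------------------------------------------------------

def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_plane(path: str | Path, plane: PlaneModel) -> None:
    write_json(path, plane.to_dict())


def read_plane(path: str | Path) -> PlaneModel:
    return PlaneModel.from_dict(read_json(path))


def write_transform(path: str | Path, t: RigidTransform) -> None:
    write_json(path, t.to_dict())


def read_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(read_json(path))


# -- point pairs ------------------------------------------------------------

PAIR_COLUMNS = ["xc", "yc", "zc", "xp", "yp", "zp"]


def write_point_pairs(path: str | Path, pairs: list[PointPair]) -> None:
    rows = [list(p.camera_point) + list(p.projector_point) for p in pairs]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, index=False)


def read_point_pairs(path: str | Path) -> list[PointPair]:
    df = pd.read_csv(path)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point-pair CSV missing columns: {missing}")
    return [
        PointPair(
            camera_point=(row.xc, row.yc, row.zc),
            projector_point=(row.xp, row.yp, row.zp),
        )
        for row in df.itertuples()
    ]


# -- displacement fields ----------------------------------------------------

def write_ddf(path: str | Path, fld: DisplacementField) -> None:
    path = Path(path)
    stack = np.stack([fld.u, fld.v]).astype(np.float32)
    tifffile.imwrite(path, stack)
    write_json(
        path.with_suffix(path.suffix + ".json"),
        {
            "planes": ["u", "v"],
            "shape": list(fld.shape),
            "convention": "backward: out(x, y) = moving(x + u, y + v)",
        },
    )


def read_ddf(path: str | Path) -> DisplacementField:
    stack = tifffile.imread(path).astype(np.float64)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError("DDF TIFF must contain exactly two planes (u, v)")
    return DisplacementField(u=stack[0], v=stack[1])


# -- rasters ----------------------------------------------------------------

def write_gray(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(path)


def read_rgb(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_rgb(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def write_indexed(path: str | Path, raster: np.ndarray) -> None:
    raster = np.asarray(raster)
    if raster.max() > 255:
        raise ValueError("indexed raster exceeds 8-bit range")
    Image.fromarray(raster.astype(np.uint8)).save(path)


def read_indexed(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int32)


def write_annotation(path: str | Path, legend_path: str | Path, ann: AnnotationMap) -> None:
    write_indexed(path, ann.labels)
    write_json(legend_path, {str(k): v for k, v in ann.legend.items()})


def read_annotation(path: str | Path, legend_path: str | Path) -> AnnotationMap:
    legend = {int(k): v for k, v in read_json(legend_path).items()}
    return AnnotationMap(labels=read_indexed(path), legend=legend)


# -- POIs and reports -------------------------------------------------------

def write_pois(path: str | Path, pois: POISet) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(1, len(pois) + 1),
            "x": pois.centers[:, 0],
            "y": pois.centers[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_pois(path: str | Path, radius: float) -> POISet:
    df = pd.read_csv(path)
    return POISet(centers=df[["x", "y"]].to_numpy(dtype=float), radius=radius)


def write_label_report(csv_path: str | Path, json_path: str | Path,
                       report: TissueLabelReport) -> None:
    pd.DataFrame(report.to_records()).to_csv(csv_path, index=False)
    write_json(json_path, report.to_dict())
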