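"""Measurement-location extraction and histology label transfer.

Projected measurement dots are found by differencing the snapshot with and
without projections, probe-sized disks are rasterized around the dot
centers, the disks are carried into histology space by the registration
displacement field (nearest-neighbor, same backward convention as the image
warp), and per-disk tissue-class percentages are read off the annotated
histology raster.

Coordinates are 0-based ``(x, y)`` = (column, row) with pixel centers at
integer positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

from .preprocessing import SpecimenImage, to_luminance_gray
from .registration import DisplacementField

__all__ = [
    "POISet",
    "AnnotationMap",
    "POILabel",
    "TissueLabelReport",
    "detect_pois",
    "rasterize_poi_areas",
    "warp_poi_mask",
    "extract_labels",
]

DEFAULT_MIN_AREA = 5


@dataclass
class POISet:
    """Measurement locations: dot centers (x, y) and one probe radius, in pixels."""

    centers: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        if self.centers.size == 0:
            raise ValueError("POISet requires at least one center")
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array of (x, y)")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")
        if not self.radius > 0:
            raise ValueError("probe radius must be positive")
        d2 = np.sum(
            (self.centers[:, None, :] - self.centers[None, :, :]) ** 2, axis=-1
        )
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 < 1e-12):
            raise ValueError("POI centers must be pairwise distinct")

    def __len__(self) -> int:
        return self.centers.shape[0]


@dataclass
class AnnotationMap:
    """Integer-coded tissue-class raster with a legend (code -> class name)."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation raster must be integer-coded")
        if self.labels.ndim != 2:
            raise ValueError("annotation raster must be 2-D")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"raster values missing from legend: {sorted(missing)}")


@dataclass
class POILabel:
    """Tissue-class percentages for one measurement area in histology space."""

    poi_id: int
    center: tuple[float, float] | None
    registered_center: tuple[float, float] | None
    n_pixels: int
    percentages: dict[str, float]
    outside_tissue: bool = False


@dataclass
class TissueLabelReport:
    entries: list[POILabel] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        rows = []
        for e in self.entries:
            for cls, pct in e.percentages.items():
                rows.append(
                    {
                        "poi_id": e.poi_id,
                        "class": cls,
                        "percent": pct,
                        "outside_tissue": e.outside_tissue,
                    }
                )
        return rows

    def to_dict(self) -> dict:
        return {
            "pois": [
                {
                    "poi_id": e.poi_id,
                    "center": list(e.center) if e.center is not None else None,
                    "registered_center": (
                        list(e.registered_center)
                        if e.registered_center is not None
                        else None
                    ),
                    "n_pixels": e.n_pixels,
                    "percentages": e.percentages,
                    "outside_tissue": e.outside_tissue,
                }
                for e in self.entries
            ]
        }


def detect_pois(
    s_poi: SpecimenImage,
    s_o: SpecimenImage,
    radius: float = 5.0,
    min_area: int = DEFAULT_MIN_AREA,
    n_sigma: float = 3.0,
) -> POISet:
    """Locate projected dots as bright blobs in the S_POI minus S_O difference.

    The luminance difference is thresholded at mean + ``n_sigma`` * SD,
    connected components smaller than ``min_area`` pixels are discarded, and
    the component centroids become the POI centers.  ``radius`` is attached
    to the returned set as the probe radius (it is a property of the probe,
    not of the dots).

    Components much larger than the typical dot are reported with a warning
    as probable merges of overlapping dots.
    """
    if s_poi.pixels.shape != s_o.pixels.shape:
        raise ValueError("S_POI and S_O must have identical dimensions")
    diff = to_luminance_gray(s_poi.pixels).pixels - to_luminance_gray(s_o.pixels).pixels
    thr = float(diff.mean() + n_sigma * diff.std())
    blobs = measure.label(diff > thr, connectivity=2)
    props = [p for p in measure.regionprops(blobs) if p.area >= min_area]
    if not props:
        raise ValueError("no projected measurement dots detected")
    areas = np.array([p.area for p in props], dtype=float)
    merged = [p.label for p in props if p.area > 1.5 * np.median(areas)]
    if merged:
        warnings.warn(
            f"components {merged} are much larger than the typical dot; "
            "overlapping dots may have merged",
            RuntimeWarning,
            stacklevel=2,
        )
    centers = np.array([(p.centroid[1], p.centroid[0]) for p in props])
    return POISet(centers=centers, radius=radius)


def rasterize_poi_areas(pois: POISet, shape: tuple[int, int]) -> np.ndarray:
    """Indexed raster of probe disks: pixel value k marks POI k's disk (1-based).

    Membership is pixel-center-inside-circle.  Disks extending past the
    raster or overlapping each other are errors: measurement areas must be
    distinct and fully observed.
    """
    h, w = shape
    r = pois.radius
    for cx, cy in pois.centers:
        if cx - r < -0.5 or cx + r > w - 0.5 or cy - r < -0.5 or cy + r > h - 0.5:
            raise ValueError(f"POI disk at ({cx}, {cy}) exceeds image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros(shape, dtype=np.int32)
    for k, (cx, cy) in enumerate(pois.centers, start=1):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        if np.any(out[disk] != 0):
            raise ValueError(f"POI disk {k} overlaps another measurement area")
        out[disk] = k
    return out


def warp_poi_mask(mask: np.ndarray, fld: DisplacementField) -> np.ndarray:
    """Carry an indexed mask through the DDF (nearest-neighbor backward warp).

    Label codes are preserved exactly; disks deform with the field, so the
    output areas live in histology space.
    """
    mask = np.asarray(mask)
    if mask.shape != fld.shape:
        raise ValueError("mask dimensions must match the displacement field")
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + fld.v, xx + fld.u])
    return map_coordinates(mask, coords, order=0, mode="nearest")


def extract_labels(
    warped_mask: np.ndarray,
    annotation: AnnotationMap,
    pois: POISet | None = None,
    background_label: int = 0,
) -> TissueLabelReport:
    """Per-POI tissue-class percentages from the annotated histology raster.

    For POI k, the percentage of class c is 100 * (disk-k pixels annotated c)
    / (disk-k pixels); every legend class is reported, including at 0%.
    Disks landing entirely on background are flagged, not dropped.
    """
    warped_mask = np.asarray(warped_mask)
    if warped_mask.shape != annotation.labels.shape:
        raise ValueError("mask and annotation dimensions must match")
    n_poi = int(warped_mask.max())
    if n_poi == 0:
        raise ValueError("warped mask contains no measurement areas")
    report = TissueLabelReport()
    class_codes = sorted(annotation.legend)
    for k in range(1, n_poi + 1):
        sel = warped_mask == k
        n = int(sel.sum())
        center = None
        if pois is not None and k - 1 < len(pois):
            center = tuple(float(v) for v in pois.centers[k - 1])
        if n == 0:
            warnings.warn(
                f"POI {k} vanished under the deformation; no pixels to label",
                RuntimeWarning,
                stacklevel=2,
            )
            report.entries.append(
                POILabel(
                    poi_id=k,
                    center=center,
                    registered_center=None,
                    n_pixels=0,
                    percentages={},
                    outside_tissue=True,
                )
            )
            continue
        vals = annotation.labels[sel]
        pct = {
            annotation.legend[c]: 100.0 * int(np.sum(vals == c)) / n
            for c in class_codes
        }
        ys, xs = np.nonzero(sel)
        bg_name = annotation.legend.get(background_label)
        outside = bg_name is not None and pct.get(bg_name, 0.0) >= 100.0 - 1e-9
        report.entries.append(
            POILabel(
                poi_id=k,
                center=center,
                registered_center=(float(xs.mean()), float(ys.mean())),
                n_pixels=n,
                percentages=pct,
                outside_tissue=outside,
            )
        )
    return report
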