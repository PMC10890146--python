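"""Base-plane calibration for downward-facing depth cameras.

The work surface under the camera is rarely perfectly horizontal, so raw
depth frames contain a global tilt.  This module fits the plane model

    a*x + b*y + z + c = 0

to (averaged) depth frames by linear least squares on the vertical residual
and corrects depth values pixel-wise with

    z_new = z + a*x + b*y + c

so that base-plane pixels map to zero and object heights become absolute.

Coordinates are pixel indices: ``x`` is the column, ``y`` is the row, both
0-based.  Slopes ``a`` and ``b`` are therefore mm per pixel unless the
caller rescales coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DepthFrame",
    "PlaneModel",
    "DegenerateGeometryError",
    "average_depth_frames",
    "fit_base_plane",
    "correct_depth",
]

DEFAULT_N_SAMPLES = 10_000


class DegenerateGeometryError(ValueError):
    """Raised when the sampled points cannot determine a unique plane."""


@dataclass
class DepthFrame:
    """A 2-D grid of depth values in mm with a validity mask.

    Invalid pixels (sensor dropouts, out-of-range returns) are excluded from
    every computation via ``valid_mask``.
    """

    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("depth values must be a non-empty 2-D grid")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("depth values must be finite where valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        z_min: float | None = None,
        z_max: float | None = None,
    ) -> "DepthFrame":
        """Build a frame gating validity to finite values inside [z_min, z_max]."""
        values = np.asarray(values, dtype=np.float64)
        mask = np.isfinite(values)
        if z_min is not None:
            mask &= values >= z_min
        if z_max is not None:
            mask &= values <= z_max
        safe = np.where(mask, values, 0.0)
        return cls(values=safe, valid_mask=mask)


@dataclass(frozen=True)
class PlaneModel:
    """Parameters (a, b, c) of the base-plane model a*x + b*y + z + c = 0."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"plane parameter {name!r} must be finite")

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Depth of the ideal plane at (x, y): z = -(a*x + b*y + c)."""
        return -(self.a * np.asarray(x) + self.b * np.asarray(y) + self.c)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneModel":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]))


def average_depth_frames(frames: Sequence[DepthFrame]) -> DepthFrame:
    """Per-pixel mean of a stack of equally sized depth frames.

    A pixel is valid in the result only if it is valid in every input frame;
    invalid output pixels are set to 0.
    """
    if len(frames) == 0:
        raise ValueError("need at least one depth frame to average")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("all depth frames must have identical dimensions")
    stack = np.stack([f.values for f in frames])
    mask = np.logical_and.reduce([f.valid_mask for f in frames])
    mean = stack.mean(axis=0)
    return DepthFrame(values=np.where(mask, mean, 0.0), valid_mask=mask)


def _sample_points(
    depth: DepthFrame, n_samples: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(depth.valid_mask)
    n_valid = rows.size
    if n_valid > n_samples:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_valid, size=n_samples, replace=False)
        idx.sort()  # fit must not depend on draw order
        rows, cols = rows[idx], cols[idx]
    z = depth.values[rows, cols]
    return cols.astype(np.float64), rows.astype(np.float64), z


def fit_base_plane(
    depth: DepthFrame,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> PlaneModel:
    """Least-squares fit of (a, b, c) minimizing mean (a*x + b*y + z + c)^2.

    Points are drawn uniformly without replacement from the valid pixels
    (all of them if fewer than ``n_samples``).  The objective is linear in
    the parameters, so the solve is the exact linear least-squares solution.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 valid points are available or the sampled (x, y)
        locations are collinear.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    x, y, z = _sample_points(depth, n_samples, seed)
    if x.size < 3:
        raise DegenerateGeometryError("need at least 3 valid depth points")
    xy = np.column_stack([x, y])
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(xy).max())) < 2:
        raise DegenerateGeometryError("sampled points are collinear in (x, y)")
    # a*x + b*y + c = -z  in the least-squares sense
    design = np.column_stack([x, y, np.ones_like(x)])
    params, *_ = np.linalg.lstsq(design, -z, rcond=None)
    return PlaneModel(a=float(params[0]), b=float(params[1]), c=float(params[2]))


def plane_residual_rms(depth: DepthFrame, plane: PlaneModel) -> float:
    """RMS of the vertical residual a*x + b*y + z + c over valid pixels."""
    rows, cols = np.nonzero(depth.valid_mask)
    z = depth.values[rows, cols]
    r = plane.a * cols + plane.b * rows + z + plane.c
    return float(np.sqrt(np.mean(r**2)))


def correct_depth(depth: DepthFrame, plane: PlaneModel) -> DepthFrame:
    """Tilt-correct a depth frame: z_new = z + a*x + b*y + c at every valid pixel.

    Invalid pixels keep their stored value; the mask is unchanged.
    """
    h, w = depth.shape
    yy, xx = np.mgrid[0:h, 0:w]
    corrected = depth.values + plane.a * xx + plane.b * yy + plane.c
    out = np.where(depth.valid_mask, corrected, depth.values)
    return DepthFrame(values=out, valid_mask=depth.valid_mask.copy())
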