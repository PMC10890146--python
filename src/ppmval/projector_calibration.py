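"""Rigid camera-to-projector transform estimation from 3-D point pairs.

A point ``p_c`` in camera space maps to projector space as ``R @ p_c + T``
with ``R`` a proper rotation and ``T`` a translation in mm.  The estimator
is the closed-form orthogonal Procrustes (Kabsch) solution, optionally
polished with a derivative-free simplex refinement; accuracy is summarised
as the RMSE between mapped camera points and the observed projector points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "PointPair",
    "RigidTransform",
    "DegeneratePairsError",
    "apply_transform",
    "estimate_transform",
    "calibration_rmse",
]

_ORTHO_TOL = 1e-8


class DegeneratePairsError(ValueError):
    """Raised when point pairs cannot determine a unique rigid transform."""


@dataclass(frozen=True)
class PointPair:
    """A corresponding 3-D point in camera space and projector space (mm)."""

    camera_point: tuple[float, float, float]
    projector_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("camera_point", "projector_point"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"{name} must be a finite 3-vector")


@dataclass
class RigidTransform:
    """Rotation ``R`` (3x3) and translation ``T`` (3-vector, mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64)
        self.T = np.asarray(self.T, dtype=np.float64).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=_ORTHO_TOL):
            raise ValueError("R must be a proper rotation (det = +1)")
        if not np.all(np.isfinite(self.T)):
            raise ValueError("T must be finite")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(R=np.eye(3), T=np.zeros(3))

    def to_dict(self) -> dict:
        return {"R": self.R.ravel().tolist(), "T": self.T.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(R=np.asarray(d["R"], dtype=float).reshape(3, 3),
                   T=np.asarray(d["T"], dtype=float))


def _as_arrays(pairs: Sequence[PointPair]) -> tuple[np.ndarray, np.ndarray]:
    cam = np.array([p.camera_point for p in pairs], dtype=np.float64)
    proj = np.array([p.projector_point for p in pairs], dtype=np.float64)
    return cam, proj


def apply_transform(t: RigidTransform, points: Iterable) -> np.ndarray:
    """Map points from camera space to projector space: R @ p + T."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[-1] != 3:
        raise ValueError("points must be 3-vectors")
    return pts @ t.R.T + t.T


def estimate_transform(
    pairs: Sequence[PointPair],
    refine: bool = False,
) -> RigidTransform:
    """Estimate the rigid transform minimizing sum ||R p_c + T - p_p||^2.

    Uses the closed-form SVD (Kabsch) solution on the centered point sets.
    With ``refine=True`` a Nelder-Mead polish over (rotation vector, T) is
    run from the closed-form optimum; for the squared-error objective this
    cannot improve an exact fit and exists to mirror derivative-free usage.

    Raises
    ------
    DegeneratePairsError
        Fewer than 3 pairs, collinear camera points, or data explained only
        by a reflection (improper orthogonal map).
    """
    if len(pairs) < 3:
        raise DegeneratePairsError("need at least 3 point pairs")
    cam, proj = _as_arrays(pairs)
    cam_c = cam - cam.mean(axis=0)
    proj_c = proj - proj.mean(axis=0)
    if np.linalg.matrix_rank(cam_c, tol=1e-9 * max(1.0, np.abs(cam).max())) < 2:
        raise DegeneratePairsError("camera points are collinear")

    h = cam_c.T @ proj_c
    u, s, vt = np.linalg.svd(h)
    d = np.linalg.det(vt.T @ u.T)
    if d < 0 and s[-1] > 1e-6 * s[0]:
        # Full-rank correspondence that genuinely prefers an improper map.
        raise DegeneratePairsError(
            "best-fitting orthogonal map is a reflection; cannot return a rotation"
        )
    corr = np.diag([1.0, 1.0, float(np.sign(d) or 1.0)])
    r = vt.T @ corr @ u.T
    t = proj.mean(axis=0) - r @ cam.mean(axis=0)

    if refine:
        def cost(theta: np.ndarray) -> float:
            rr = Rotation.from_rotvec(theta[:3]).as_matrix()
            res = cam @ rr.T + theta[3:] - proj
            return float(np.sum(res**2))

        x0 = np.concatenate([Rotation.from_matrix(r).as_rotvec(), t])
        sol = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 4000})
        if cost(sol.x) < cost(x0):
            r = Rotation.from_rotvec(sol.x[:3]).as_matrix()
            t = sol.x[3:]

    return RigidTransform(R=r, T=t)


def calibration_rmse(t: RigidTransform, pairs: Sequence[PointPair]) -> float:
    """Root-mean-squared residual ||R p_c + T - p_p|| over the pairs, in mm."""
    if len(pairs) == 0:
        raise ValueError("need at least one point pair")
    cam, proj = _as_arrays(pairs)
    res = apply_transform(t, cam) - proj
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
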