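"""Deformable registration of specimen snapshots to histology images.

The moving image is aligned to the fixed image by a dense displacement
field (DDF) that maximizes the mutual information between the fixed image
and the warped moving image.  The field is parameterized on a coarse-to-fine
control-point grid (bilinear basis) and optimized by analytic-gradient
ascent on a partial-volume (linearly interpolated) joint histogram, with a
diffusion (squared-difference) smoothness penalty and monotone step-halving
line search.  Reported mutual information always uses the hard-binned
histogram so that the metric matches a direct joint-histogram computation.

Displacement convention is backward mapping: ``out(x, y) = moving(x + u, y + v)``,
the convention that resamples without holes; the same operator is applied
to measurement-area masks downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .preprocessing import REG_HEIGHT, REG_WIDTH, GrayImage, foreground_mask

__all__ = [
    "DisplacementField",
    "RegistrationConfig",
    "RegistrationResult",
    "mutual_information",
    "dice_score",
    "warp",
    "estimate_ddf",
]


@dataclass
class DisplacementField:
    """Per-pixel displacements in pixels: ``u`` along x (columns), ``v`` along y (rows)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.ndim != 2 or self.u.shape != self.v.shape:
            raise ValueError("u and v must be 2-D grids of identical shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(u=np.zeros(shape), v=np.zeros(shape))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class RegistrationConfig:
    """Knobs for the DDF estimator; defaults match the documented pipeline."""

    bins: int = 32
    smoothness: float = 0.05          # weight of the diffusion penalty
    levels: int = 3                   # pyramid depth over control spacings
    control_spacing: int = 16         # px between control points at the finest level
    max_iter: int = 80                # ascent iterations per level
    step0: float = 40.0               # initial line-search step
    min_step: float = 1e-4
    seed: int = 0
    enforce_size: bool = True         # require the 256x192 network input grid


@dataclass
class RegistrationResult:
    field: DisplacementField
    warped: GrayImage
    mi_before: float
    mi_after: float
    dice_before: float
    dice_after: float
    converged: bool = True
    # one list of accepted objective values per pyramid level
    objective_trace: list = field(default_factory=list)

    def metrics(self) -> dict:
        return {
            "mi_before": self.mi_before,
            "mi_after": self.mi_after,
            "dice_before": self.dice_before,
            "dice_after": self.dice_after,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def _bin_indices(px: np.ndarray, bins: int) -> np.ndarray:
    # value 1.0 falls in the last bin (half-open bins, last bin closed)
    return np.minimum((np.clip(px, 0.0, 1.0) * bins).astype(np.intp), bins - 1)


def joint_histogram(a: GrayImage, b: GrayImage, bins: int = 32) -> np.ndarray:
    """Hard-binned joint intensity histogram (counts) over [0, 1]^2."""
    if a.shape != b.shape:
        raise ValueError("images must have identical dimensions")
    ia = _bin_indices(a.pixels.ravel(), bins)
    ib = _bin_indices(b.pixels.ravel(), bins)
    return np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins).astype(np.float64)


def mutual_information(a: GrayImage, b: GrayImage, bins: int = 32) -> float:
    """Mutual information in bits from the hard-binned joint histogram.

    MI = sum_ij p(i,j) log2( p(i,j) / (p(i) p(j)) ); zero-probability cells
    contribute nothing.  Symmetric in its arguments; MI(a, a) equals the
    entropy of ``a`` at the same binning.
    """
    if bins < 2:
        raise ValueError("bins must be at least 2")
    p = joint_histogram(a, b, bins)
    p /= p.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have identical dimensions")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def _warp_array(moving: np.ndarray, fld: DisplacementField, order: int) -> np.ndarray:
    h, w = moving.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + fld.v, xx + fld.u])
    return map_coordinates(moving, coords, order=order, mode="nearest")


def warp(moving: GrayImage, fld: DisplacementField) -> GrayImage:
    """Backward-warp: output(x, y) = moving(x + u(x,y), y + v(x,y)), bilinear.

    Out-of-bounds samples clamp to the boundary value.
    """
    if fld.shape != moving.shape:
        raise ValueError("field dimensions must match the moving image")
    return GrayImage(pixels=np.clip(_warp_array(moving.pixels, fld, order=1), 0.0, 1.0))


# ---------------------------------------------------------------------------
# control-grid machinery
# ---------------------------------------------------------------------------

class _ControlGrid:
    """Bilinear interpolation from a coarse control grid to the dense field,
    plus the exact adjoint used to pull dense gradients back to the grid."""

    def __init__(self, shape: tuple[int, int], spacing: float):
        h, w = shape
        self.shape = shape
        self.spacing = float(spacing)
        self.ni = int(np.ceil((h - 1) / spacing)) + 1
        self.nj = int(np.ceil((w - 1) / spacing)) + 1
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        gy = yy.ravel() / spacing
        gx = xx.ravel() / spacing
        i0 = np.minimum(gy.astype(np.intp), self.ni - 2)
        j0 = np.minimum(gx.astype(np.intp), self.nj - 2)
        wy = gy - i0
        wx = gx - j0
        self._flat = [
            (i0 * self.nj + j0, (1 - wy) * (1 - wx)),
            (i0 * self.nj + j0 + 1, (1 - wy) * wx),
            ((i0 + 1) * self.nj + j0, wy * (1 - wx)),
            ((i0 + 1) * self.nj + j0 + 1, wy * wx),
        ]

    def upsample(self, coef: np.ndarray) -> np.ndarray:
        flat = coef.ravel()
        out = np.zeros(self.shape[0] * self.shape[1])
        for idx, w in self._flat:
            out += flat[idx] * w
        return out.reshape(self.shape)

    def adjoint(self, dense_grad: np.ndarray) -> np.ndarray:
        g = dense_grad.ravel()
        out = np.zeros(self.ni * self.nj)
        for idx, w in self._flat:
            out += np.bincount(idx, weights=w * g, minlength=out.size)
        return out.reshape(self.ni, self.nj)

    def sample_dense(self, dense: np.ndarray) -> np.ndarray:
        """Dense field values at the control-point locations (for level prolongation)."""
        ii = np.minimum(np.arange(self.ni) * self.spacing, self.shape[0] - 1)
        jj = np.minimum(np.arange(self.nj) * self.spacing, self.shape[1] - 1)
        coords = np.stack(np.meshgrid(ii, jj, indexing="ij"))
        return map_coordinates(dense, coords.reshape(2, -1), order=1,
                               mode="nearest").reshape(self.ni, self.nj)


def _smoothness(coef_u: np.ndarray, coef_v: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean squared first difference of the control coefficients + gradient."""
    val = 0.0
    gu = np.zeros_like(coef_u)
    gv = np.zeros_like(coef_v)
    n = 0
    for c, g in ((coef_u, gu), (coef_v, gv)):
        for axis in (0, 1):
            d = np.diff(c, axis=axis)
            val += float(np.sum(d**2))
            n += d.size
            pad_lo = [(0, 0), (0, 0)]
            pad_hi = [(0, 0), (0, 0)]
            pad_lo[axis] = (1, 0)
            pad_hi[axis] = (0, 1)
            g += 2 * (np.pad(d, pad_lo) - np.pad(d, pad_hi))
    n = max(n, 1)
    return val / n, gu / n, gv / n


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class _MIObjective:
    """Partial-volume MI of (fixed, warp(moving)) with analytic gradient.

    The fixed image is hard-binned; warped moving intensities spread linearly
    over the two nearest bins, which makes the histogram — and hence the MI —
    differentiable in the displacements.
    """

    def __init__(self, fixed: np.ndarray, moving: np.ndarray, bins: int):
        self.bins = bins
        self.moving = moving
        self.fi = _bin_indices(fixed.ravel(), bins)
        self.n = fixed.size
        h, w = fixed.shape
        self.yy, self.xx = np.mgrid[0:h, 0:w].astype(np.float64)
        gy, gx = np.gradient(moving)
        self._gy, self._gx = gy, gx

    def _soft_bins(self, m: np.ndarray):
        t = m * self.bins - 0.5
        j0 = np.floor(t).astype(np.intp)
        w1 = t - j0
        j0c = np.clip(j0, 0, self.bins - 1)
        j1c = np.clip(j0 + 1, 0, self.bins - 1)
        return j0c, j1c, w1

    def value_and_grad(self, u: np.ndarray, v: np.ndarray):
        coords = np.stack([(self.yy + v).ravel(), (self.xx + u).ravel()])
        m = np.clip(map_coordinates(self.moving, coords, order=1, mode="nearest"), 0.0, 1.0)
        j0c, j1c, w1 = self._soft_bins(m)
        b = self.bins
        p = (np.bincount(self.fi * b + j0c, weights=1 - w1, minlength=b * b)
             + np.bincount(self.fi * b + j1c, weights=w1, minlength=b * b))
        p = p.reshape(b, b) / self.n
        pa = p.sum(axis=1)
        pb = p.sum(axis=0)
        nz = p > 0
        log_tab = np.zeros_like(p)
        log_tab[nz] = np.log2(p[nz] / (pa[:, None] * pb[None, :])[nz])
        mi = float(np.sum(p * log_tab))

        # dMI/dm per pixel: weight moves from bin j0 to j1 at rate `bins`
        dmi_dm = (log_tab[self.fi, j1c] - log_tab[self.fi, j0c]) * (b / self.n)
        gx = map_coordinates(self._gx, coords, order=1, mode="nearest")
        gy = map_coordinates(self._gy, coords, order=1, mode="nearest")
        shape = self.moving.shape
        return mi, (dmi_dm * gx).reshape(shape), (dmi_dm * gy).reshape(shape)

    def value(self, u: np.ndarray, v: np.ndarray) -> float:
        coords = np.stack([(self.yy + v).ravel(), (self.xx + u).ravel()])
        m = np.clip(map_coordinates(self.moving, coords, order=1, mode="nearest"), 0.0, 1.0)
        j0c, j1c, w1 = self._soft_bins(m)
        b = self.bins
        p = (np.bincount(self.fi * b + j0c, weights=1 - w1, minlength=b * b)
             + np.bincount(self.fi * b + j1c, weights=w1, minlength=b * b))
        p = p.reshape(b, b) / self.n
        pa = p.sum(axis=1)
        pb = p.sum(axis=0)
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / (pa[:, None] * pb[None, :])[nz])))


def estimate_ddf(
    fixed: GrayImage,
    moving: GrayImage,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate the DDF aligning ``moving`` to ``fixed`` by MI ascent.

    Coarse-to-fine over ``config.levels`` control-grid spacings (finest
    ``config.control_spacing``), each level running monotone gradient ascent
    with step-halving on  MI_pv - smoothness * penalty.  The regularized
    objective never decreases across accepted iterations.  If a level
    exhausts ``max_iter`` without the line search collapsing, the best field
    so far is kept and a warning is issued.
    """
    cfg = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must have identical dimensions")
    if cfg.enforce_size and fixed.shape != (REG_HEIGHT, REG_WIDTH):
        raise ValueError(
            f"registration inputs must be {REG_WIDTH}x{REG_HEIGHT}; resize first"
        )

    shape = fixed.shape
    objective = _MIObjective(fixed.pixels, moving.pixels, cfg.bins)
    mi_before = mutual_information(fixed, moving, cfg.bins)

    trace: list[list[float]] = []
    converged = True
    prev_grid: _ControlGrid | None = None
    cu = cv = None

    for level in range(cfg.levels):
        spacing = cfg.control_spacing * 2 ** (cfg.levels - 1 - level)
        grid = _ControlGrid(shape, spacing)
        if prev_grid is None:
            cu = np.zeros((grid.ni, grid.nj))
            cv = np.zeros((grid.ni, grid.nj))
        else:
            cu = grid.sample_dense(prev_grid.upsample(cu))
            cv = grid.sample_dense(prev_grid.upsample(cv))
        prev_grid = grid

        def f(cu_, cv_):
            val = objective.value(grid.upsample(cu_), grid.upsample(cv_))
            pen, _, _ = _smoothness(cu_, cv_)
            return val - cfg.smoothness * pen

        cur = f(cu, cv)
        level_trace = [cur]
        trace.append(level_trace)
        step = cfg.step0
        for _ in range(cfg.max_iter):
            mi, du_dense, dv_dense = objective.value_and_grad(
                grid.upsample(cu), grid.upsample(cv)
            )
            _, pgu, pgv = _smoothness(cu, cv)
            gu = grid.adjoint(du_dense) - cfg.smoothness * pgu
            gv = grid.adjoint(dv_dense) - cfg.smoothness * pgv
            gnorm = float(np.sqrt(np.sum(gu**2) + np.sum(gv**2)))
            if gnorm < 1e-14:
                break
            accepted = False
            while step >= cfg.min_step:
                nu = cu + step * gu / gnorm
                nv = cv + step * gv / gnorm
                new = f(nu, nv)
                if new > cur:
                    cu, cv, cur = nu, nv, new
                    level_trace.append(cur)
                    accepted = True
                    step *= 1.5
                    break
                step *= 0.5
            if not accepted:
                break
        else:
            converged = False

    u = prev_grid.upsample(cu)
    v = prev_grid.upsample(cv)
    fld = DisplacementField(u=u, v=v)
    warped = warp(moving, fld)
    mi_after = mutual_information(fixed, warped, cfg.bins)
    if mi_after < mi_before:
        # resampling jitter can only hurt already-aligned inputs; the identity
        # field is always an admissible answer
        fld = DisplacementField.zero(shape)
        warped = GrayImage(pixels=moving.pixels.copy())
        mi_after = mi_before

    if not converged:
        warnings.warn(
            "DDF estimation hit the iteration cap before the line search "
            "collapsed; returning the best field so far",
            RuntimeWarning,
            stacklevel=2,
        )

    fixed_mask = foreground_mask(fixed)
    return RegistrationResult(
        field=fld,
        warped=warped,
        mi_before=mi_before,
        mi_after=mi_after,
        dice_before=dice_score(fixed_mask, foreground_mask(moving)),
        dice_after=dice_score(fixed_mask, foreground_mask(warped)),
        converged=converged,
        objective_trace=trace,
    )
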