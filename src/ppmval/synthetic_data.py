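"""Synthetic phantoms for exercising every pipeline stage without hardware.

Three families of fixtures are generated, each with its ground truth
attached so that no test has to re-derive truth from the rendered data:

* inclined noisy depth scenes (optionally with a raised box object),
* checkerboard-style 3-D point pairs under a known rigid transform,
* specimen/histology image pairs related by a known smooth displacement
  field, with class-annotated regions and projected measurement dots.

All randomness flows from ``PhantomSpec.seed``; identical specs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .label_extraction import AnnotationMap
from .plane_calibration import DepthFrame, PlaneModel
from .preprocessing import SpecimenImage
from .projector_calibration import PointPair, RigidTransform
from .registration import DisplacementField

__all__ = [
    "PhantomSpec",
    "DepthScene",
    "SpecimenPhantom",
    "generate_depth_scene",
    "generate_calibration_pairs",
    "generate_smooth_deformation",
    "generate_specimen_pair",
    "CLASS_LEGEND",
]

CLASS_LEGEND = {0: "background", 1: "fat", 2: "connective", 3: "tumor"}

# colors chosen so the saturation channel separates the classes
_CLASS_RGB = {
    0: (0.08, 0.08, 0.08),
    1: (0.90, 0.84, 0.55),   # fat analog, saturation ~0.39
    2: (0.74, 0.90, 0.74),   # connective analog, saturation ~0.18
    3: (0.78, 0.31, 0.31),   # tumor analog, saturation ~0.60
}
# histology-space gray rendering (a different "modality": unrelated levels)
_CLASS_GRAY = {0: 0.05, 1: 0.75, 2: 0.45, 3: 0.22}


@dataclass
class PhantomSpec:
    """Everything the generators need; the seed fixes all randomness."""

    seed: int = 0
    shape: tuple[int, int] = (192, 256)      # (rows, cols)
    plane: tuple[float, float, float] = (0.05, -0.03, -80.0)
    depth_noise_sigma: float = 0.0           # mm
    box_height: float = 0.0                  # mm; 0 disables the object
    rotation_axis: tuple[float, float, float] = (0.2, -0.3, 1.0)
    rotation_angle_deg: float = 25.0
    translation: tuple[float, float, float] = (40.0, -15.0, 8.0)
    pair_noise_sigma: float = 0.0            # mm on projector points
    deform_amplitude: float = 8.0            # px
    deform_scale: float = 32.0               # px, Gaussian smoothing of the field
    n_poi: int = 5
    poi_radius: float = 6.0                  # probe radius in px
    dot_radius: float = 3.0                  # rendered projection-dot radius in px

    def __post_init__(self) -> None:
        if self.deform_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if self.deform_scale <= 0:
            raise ValueError("deformation smoothness scale must be > 0")

    def true_transform(self) -> RigidTransform:
        axis = np.asarray(self.rotation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        r = Rotation.from_rotvec(np.deg2rad(self.rotation_angle_deg) * axis)
        return RigidTransform(R=r.as_matrix(), T=np.asarray(self.translation, float))


# ---------------------------------------------------------------------------
# depth scenes
# ---------------------------------------------------------------------------

@dataclass
class DepthScene:
    frames: list[DepthFrame]
    plane: PlaneModel
    object_mask: np.ndarray
    object_height: float


def generate_depth_scene(spec: PhantomSpec, n_frames: int = 1) -> DepthScene:
    """Noisy depth frames of the spec's inclined plane, plus truth.

    The ideal surface is z = -(a x + b y + c); ``box_height`` > 0 adds that
    many mm over a centered rectangle covering ~1/9 of the frame.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    a, b, c = spec.plane
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    base = -(a * xx + b * yy + c)
    obj = np.zeros(spec.shape, dtype=bool)
    if spec.box_height > 0:
        obj[h // 3: 2 * h // 3, w // 3: 2 * w // 3] = True
    surface = base + np.where(obj, spec.box_height, 0.0)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for _ in range(n_frames):
        noise = (
            rng.normal(0.0, spec.depth_noise_sigma, spec.shape)
            if spec.depth_noise_sigma > 0
            else 0.0
        )
        frames.append(DepthFrame(values=surface + noise))
    return DepthScene(
        frames=frames,
        plane=PlaneModel(a=a, b=b, c=c),
        object_mask=obj,
        object_height=spec.box_height,
    )


# ---------------------------------------------------------------------------
# calibration point pairs
# ---------------------------------------------------------------------------

def generate_calibration_pairs(
    spec: PhantomSpec, n_configs: int = 1
) -> tuple[list[PointPair], RigidTransform]:
    """12 point pairs per board configuration under the spec's true transform.

    Each configuration is a planar 4x3 inner-corner grid (20 mm pitch)
    given a random mild tilt, in-plane rotation, and position at a varying
    height, mimicking a checkerboard held at different poses.  Projector
    points get isotropic Gaussian noise of ``pair_noise_sigma`` mm.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    rng = np.random.default_rng(spec.seed)
    truth = spec.true_transform()
    gx, gy = np.meshgrid(np.arange(4) * 20.0, np.arange(3) * 20.0)
    board = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(12)])
    board -= board.mean(axis=0)
    pairs: list[PointPair] = []
    for k in range(n_configs):
        tilt = Rotation.from_euler(
            "xyz",
            [rng.uniform(-15, 15), rng.uniform(-15, 15), rng.uniform(0, 360)],
            degrees=True,
        )
        offset = np.array(
            [rng.uniform(-60, 60), rng.uniform(-60, 60), 20.0 * k + rng.uniform(0, 10)]
        )
        cam = board @ tilt.as_matrix().T + offset
        proj = cam @ truth.R.T + truth.T
        if spec.pair_noise_sigma > 0:
            proj = proj + rng.normal(0.0, spec.pair_noise_sigma, proj.shape)
        pairs.extend(
            PointPair(camera_point=tuple(pc), projector_point=tuple(pp))
            for pc, pp in zip(cam, proj)
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# smooth deformations and specimen/histology pairs
# ---------------------------------------------------------------------------

def generate_smooth_deformation(
    spec: PhantomSpec, shape: tuple[int, int] | None = None
) -> DisplacementField:
    """Seeded Gaussian-smoothed random field scaled to the requested amplitude.

    A cosine taper forces the displacement to zero at the image borders so
    warped content never leaves the frame.  The maximum displacement
    magnitude equals ``deform_amplitude`` exactly (unless it is zero).
    """
    shape = shape or spec.shape
    if spec.deform_amplitude == 0:
        return DisplacementField.zero(shape)
    rng = np.random.default_rng(spec.seed)
    u = gaussian_filter(rng.normal(size=shape), spec.deform_scale, mode="constant")
    v = gaussian_filter(rng.normal(size=shape), spec.deform_scale, mode="constant")
    h, w = shape
    margin = spec.deform_scale
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.minimum.reduce([xx, yy, w - 1 - xx, h - 1 - yy])
    taper = 0.5 * (1 - np.cos(np.pi * np.clip(d / margin, 0.0, 1.0)))
    u *= taper
    v *= taper
    mag = np.hypot(u, v).max()
    if mag > 0:
        u *= spec.deform_amplitude / mag
        v *= spec.deform_amplitude / mag
    return DisplacementField(u=u, v=v)


def _draw_disks(img: np.ndarray, centers: np.ndarray, radius: float, value) -> None:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in centers:
        sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        img[sel] = value


def _class_layout(shape: tuple[int, int]) -> np.ndarray:
    """Default tissue-analog layout: fat ellipse, connective lobe, tumor blob."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = w / 2, h / 2
    layout = np.zeros(shape, dtype=np.int32)
    in_spec = ((xx - cx) / (0.38 * w)) ** 2 + ((yy - cy) / (0.36 * h)) ** 2 <= 1
    layout[in_spec] = 1
    lobe = ((xx - cx + 0.12 * w) / (0.20 * w)) ** 2 + ((yy - cy - 0.08 * h) / (0.22 * h)) ** 2 <= 1
    layout[lobe & in_spec] = 2
    blob = ((xx - cx - 0.14 * w) / (0.11 * w)) ** 2 + ((yy - cy + 0.06 * h) / (0.13 * h)) ** 2 <= 1
    layout[blob & in_spec] = 3
    return layout


def _map_center_to_histology(
    center: np.ndarray, fld: DisplacementField, n_iter: int = 50
) -> np.ndarray:
    """Solve x + phi(x) = center for x (the disk's location in fixed space)."""
    x = center.astype(np.float64).copy()
    for _ in range(n_iter):
        u = map_coordinates(fld.u, [[x[1]], [x[0]]], order=1, mode="nearest")[0]
        v = map_coordinates(fld.v, [[x[1]], [x[0]]], order=1, mode="nearest")[0]
        x_new = center - np.array([u, v])
        if np.max(np.abs(x_new - x)) < 1e-10:
            return x_new
        x = x_new
    return x


@dataclass
class SpecimenPhantom:
    """A rendered specimen/histology pair plus every piece of ground truth."""

    s_o: SpecimenImage
    s_poi: SpecimenImage
    h_o: np.ndarray                      # RGB histology rendering
    annotation: AnnotationMap
    field: DisplacementField             # true backward field (specimen -> histology frame)
    poi_centers: np.ndarray              # (n, 2) in specimen space
    poi_centers_histology: np.ndarray    # (n, 2) mapped through the true field
    poi_radius: float
    intended_labels: list[str]
    specimen_foreground: np.ndarray
    histology_foreground: np.ndarray
    class_layout: np.ndarray


def generate_specimen_pair(spec: PhantomSpec) -> SpecimenPhantom:
    """Render S_O / S_POI / H_O / annotation related by a known deformation.

    The true field is the backward map used by the registration module:
    ``histology(x) = specimen(x + field(x))`` exactly (up to resampling), so
    registering the specimen to the histology should recover it.  POI
    centers are sampled inside a single tissue class with non-overlapping,
    in-bounds probe disks; the class under each center is the intended label.
    """
    h, w = spec.shape
    layout = _class_layout(spec.shape)
    rng = np.random.default_rng(spec.seed)

    s_o_px = np.zeros((h, w, 3))
    for code, rgb in _CLASS_RGB.items():
        s_o_px[layout == code] = rgb
    s_o_px = gaussian_filter(s_o_px, sigma=(0.6, 0.6, 0.0))
    s_o_px += rng.normal(0.0, 0.004, s_o_px.shape)
    s_o_px = np.clip(s_o_px, 0.0, 1.0)

    # POI placement: disk fully inside one class, pairwise non-overlapping
    centers: list[np.ndarray] = []
    intended: list[str] = []
    yy, xx = np.mgrid[0:h, 0:w]
    r = spec.poi_radius
    # placement uses a 3 px safety margin so the probe disk stays inside one
    # class even under small registration jitter
    r_place = r + 3.0
    for _ in range(20000):
        if len(centers) == spec.n_poi:
            break
        c = np.array(
            [rng.uniform(r_place + 1, w - r_place - 2),
             rng.uniform(r_place + 1, h - r_place - 2)]
        )
        disk = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_place**2
        classes = np.unique(layout[disk])
        if classes.size != 1 or classes[0] == 0:
            continue
        if any(np.sum((c - p) ** 2) <= (2 * r_place + 2) ** 2 for p in centers):
            continue
        centers.append(c)
        intended.append(CLASS_LEGEND[int(classes[0])])
    if len(centers) < spec.n_poi:
        raise RuntimeError("could not place the requested number of POIs")
    poi_centers = np.array(centers)

    s_poi_px = s_o_px.copy()
    _draw_disks(s_poi_px, poi_centers, spec.dot_radius, (1.0, 1.0, 1.0))

    fld = generate_smooth_deformation(spec)
    coords = np.stack([(yy + fld.v).ravel(), (xx + fld.u).ravel()])

    hist_layout = (
        map_coordinates(layout, coords, order=0, mode="nearest")
        .reshape(spec.shape)
        .astype(np.int32)
    )
    gray = np.zeros(spec.shape)
    for code, g in _CLASS_GRAY.items():
        gray[layout == code] = g
    gray = gaussian_filter(gray, 1.0)
    h_gray = np.clip(
        map_coordinates(gray, coords, order=1, mode="nearest").reshape(spec.shape),
        0.0,
        1.0,
    )
    h_o = np.stack([h_gray, h_gray, h_gray], axis=-1)

    mapped = np.array([_map_center_to_histology(c, fld) for c in poi_centers])

    return SpecimenPhantom(
        s_o=SpecimenImage(pixels=s_o_px, role="S_O"),
        s_poi=SpecimenImage(pixels=s_poi_px, role="S_POI"),
        h_o=h_o,
        annotation=AnnotationMap(labels=hist_layout, legend=dict(CLASS_LEGEND)),
        field=fld,
        poi_centers=poi_centers,
        poi_centers_histology=mapped,
        poi_radius=spec.poi_radius,
        intended_labels=intended,
        specimen_foreground=layout > 0,
        histology_foreground=hist_layout > 0,
        class_layout=layout,
    )
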