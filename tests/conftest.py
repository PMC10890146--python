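import numpy as np
import pytest

from ppmval.plane_calibration import DepthFrame, PlaneModel
from ppmval.preprocessing import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_plane_frame(a, b, c, shape=(100, 100), noise_sigma=0.0, seed=0):
    """Depth frame of z = -(a x + b y + c) plus optional Gaussian noise."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    z = -(a * xx + b * yy + c)
    if noise_sigma > 0:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sigma, shape)
    return DepthFrame(values=z)


def normal_equations_plane(x, y, z):
    """Independent closed-form oracle: solve the 3x3 normal equations of
    min (1/n) sum (a x + b y + z + c)^2 explicitly."""
    n = len(x)
    ata = np.array(
        [
            [np.sum(x * x), np.sum(x * y), np.sum(x)],
            [np.sum(x * y), np.sum(y * y), np.sum(y)],
            [np.sum(x), np.sum(y), float(n)],
        ]
    )
    rhs = -np.array([np.sum(x * z), np.sum(y * z), np.sum(z)])
    return np.linalg.solve(ata, rhs)


def kabsch_oracle(cam, proj):
    """Independent closed-form rigid-fit oracle on centered point sets."""
    cam = np.asarray(cam, float)
    proj = np.asarray(proj, float)
    cc = cam - cam.mean(axis=0)
    pc = proj - proj.mean(axis=0)
    u, s, vt = np.linalg.svd(cc.T @ pc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = proj.mean(axis=0) - r @ cam.mean(axis=0)
    return r, t


def random_gray(rng, shape=(32, 32)):
    return GrayImage(pixels=rng.uniform(0.0, 1.0, shape))
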