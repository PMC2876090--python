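import numpy as np
import pytest

from histovol import ImageStack, quantize_u8


def _blob_params(shape, n_blobs, seed):
    rng = np.random.default_rng(seed)
    h, w = shape
    out = []
    for _ in range(n_blobs):
        out.append(
            (
                rng.uniform(0.2 * w, 0.8 * w),
                rng.uniform(0.2 * h, 0.8 * h),
                rng.uniform(3.0, 7.0),
                rng.uniform(80.0, 255.0),
            )
        )
    return out


def _eval_blobs(params, x, y):
    img = np.zeros_like(x, dtype=np.float64)
    for cx, cy, s, a in params:
        img += a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s * s))
    return np.clip(img, 0, 255)


def smooth_image(shape=(48, 48), n_blobs=6, seed=0, background=0.0):
    """Sum of Gaussian blobs: smooth content suitable for registration."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    return np.clip(_eval_blobs(_blob_params(shape, n_blobs, seed), x, y) + background, 0, 255)


def smooth_image_pair(shape, transform, n_blobs=6, seed=0):
    """Fixed slice plus the same continuous scene imaged under ``transform``.

    The moving slice is evaluated analytically at transformed coordinates
    (no resampling), so registering it onto the fixed slice should recover
    ``transform`` exactly up to quantisation.
    """
    h, w = shape
    params = _blob_params(shape, n_blobs, seed)
    y, x = np.mgrid[0:h, 0:w]
    fixed = _eval_blobs(params, x.astype(float), y.astype(float))
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    pts = np.stack([x.ravel(), y.ravel()], axis=1).astype(float)
    src = transform.apply_points(pts, center)
    moving = _eval_blobs(params, src[:, 0].reshape(h, w), src[:, 1].reshape(h, w))
    return quantize_u8(fixed), quantize_u8(moving)


@pytest.fixture
def smooth_slice():
    return smooth_image(seed=7)


@pytest.fixture
def random_rgb_stack():
    rng = np.random.default_rng(11)
    data = rng.integers(0, 256, size=(5, 12, 10, 3), dtype=np.uint8)
    return ImageStack(data, (0.5, 0.5, 1.0))


@pytest.fixture
def random_gray_stack():
    rng = np.random.default_rng(13)
    data = rng.integers(0, 256, size=(8, 8, 8, 1), dtype=np.uint8)
    return ImageStack(data, (1.0, 1.0, 1.0))
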