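"""3D Gaussian and edge-preserving smoothing against independent oracles."""

import numpy as np
import pytest

from histovol import (
    EdgePreserveParams,
    GaussParams,
    ImageStack,
    edge_preserving_smooth,
    filter_rgb,
    gaussian_smooth,
    invert,
)
from histovol.filter3d import gaussian_kernel_1d
from histovol.stack_io import luminance, quantize_u8


def gray_stack(vol, spacing=(1, 1, 1)):
    return ImageStack(np.asarray(vol, np.uint8)[..., np.newaxis], spacing)


def brute_force_gauss3d(vol, kernel, sigma):
    """Direct (non-separable) 3D convolution oracle with reflect boundary."""
    ks = []
    for size, s in zip(kernel, sigma):
        if size % 2 == 0:
            size += 1
        r = (size - 1) // 2
        x = np.arange(-r, r + 1, dtype=float)
        ks.append(np.exp(-(x * x) / (2 * s * s)))
    kx, ky, kz = ks
    full = kz[:, None, None] * ky[None, :, None] * kx[None, None, :]
    full /= full.sum()
    rz, ry, rx = (k.size // 2 for k in (kz, ky, kx))
    padded = np.pad(vol.astype(float), ((rz, rz), (ry, ry), (rx, rx)), mode="symmetric")
    out = np.zeros_like(vol, dtype=float)
    nz, nh, nw = vol.shape
    for z in range(nz):
        for y in range(nh):
            for x in range(nw):
                region = padded[z : z + 2 * rz + 1, y : y + 2 * ry + 1, x : x + 2 * rx + 1]
                out[z, y, x] = np.sum(region * full)
    return out


class TestGaussianSmooth:
    def test_constant_stack_is_fixed_point(self):
        out = gaussian_smooth(gray_stack(np.full((9, 9, 9), 100)))
        assert np.all(out.data == 100)

    def test_impulse_response_equals_normalized_kernel(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 255
        out = gaussian_smooth(gray_stack(vol), GaussParams((3, 3, 3), (1, 1, 1)))
        expected = quantize_u8(brute_force_gauss3d(vol, (3, 3, 3), (1, 1, 1)))
        assert np.array_equal(out.data[..., 0], expected)

    def test_matches_brute_force_convolution_on_random_volume(self):
        rng = np.random.default_rng(42)
        vol = rng.integers(0, 256, (8, 8, 8))
        out = gaussian_smooth(gray_stack(vol), GaussParams((3, 3, 3), (1, 1, 1)))
        oracle = brute_force_gauss3d(vol, (3, 3, 3), (1, 1, 1))
        assert np.max(np.abs(out.data[..., 0].astype(float) - oracle)) <= 1.0

    def test_even_kernel_promoted_matches_odd(self):
        rng = np.random.default_rng(1)
        vol = rng.integers(0, 256, (10, 10, 10))
        even = gaussian_smooth(gray_stack(vol), GaussParams((6, 6, 6), (1, 1, 1)))
        odd = gaussian_smooth(gray_stack(vol), GaussParams((7, 7, 7), (1, 1, 1)))
        assert np.array_equal(even.data, odd.data)

    def test_volume_mean_preserved_within_half_gray_level(self):
        rng = np.random.default_rng(3)
        vol = rng.integers(0, 256, (10, 12, 11))
        out = gaussian_smooth(gray_stack(vol), GaussParams((7, 7, 7), (1.5, 1.5, 1.5)))
        assert abs(out.data.mean() - vol.mean()) < 0.5

    def test_kernel_exceeding_extent_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(gray_stack(np.zeros((3, 9, 9))), GaussParams((3, 3, 9)))

    def test_rejects_color_stack(self, random_rgb_stack):
        with pytest.raises(ValueError):
            gaussian_smooth(random_rgb_stack)

    def test_commutes_with_invert_exactly(self, random_gray_stack):
        params = GaussParams((5, 5, 5), (1, 1, 1))
        a = gaussian_smooth(invert(random_gray_stack), params)
        b = invert(gaussian_smooth(random_gray_stack, params))
        assert np.array_equal(a.data, b.data)


def diffusion_oracle(vol, params):
    """Independently coded explicit-scheme nonlinear diffusion.

    Shift-based implementation (np.roll on edge-padded arrays) of
    u += dt * div(g grad u) with g = exp(-(|grad u_sigma|/contrast)^2),
    zero-flux boundaries, stable sub-stepping.
    """
    from scipy.ndimage import gaussian_filter

    u = vol.astype(float)
    n_steps = int(params.stop // params.step)
    dt_max = 1.0 / 6.0
    n_sub = max(1, int(np.ceil(params.step / dt_max)))
    dt = params.step / n_sub
    for _ in range(n_steps * n_sub):
        us = gaussian_filter(u, params.sigma, mode="reflect")
        gz, gy, gx = np.gradient(us)
        g = np.exp(-(gz**2 + gy**2 + gx**2) / params.contrast**2)
        total = np.zeros_like(u)
        for axis in range(3):
            up = np.pad(u, [(1, 1) if a == axis else (0, 0) for a in range(3)], mode="edge")
            gp = np.pad(g, [(1, 1) if a == axis else (0, 0) for a in range(3)], mode="edge")
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_mid = [slice(None)] * 3
            sl_lo[axis] = slice(0, -2)
            sl_hi[axis] = slice(2, None)
            sl_mid[axis] = slice(1, -1)
            u_lo, u_hi, u_mid = up[tuple(sl_lo)], up[tuple(sl_hi)], up[tuple(sl_mid)]
            g_lo, g_hi, g_mid = gp[tuple(sl_lo)], gp[tuple(sl_hi)], gp[tuple(sl_mid)]
            total += 0.5 * (g_hi + g_mid) * (u_hi - u_mid) - 0.5 * (g_mid + g_lo) * (u_mid - u_lo)
        u = u + dt * total
    return u


def step_volume(shape=(8, 8, 8), lo=40, hi=200):
    vol = np.full(shape, lo)
    vol[:, :, shape[2] // 2 :] = hi
    return vol


class TestEdgePreservingSmooth:
    def test_constant_stack_unchanged(self):
        out = edge_preserving_smooth(gray_stack(np.full((8, 8, 8), 123)))
        assert np.all(out.data == 123)

    def test_stop_below_step_is_identity(self, random_gray_stack):
        out = edge_preserving_smooth(
            random_gray_stack, EdgePreserveParams(step=5.0, stop=4.0)
        )
        assert np.array_equal(out.data, random_gray_stack.data)

    def test_matches_independent_explicit_scheme_oracle(self):
        vol = step_volume()
        params = EdgePreserveParams()
        out = edge_preserving_smooth(gray_stack(vol), params)
        oracle = quantize_u8(diffusion_oracle(vol, params))
        assert np.max(np.abs(out.data[..., 0].astype(int) - oracle.astype(int))) <= 1

    def test_oracle_agreement_on_random_volume(self):
        rng = np.random.default_rng(6)
        vol = rng.integers(0, 256, (8, 8, 8))
        params = EdgePreserveParams(contrast=10.0, sigma=1.5, step=2.0, stop=6.0)
        out = edge_preserving_smooth(gray_stack(vol), params)
        oracle = quantize_u8(diffusion_oracle(vol, params))
        assert np.max(np.abs(out.data[..., 0].astype(int) - oracle.astype(int))) <= 1

    def test_maximum_principle(self):
        rng = np.random.default_rng(9)
        vol = rng.integers(30, 220, (8, 8, 8))
        out = edge_preserving_smooth(gray_stack(vol))
        assert out.data.min() >= vol.min()
        assert out.data.max() <= vol.max()

    def test_large_contrast_approaches_linear_diffusion(self):
        rng = np.random.default_rng(12)
        vol = rng.integers(0, 256, (8, 8, 8))
        linear = diffusion_oracle(vol, EdgePreserveParams(contrast=1e9, sigma=3.0))
        diffs = []
        for contrast in (10.0, 100.0, 1000.0):
            out = edge_preserving_smooth(
                gray_stack(vol), EdgePreserveParams(contrast=contrast, sigma=3.0)
            )
            diffs.append(np.abs(out.data[..., 0].astype(float) - linear).max())
        assert diffs[0] >= diffs[1] >= diffs[2]
        assert diffs[2] <= 1.0

    def test_preserves_edges_better_than_gaussian(self):
        vol = step_volume((12, 12, 12), 30, 220)
        ep = edge_preserving_smooth(gray_stack(vol)).data[..., 0].astype(float)
        ga = gaussian_smooth(gray_stack(vol), GaussParams((6, 6, 6), (1, 1, 1))).data[..., 0].astype(float)
        edge_grad = lambda v: np.abs(np.diff(v, axis=2)).max()
        assert edge_grad(ep) > edge_grad(ga)

    def test_commutes_with_invert_within_one_gray_level(self, random_gray_stack):
        params = EdgePreserveParams(step=2.0, stop=4.0)
        a = edge_preserving_smooth(invert(random_gray_stack), params)
        b = invert(edge_preserving_smooth(random_gray_stack, params))
        assert np.max(np.abs(a.data.astype(int) - b.data.astype(int))) <= 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EdgePreserveParams(contrast=-1.0)


class TestFilterRGB:
    def test_channels_filtered_independently(self):
        rng = np.random.default_rng(20)
        data = rng.integers(0, 256, (6, 6, 6, 3), dtype=np.uint8)
        stack = ImageStack(data, (1, 1, 1))
        params = GaussParams((3, 3, 3), (1, 1, 1))
        out = filter_rgb(stack, params)
        for c in range(3):
            single = gaussian_smooth(
                ImageStack(data[..., c][..., np.newaxis], (1, 1, 1)), params
            )
            assert np.array_equal(out.data[..., c], single.data[..., 0])

    def test_alpha_recomputed_as_luminance_of_filtered_channels(self):
        rng = np.random.default_rng(21)
        data = rng.integers(0, 256, (5, 7, 6, 3), dtype=np.uint8)
        out = filter_rgb(ImageStack(data, (1, 1, 1)), GaussParams((3, 3, 3), (1, 1, 1)))
        assert out.n_channels == 4
        expected_alpha = luminance(out.data[..., :3].astype(float))
        assert np.array_equal(out.data[..., 3], expected_alpha)

    def test_gray_valued_rgb_keeps_channels_equal(self):
        rng = np.random.default_rng(22)
        g = rng.integers(0, 256, (5, 6, 6), dtype=np.uint8)
        data = np.stack([g, g, g], axis=-1)
        out = filter_rgb(ImageStack(data, (1, 1, 1)), GaussParams((3, 3, 3), (1, 1, 1)))
        assert np.array_equal(out.data[..., 0], out.data[..., 1])
        assert np.array_equal(out.data[..., 1], out.data[..., 2])
        assert np.max(np.abs(out.data[..., 3].astype(int) - out.data[..., 0].astype(int))) <= 1

    def test_rejects_gray_stack(self, random_gray_stack):
        with pytest.raises(ValueError):
            filter_rgb(random_gray_stack, GaussParams((3, 3, 3), (1, 1, 1)))
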