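"""Emission-absorption ray casting against compositing oracles."""

import numpy as np
import pytest

from histovol import ImageStack, ROI, ViewSpec, reinvert_snapshot, render, turntable
from histovol.phantom import PhantomSpec, generate_phantom
from histovol.transfer import TransferFunction, apply_transfer, luminance_alpha
from histovol.preprocess import invert


def rgba_stack(data, spacing=(1, 1, 1)):
    return ImageStack(np.asarray(data, np.uint8), spacing)


def axis_view(stack, **kw):
    kw.setdefault("image_size", (stack.shape[2], stack.shape[1]))
    kw.setdefault("sample_step", min(stack.spacing))
    kw.setdefault("pixel_pitch", min(stack.spacing[0], stack.spacing[1]))
    return ViewSpec(**kw)


class TestRenderBasics:
    def test_fully_transparent_volume_renders_background(self):
        data = np.zeros((3, 4, 4, 4), np.uint8)
        data[..., :3] = 200
        img = render(rgba_stack(data), axis_view(rgba_stack(data), background=(12, 34, 56)))
        assert np.all(img.pixels == np.array([12, 34, 56]))

    def test_single_opaque_voxel_returns_its_rgb(self):
        data = np.zeros((3, 5, 5, 4), np.uint8)
        data[0, 3, 1] = (120, 40, 200, 255)
        stack = rgba_stack(data)
        img = render(stack, axis_view(stack))
        assert tuple(img.pixels[3, 1]) == (120, 40, 200)
        assert np.all(img.pixels[0, 0] == 0)

    def test_two_sample_ray_matches_over_operator_closed_form(self):
        data = np.zeros((2, 1, 1, 4), np.uint8)
        data[0, 0, 0] = (200, 10, 50, 128)
        data[1, 0, 0] = (30, 220, 90, 200)
        stack = rgba_stack(data)
        view = axis_view(stack, interpolation="nearest", background=(7, 9, 11))
        img = render(stack, view)
        a1, a2 = 128 / 255, 200 / 255
        c1, c2 = np.array([200, 10, 50]), np.array([30, 220, 90])
        bg = np.array([7, 9, 11])
        expected = a1 * c1 + (1 - a1) * a2 * c2 + (1 - a1) * (1 - a2) * bg
        assert np.max(np.abs(img.pixels[0, 0].astype(float) - expected)) <= 1.0

    def test_back_to_front_compositing_identity(self):
        rng = np.random.default_rng(8)
        n = 6
        alphas = rng.uniform(0.05, 0.7, n)
        colors = rng.uniform(0, 255, (n, 3))
        # front-to-back over operator
        C = np.zeros(3)
        T = 1.0
        for a, c in zip(alphas, colors):
            C += T * a * c
            T *= 1.0 - a
        # independent back-to-front recursion
        C2 = np.zeros(3)
        for a, c in zip(alphas[::-1], colors[::-1]):
            C2 = a * c + (1.0 - a) * C2
        assert np.allclose(C, C2, atol=1e-9)
        # renderer agrees on the stacked-voxel version of the same ray
        data = np.zeros((n, 1, 1, 4))
        data[:, 0, 0, :3] = colors
        data[:, 0, 0, 3] = alphas * 255
        stack = rgba_stack(np.round(data))
        img = render(stack, axis_view(stack, interpolation="nearest"))
        a_q = np.round(alphas * 255) / 255
        C3 = np.zeros(3)
        T = 1.0
        for a, c in zip(a_q, np.round(colors)):
            C3 += T * a * c
            T *= 1.0 - a
        assert np.max(np.abs(img.pixels[0, 0].astype(float) - C3)) <= 1.0

    def test_rejects_non_rgba_stack(self, random_rgb_stack):
        with pytest.raises(ValueError):
            render(random_rgb_stack, ViewSpec())


class TestOpacityCorrection:
    def test_homogeneous_volume_step_invariant(self):
        data = np.zeros((8, 6, 6, 4), np.uint8)
        data[..., :3] = 180
        data[..., 3] = 100
        stack = rgba_stack(data)
        img1 = render(stack, axis_view(stack, sample_step=1.0))
        img2 = render(stack, axis_view(stack, sample_step=0.5))
        assert np.max(np.abs(img1.pixels.astype(int) - img2.pixels.astype(int))) <= 2

    def test_increasing_alpha_never_decreases_opacity(self):
        rng = np.random.default_rng(15)
        data = rng.integers(0, 200, (5, 6, 6, 4), dtype=np.uint8)
        data[..., :3] = 255  # white emission; pixel brightness tracks opacity
        stack = rgba_stack(data)
        brighter = data.copy()
        brighter[..., 3] = np.clip(brighter[..., 3].astype(int) + 40, 0, 255).astype(np.uint8)
        img1 = render(stack, axis_view(stack, background=(0, 0, 0)))
        img2 = render(rgba_stack(brighter), axis_view(stack, background=(0, 0, 0)))
        assert np.all(img2.pixels.astype(int) >= img1.pixels.astype(int) - 1)


class TestROI:
    def test_out_of_bounds_roi_rejected(self):
        data = np.zeros((3, 4, 4, 4), np.uint8)
        stack = rgba_stack(data)
        with pytest.raises(ValueError):
            render(stack, axis_view(stack), ROI(0, 5, 0, 4, 0, 3))

    def test_cropping_removes_contribution(self):
        data = np.zeros((2, 4, 4, 4), np.uint8)
        data[0, :, :2] = (255, 0, 0, 255)
        data[0, :, 2:] = (0, 255, 0, 255)
        stack = rgba_stack(data)
        img = render(stack, axis_view(stack), ROI(0, 2, 0, 4, 0, 2))
        assert tuple(img.pixels[1, 0]) == (255, 0, 0)
        assert tuple(img.pixels[1, 3]) == (0, 0, 0)  # cropped: background


class TestSnapshots:
    def test_reinvert_is_involution(self):
        rng = np.random.default_rng(2)
        data = np.zeros((2, 3, 3, 4), np.uint8)
        data[..., :3] = rng.integers(0, 256, (2, 3, 3, 3))
        data[..., 3] = 255
        stack = rgba_stack(data)
        img = render(stack, axis_view(stack))
        twice = reinvert_snapshot(reinvert_snapshot(img))
        assert np.array_equal(twice.pixels, img.pixels)
        assert np.all(reinvert_snapshot(img).pixels == 255 - img.pixels)

    def test_reinverted_rendering_recovers_stain_colors(self):
        """Opaque voxels of an inverted phantom re-invert to the stain hue."""
        spec = PhantomSpec(
            extent=(24, 24, 8), jitter=(0, 0), elastic=(0, 0),
            stain_gain=0.0, bleach_rate=0.0, speckle=0.0, seed=5,
        )
        stack, truth = generate_phantom(spec)
        inv = invert(stack)
        rgba = apply_transfer(luminance_alpha(inv), TransferFunction.threshold(10))
        img = reinvert_snapshot(render(rgba, axis_view(rgba)))
        # a pixel on the gut-tube axis sees a fully opaque tube voxel as
        # its first hit under a threshold transfer: expect the stain colour
        on_tube = img.pixels[10, 14].astype(int)  # (row y=10, col x=14)
        tube_color = np.array([70, 50, 150])
        assert np.max(np.abs(on_tube - tube_color)) <= 2


class TestTurntable:
    def test_single_frame_equals_base_render(self):
        data = np.zeros((3, 5, 5, 4), np.uint8)
        data[1, 2, 2] = (100, 150, 200, 255)
        stack = rgba_stack(data)
        view = axis_view(stack)
        frames = turntable(stack, view, 1)
        assert len(frames) == 1
        assert np.array_equal(frames[0].pixels, render(stack, view).pixels)

    def test_z_symmetric_phantom_frames_agree(self):
        # rotationally symmetric object about z: centred opaque cylinder
        z, h, w = 4, 17, 17
        data = np.zeros((z, h, w, 4), np.uint8)
        y, x = np.mgrid[0:h, 0:w]
        r = np.hypot(x - 8, y - 8)
        inside = r < 5
        data[:, inside] = (200, 120, 80, 255)
        stack = rgba_stack(data)
        view = axis_view(stack)  # looking along z; rotation about z
        frames = turntable(stack, view, 4, axis=(0, 0, 1))
        for f in frames[1:]:
            # interiors agree; allow the antialiased rim one level of slack
            diff = np.abs(f.pixels.astype(int) - frames[0].pixels.astype(int))
            assert np.percentile(diff, 95) <= 1

    def test_frame_k_equals_prerotated_base_view(self):
        data = np.zeros((3, 6, 6, 4), np.uint8)
        data[1, 2, 3] = (50, 100, 150, 255)
        stack = rgba_stack(data)
        view = axis_view(stack)
        frames = turntable(stack, view, 3, axis=(0, 1, 0))
        from histovol.render import _rotate_about
        from dataclasses import replace

        d = _rotate_about(np.array(view.direction), np.array([0, 1, 0.0]), 240.0)
        up = _rotate_about(np.array(view.up), np.array([0, 1, 0.0]), 240.0)
        single = render(stack, replace(view, direction=tuple(d), up=tuple(up)))
        assert np.array_equal(frames[2].pixels, single.pixels)


class TestStriationArtifact:
    def test_edge_on_view_shows_per_slice_banding(self):
        """Per-slice gain variation appears as striations in edge-on views.

        A z-homogeneous object (tube along the sectioning axis) viewed
        edge-on is uniform along z except for the staining variation, so
        inside the object the intensity variance along z dominates the
        variance along y.
        """
        from histovol.phantom import Primitive

        geom = (Primitive("tube", (16.0, 16.0, 0.0), (10.0, 10.0, 1.0), (140, 90, 120)),)
        spec = PhantomSpec(
            extent=(32, 32, 32), spacing=(1, 1, 1), geometry=geom,
            jitter=(0, 0), elastic=(0, 0),
            stain_gain=0.15, bleach_rate=0.0, speckle=0.0, seed=77,
        )
        stack, _ = generate_phantom(spec)
        inv = invert(stack)
        rgba = luminance_alpha(inv)
        # edge-on: view along x; image columns run along z, rows along y
        view = ViewSpec(direction=(1, 0, 0), up=(0, -1, 0), image_size=(32, 32),
                        sample_step=1.0, pixel_pitch=1.0)
        img = render(rgba, view).pixels.astype(float).mean(axis=-1)
        interior = img[13:20, :]  # rows crossing the tube interior
        var_along_z = np.var(interior.mean(axis=0))  # striation banding
        var_along_y = np.var(interior.mean(axis=1))
        assert var_along_z > var_along_y
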