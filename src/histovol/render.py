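"""Software orthographic ray casting with the emission-absorption model.

An image is formed by marching rays through the RGBA volume and
simulating the absorption and emission of light along each ray path to
the eye: every sample contributes its colour weighted by its opacity and
by the transparency accumulated in front of it (front-to-back "over"
compositing).  Sampling is trilinear in physical coordinates, so
anisotropic voxels (section thickness larger than pixel size) are
handled correctly, and the stored alpha is converted to per-sample
opacity with a step-size correction that makes the accumulated opacity
independent of the sampling rate for homogeneous regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .stack_io import ImageStack, Semantics, quantize_u8

__all__ = [
    "ViewSpec",
    "ROI",
    "RenderedImage",
    "render",
    "reinvert_snapshot",
    "turntable",
    "save_snapshot",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length view vector")
    return v / n


@dataclass(frozen=True)
class ViewSpec:
    """Orthographic camera description in physical (micrometre) space.

    ``direction`` points from the eye into the volume; ``up`` must not be
    parallel to it.  The default view looks along +z (the sectioning
    axis) with image rows running along +y and columns along +x, so a
    pixel grid matching the slice grid reproduces slice geometry exactly.
    """

    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    up: tuple[float, float, float] = (0.0, -1.0, 0.0)
    sample_step: float = 1.0
    image_size: tuple[int, int] = (128, 128)  # (nx, ny) pixels
    pixel_pitch: float = 1.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interpolation: str = "trilinear"
    early_termination: float = 0.995

    def __post_init__(self) -> None:
        d = _unit(self.direction)
        object.__setattr__(self, "direction", tuple(d))
        u = np.asarray(self.up, dtype=np.float64)
        if np.linalg.norm(np.cross(d, u)) < 1e-9:
            raise ValueError("up vector is parallel to the view direction")
        object.__setattr__(self, "up", tuple(float(x) for x in u))
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be 'trilinear' or 'nearest'")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(direction, column axis, row axis) orthonormal frame."""
        d = np.asarray(self.direction)
        u_axis = _unit(np.cross(d, self.up))
        v_axis = np.cross(d, u_axis)
        return d, u_axis, v_axis


@dataclass(frozen=True)
class ROI:
    """Half-open voxel-index box [x0,x1) x [y0,y1) x [z0,z1)."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self) -> None:
        for lo, hi, name in ((self.x0, self.x1, "x"), (self.y0, self.y1, "y"), (self.z0, self.z1, "z")):
            if lo < 0 or hi <= lo:
                raise ValueError(f"ROI {name} bounds invalid: [{lo}, {hi})")

    @classmethod
    def full(cls, stack: ImageStack) -> "ROI":
        z, h, w, _ = stack.shape
        return cls(0, w, 0, h, 0, z)

    def check_within(self, stack: ImageStack) -> None:
        z, h, w, _ = stack.shape
        if self.x1 > w or self.y1 > h or self.z1 > z:
            raise ValueError(
                f"ROI {self} exceeds stack extent (W={w}, H={h}, Z={z})"
            )


@dataclass
class RenderedImage:
    """An 8-bit RGB snapshot plus the view that produced it."""

    pixels: np.ndarray  # (ny, nx, 3) uint8
    view: ViewSpec

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("rendered image must be (ny, nx, 3)")


def render(stack: ImageStack, view: ViewSpec, roi: ROI | None = None) -> RenderedImage:
    """Emission-absorption ray casting of an RGBA stack.

    For every pixel a ray is marched front to back at ``sample_step``
    spacing; each RGBA sample (trilinear in physical coordinates) is
    converted to opacity ``a' = 1 - (1 - A/255)^(step / s_ref)`` with
    ``s_ref = min(spacing)`` and composited with the over operator
    ``C += (1 - alpha) a' c; alpha += (1 - alpha) a'``.  Rays terminate
    early once alpha reaches ``early_termination``; the remaining
    transparency is finally blended with the background colour.  Voxels
    outside the ROI contribute nothing, so cropping exposes interior
    structure without introducing background walls.
    """
    if stack.semantics is not Semantics.RGBA:
        raise ValueError(
            "render requires an RGBA stack (apply a colormap or luminance alpha first)"
        )
    nz, h, w, _ = stack.shape
    sx, sy, sz = stack.spacing
    vol = stack.data.astype(np.float64)
    if roi is not None:
        roi.check_within(stack)
        mask = np.zeros((nz, h, w), dtype=bool)
        mask[roi.z0 : roi.z1, roi.y0 : roi.y1, roi.x0 : roi.x1] = True
        vol = vol.copy()
        vol[~mask, 3] = 0.0

    d, u_axis, v_axis = view.basis()
    nx, ny = view.image_size
    center = np.array([(w - 1) * sx, (h - 1) * sy, (nz - 1) * sz]) / 2.0

    us = (np.arange(nx) - (nx - 1) / 2.0) * view.pixel_pitch
    vs = (np.arange(ny) - (ny - 1) / 2.0) * view.pixel_pitch
    uu, vv = np.meshgrid(us, vs)  # (ny, nx)
    origins = (
        center[np.newaxis, :]
        + uu.ravel()[:, np.newaxis] * u_axis[np.newaxis, :]
        + vv.ravel()[:, np.newaxis] * v_axis[np.newaxis, :]
    )  # (npix, 3); all lie in the plane through the centre normal to d

    corners = np.array(
        [[x, y, z] for x in (0, (w - 1) * sx) for y in (0, (h - 1) * sy) for z in (0, (nz - 1) * sz)]
    )
    proj = corners @ d
    t0 = proj.min() - center @ d
    t1 = proj.max() - center @ d
    n_steps = int(math.floor((t1 - t0) / view.sample_step + 1e-9)) + 1

    order = 1 if view.interpolation == "trilinear" else 0
    ratio = view.sample_step / min(sx, sy, sz)
    npix = origins.shape[0]
    color = np.zeros((npix, 3))
    alpha = np.zeros(npix)
    spacing = np.array([sx, sy, sz])

    for k in range(n_steps):
        if np.all(alpha >= view.early_termination):
            break
        pos = origins + (t0 + k * view.sample_step) * d  # physical
        idx = pos / spacing  # voxel coords (x, y, z)
        coords = np.stack([idx[:, 2], idx[:, 1], idx[:, 0]])  # (z, y, x)
        samples = np.stack(
            [
                ndimage.map_coordinates(vol[..., c], coords, order=order, mode="constant", cval=0.0)
                for c in range(4)
            ],
            axis=-1,
        )
        a = 1.0 - np.power(1.0 - samples[:, 3] / 255.0, ratio)
        a = np.where(alpha >= view.early_termination, 0.0, a)
        weight = (1.0 - alpha) * a
        color += weight[:, np.newaxis] * samples[:, :3]
        alpha = alpha + weight

    bg = np.asarray(view.background, dtype=np.float64)
    color += (1.0 - alpha)[:, np.newaxis] * bg[np.newaxis, :]
    return RenderedImage(quantize_u8(color.reshape(ny, nx, 3)), view)


def reinvert_snapshot(img: RenderedImage) -> RenderedImage:
    """Re-invert a snapshot (v -> 255 - v per channel).

    Renderings of colour-inverted stacks show inverted hues; re-inversion
    of the snapshot recovers the original colours of the histological
    stain.  Applying it twice restores the input.
    """
    return RenderedImage(255 - img.pixels, img.view)


def _rotate_about(vec: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``vec`` about unit ``axis``."""
    a = math.radians(angle_deg)
    k = _unit(axis)
    return (
        vec * math.cos(a)
        + np.cross(k, vec) * math.sin(a)
        + k * (k @ vec) * (1.0 - math.cos(a))
    )


def turntable(
    stack: ImageStack,
    view: ViewSpec,
    n_frames: int,
    axis=(0.0, 1.0, 0.0),
    roi: ROI | None = None,
) -> list[RenderedImage]:
    """Render ``n_frames`` equally spaced azimuthal rotations of the view.

    Frame k uses the base view rotated by k * 360 / n_frames degrees
    about ``axis``; frame 0 is the base view itself.  Useful for
    assembling rotation videos as numbered frame sequences.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    axis = np.asarray(axis, dtype=np.float64)
    frames = []
    for k in range(n_frames):
        angle = 360.0 * k / n_frames
        d = _rotate_about(np.asarray(view.direction), axis, angle)
        up = _rotate_about(np.asarray(view.up), axis, angle)
        frames.append(render(stack, replace(view, direction=tuple(d), up=tuple(up)), roi))
    return frames


def save_snapshot(img: RenderedImage, path: str) -> None:
    """Write a snapshot as 8-bit RGB PNG plus a sidecar view-parameter file."""
    iio.imwrite(path, img.pixels)
    v = img.view
    with open(str(path) + ".view.txt", "w") as fh:
        fh.write("# histovol view parameters\n")
        fh.write(f"direction = {v.direction}\n")
        fh.write(f"up = {v.up}\n")
        fh.write(f"sample_step_um = {v.sample_step}\n")
        fh.write(f"image_size = {v.image_size}\n")
        fh.write(f"pixel_pitch_um = {v.pixel_pitch}\n")
        fh.write(f"background = {v.background}\n")
        fh.write(f"interpolation = {v.interpolation}\n")
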