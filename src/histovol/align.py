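"""Rigid least-squares alignment of adjacent sections.

Physical sectioning places every section on its slide with an arbitrary
shift and rotation, so the stack must be registered before any 3D
operation.  Registration here is rigid (translation + rotation about the
image centre) and minimises the mean squared gray-value difference
between corresponding points of adjacent slices — the classic
least-squares slice alignment objective.  Colour stacks are registered on
their NTSC luminance and the recovered transform is applied to all
channels identically.

The optimiser is an exhaustive coarse grid over (theta, tx, ty) followed
by derivative-free local refinement; it is guaranteed never to return a
transform worse than the identity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .stack_io import ImageStack, Semantics, luminance, quantize_u8

__all__ = [
    "RigidTransform2D",
    "AlignmentResult",
    "register_pair",
    "resample_slice",
    "align_stack",
    "default_fill_value",
]

log = logging.getLogger(__name__)

#: Default search bounds: (pixels of translation, degrees of rotation).
DEFAULT_SEARCH = (15.0, 10.0)


def _normalize_angle(theta: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    theta = math.fmod(theta, 360.0)
    if theta <= -180.0:
        theta += 360.0
    elif theta > 180.0:
        theta -= 360.0
    return theta


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` degrees CCW about the image centre, then
    translation by ``(tx, ty)`` pixels (x = column, y = row)."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", _normalize_angle(float(self.theta)))
        object.__setattr__(self, "tx", float(self.tx))
        object.__setattr__(self, "ty", float(self.ty))

    # p' = R (p - c) + c + t, with p = (x, y) and c the image centre
    def _rotation(self) -> np.ndarray:
        a = math.radians(self.theta)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        r1 = self._rotation()
        t = r1 @ np.array([other.tx, other.ty]) + np.array([self.tx, self.ty])
        return RigidTransform2D(self.theta + other.theta, t[0], t[1])

    def inverse(self) -> "RigidTransform2D":
        r_inv = RigidTransform2D(-self.theta)._rotation()
        t = -(r_inv @ np.array([self.tx, self.ty]))
        return RigidTransform2D(-self.theta, t[0], t[1])

    def apply_points(self, xy: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Apply to an ``(N, 2)`` array of (x, y) points."""
        return (self._rotation() @ (xy - center).T).T + center + np.array([self.tx, self.ty])

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.tx == 0.0 and self.ty == 0.0

    def magnitude(self) -> tuple[float, float]:
        """(translation norm in px, |rotation| in degrees)."""
        return (math.hypot(self.tx, self.ty), abs(self.theta))


# ----------------------------------------------------------------------
# resampling


def _source_coords(shape: tuple[int, int], transform: RigidTransform2D) -> np.ndarray:
    """Row/col source coordinates sampling the input at ``transform``⁻¹."""
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(np.float64)
    src = transform.inverse().apply_points(pts, center)
    # map_coordinates wants (row, col)
    return np.stack([src[:, 1], src[:, 0]])


def _resample_float(
    img: np.ndarray, transform: RigidTransform2D, fill_value: float, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a 2D float image; returns (image, validity mask)."""
    h, w = img.shape[:2]
    coords = _source_coords((h, w), transform)
    valid = (
        (coords[0] >= 0) & (coords[0] <= h - 1) & (coords[1] >= 0) & (coords[1] <= w - 1)
    ).reshape(h, w)
    out = ndimage.map_coordinates(
        img.astype(np.float64), coords, order=order, mode="constant", cval=fill_value
    ).reshape(h, w)
    # bilinear taps outside the source blend toward cval already; force
    # strictly-outside pixels to the fill value exactly
    out[~valid] = fill_value
    return out, valid


def default_fill_value(stack_or_inverted) -> int:
    """0 for inverted (black-background) stacks, 255 for non-inverted."""
    inverted = (
        stack_or_inverted.inverted
        if isinstance(stack_or_inverted, ImageStack)
        else bool(stack_or_inverted)
    )
    return 0 if inverted else 255


def resample_slice(
    img: np.ndarray,
    transform: RigidTransform2D,
    fill_value: float = 0,
    *,
    order: int = 1,
) -> np.ndarray:
    """Apply a rigid transform to a 2D (H, W[, C]) 8-bit slice.

    Bilinear interpolation; pixels mapping outside the source receive
    ``fill_value`` (255 keeps the background white for non-inverted
    stacks, 0 keeps it black for inverted ones).
    """
    if transform.is_identity:
        return img.copy()
    if img.ndim == 2:
        out, _ = _resample_float(img, transform, fill_value, order)
        return quantize_u8(out)
    chans = []
    for c in range(img.shape[-1]):
        out, _ = _resample_float(img[..., c], transform, fill_value, order)
        chans.append(out)
    return quantize_u8(np.stack(chans, axis=-1))


# ----------------------------------------------------------------------
# registration


def _objective(fixed: np.ndarray, moving: np.ndarray, transform: RigidTransform2D) -> float:
    """Mean squared gray difference over the overlap region."""
    resampled, valid = _resample_float(moving, transform, 0.0)
    if valid.sum() < 16:
        return np.inf
    diff = fixed[valid] - resampled[valid]
    return float(np.mean(diff * diff))


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    search: tuple[float, float] = DEFAULT_SEARCH,
    *,
    grid_step: tuple[float, float] = (2.0, 2.0),
    refine: bool = True,
) -> RigidTransform2D:
    """Find the rigid transform minimising the least-squares objective.

    Parameters
    ----------
    fixed, moving
        2D grayscale slices of identical shape (uint8 or float).
    search
        ``(max translation px, max rotation deg)`` bounds, both positive.
    grid_step
        Coarse grid spacing ``(px, deg)`` for the exhaustive stage.

    The returned transform maps ``moving`` onto ``fixed``; its objective
    value never exceeds the objective at the identity.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving slices must have identical shape")
    max_t, max_r = search
    if max_t <= 0 or max_r <= 0:
        raise ValueError("search bounds must be positive")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        warnings.warn("constant image(s): objective is flat, returning identity")
        return RigidTransform2D()

    identity_obj = _objective(fixed, moving, RigidTransform2D())

    step_t, step_r = grid_step
    t_vals = np.arange(-max_t, max_t + 1e-9, step_t)
    r_vals = np.arange(-max_r, max_r + 1e-9, step_r)
    candidates: list[tuple[float, RigidTransform2D]] = [(identity_obj, RigidTransform2D())]
    for th in r_vals:
        for ty in t_vals:
            for tx in t_vals:
                cand = RigidTransform2D(th, tx, ty)
                candidates.append((_objective(fixed, moving, cand), cand))
    candidates.sort(key=lambda c: c[0])
    best_obj, best = candidates[0]

    if refine:
        # the SSD landscape of striped/blobbed content is multi-modal:
        # refine from several leading grid candidates, keep the best
        def fun(p):
            th, tx, ty = p
            th = float(np.clip(th, -max_r, max_r))
            tx = float(np.clip(tx, -max_t, max_t))
            ty = float(np.clip(ty, -max_t, max_t))
            return _objective(fixed, moving, RigidTransform2D(th, tx, ty))

        for _, start in candidates[:5]:
            res = optimize.minimize(
                fun,
                x0=[start.theta, start.tx, start.ty],
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400},
            )
            th = float(np.clip(res.x[0], -max_r, max_r))
            tx = float(np.clip(res.x[1], -max_t, max_t))
            ty = float(np.clip(res.x[2], -max_t, max_t))
            refined = RigidTransform2D(th, tx, ty)
            refined_obj = _objective(fixed, moving, refined)
            if refined_obj < best_obj:
                best, best_obj = refined, refined_obj

    # monotone improvement guarantee
    if best_obj > identity_obj:
        return RigidTransform2D()
    return best


# ----------------------------------------------------------------------
# stack alignment


@dataclass
class AlignmentResult:
    """Per-slice cumulative transforms plus residual diagnostics.

    ``transforms[0]`` is always the identity (slice 0 is the reference).
    ``residual_before[i]`` / ``residual_after[i]`` hold the mean squared
    gray difference between slice ``i`` and its aligned predecessor at the
    identity and at the recovered transform, for i >= 1.
    """

    transforms: list[RigidTransform2D]
    residual_before: list[float]
    residual_after: list[float]
    fill_value: float

    def to_table(self, path: str) -> None:
        """Serialize to a plain-text table (re-importable as overrides)."""
        with open(path, "w") as fh:
            fh.write("# slice\ttheta_deg\ttx_px\tty_px\tresidual_before\tresidual_after\n")
            for i, t in enumerate(self.transforms):
                rb = self.residual_before[i - 1] if i >= 1 else 0.0
                ra = self.residual_after[i - 1] if i >= 1 else 0.0
                fh.write(f"{i}\t{t.theta:.6f}\t{t.tx:.6f}\t{t.ty:.6f}\t{rb:.6f}\t{ra:.6f}\n")

    @staticmethod
    def read_overrides(path: str) -> dict[int, RigidTransform2D]:
        """Read a table written by :meth:`to_table` as manual overrides."""
        overrides = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                overrides[int(parts[0])] = RigidTransform2D(
                    float(parts[1]), float(parts[2]), float(parts[3])
                )
        return overrides


def _registration_image(img: np.ndarray) -> np.ndarray:
    if img.shape[-1] >= 3:
        return luminance(img[..., :3].astype(np.float64), quantize=False)
    return img[..., 0].astype(np.float64)


def align_stack(
    stack: ImageStack,
    fill_value: float | None = None,
    search: tuple[float, float] = DEFAULT_SEARCH,
    *,
    grid_step: tuple[float, float] = (2.0, 2.0),
    overrides: dict[int, RigidTransform2D] | None = None,
) -> tuple[ImageStack, AlignmentResult]:
    """Align a stack by sequential pairwise rigid registration.

    Slice 0 is fixed; each subsequent slice is registered to its already
    aligned predecessor, so the recovered pairwise transform is directly
    the cumulative transform for that slice and is applied exactly once.
    ``overrides`` maps slice index to a user-supplied transform that
    replaces the automatic estimate (the manual-correction escape hatch).
    Out-of-bounds pixels receive ``fill_value`` (default: 0 for inverted
    stacks, 255 for non-inverted ones).
    """
    if stack.n_slices < 2:
        raise ValueError("align_stack needs at least two slices")
    if fill_value is None:
        fill_value = default_fill_value(stack)
    overrides = overrides or {}

    aligned = np.empty_like(stack.data)
    aligned[0] = stack.data[0]
    transforms: list[RigidTransform2D] = [RigidTransform2D()]
    res_before: list[float] = []
    res_after: list[float] = []

    prev_reg = _registration_image(aligned[0])
    for i in range(1, stack.n_slices):
        moving_reg = _registration_image(stack.data[i])
        before = _objective(prev_reg, moving_reg, RigidTransform2D())
        if i in overrides:
            t = overrides[i]
        else:
            t = register_pair(prev_reg, moving_reg, search, grid_step=grid_step)
        after = _objective(prev_reg, moving_reg, t)
        if after > before and i not in overrides:  # safety net
            t, after = RigidTransform2D(), before
        aligned[i] = resample_slice(stack.data[i], t, fill_value)
        transforms.append(t)
        res_before.append(before)
        res_after.append(after)
        prev_reg = _registration_image(aligned[i])
        log.info(
            "align: slice %d theta=%.3f tx=%.3f ty=%.3f residual %.2f -> %.2f",
            i, t.theta, t.tx, t.ty, before, after,
        )

    return stack.with_data(aligned), AlignmentResult(
        transforms, res_before, res_after, fill_value
    )
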