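"""Alpha channels, transparency transfer functions, and colormaps.

In the emission-absorption rendering model every voxel needs an opacity.
For colour stacks the opacity comes from an alpha channel computed as the
NTSC luminance of the colour channels: after colour inversion the
background is black, so background voxels become almost totally
transparent ("linear transparency function").  The stored 8-bit alpha can
then be reshaped by a transparency transfer function before rendering:

* ``linear_gamma``   — A' = 255 (A/255)^gamma; gamma = 1 is the identity,
  gamma > 1 gives softer and gamma < 1 harder renderings;
* ``threshold``      — A' = 255 if A > t else 0 (completely opaque object
  voxels, completely transparent background);
* ``power_increasing`` — A' = A^x / 255^(x-1) (much softer than linear);
* ``power_decreasing`` — A' = 255 - (255-A)^x / 255^(x-1) (harder than
  linear, softer than a threshold);
* ``piecewise``      — monotone linear interpolation of control points.

Grayscale stacks are rendered through a 256-entry colormap; the built-in
"glow" map is a black-red-orange-yellow-white ramp with its highest
entries flattened to avoid glare.  Both colormaps and transfer functions
can be inverted, which makes rendering of non-inverted stacks possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import ImageStack, Semantics, luminance, quantize_u8, to_grayscale

__all__ = [
    "TransferFunction",
    "Colormap",
    "luminance_alpha",
    "tf_linear_gamma",
    "tf_threshold",
    "tf_power_increasing",
    "tf_power_decreasing",
    "apply_transfer",
    "apply_colormap",
    "invert_colormap",
    "invert_transfer",
    "glow_colormap",
]

_A = np.arange(256, dtype=np.float64)


# ----------------------------------------------------------------------
# scalar transfer-function kernels (double precision in, rounded out)


def tf_linear_gamma(a, gamma: float = 1.0):
    """A' = round(255 (A/255)^gamma); gamma=1 is the exact identity."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = np.asarray(a, dtype=np.float64)
    return quantize_u8(255.0 * (a / 255.0) ** gamma)


def tf_threshold(a, t: float = 10.0):
    """A' = 255 where A > t (strict), else 0."""
    if t >= 255:
        raise ValueError("threshold must be below 255")
    a = np.asarray(a, dtype=np.float64)
    return quantize_u8(np.where(a > t, 255.0, 0.0))


def tf_power_increasing(a, x: float = 3.0):
    """A' = round(A^x / 255^(x-1)) — increasing slope, soft rendering."""
    if x < 1:
        raise ValueError("exponent must be >= 1")
    a = np.asarray(a, dtype=np.float64)
    return quantize_u8(a**x / 255.0 ** (x - 1.0))


def tf_power_decreasing(a, x: float = 3.0):
    """A' = round(255 - (255-A)^x / 255^(x-1)) — decreasing slope, hard."""
    if x < 1:
        raise ValueError("exponent must be >= 1")
    a = np.asarray(a, dtype=np.float64)
    return quantize_u8(255.0 - (255.0 - a) ** x / 255.0 ** (x - 1.0))


_KINDS = ("linear_gamma", "threshold", "power_increasing", "power_decreasing", "piecewise")


@dataclass(frozen=True)
class TransferFunction:
    """Parametric monotone map from stored 8-bit alpha to 8-bit opacity.

    Construct through the classmethods.  ``inverted=True`` evaluates
    f(255 - A), which pairs with an inverted colormap to render
    non-inverted stacks.
    """

    kind: str
    gamma: float = 1.0
    t: float = 10.0
    x: float = 3.0
    points: tuple[tuple[float, float], ...] = ()
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.kind == "piecewise":
            pts = self.points
            if len(pts) < 2 or pts[0] != (0.0, 0.0) or pts[-1] != (255.0, 255.0):
                raise ValueError("piecewise points must run from (0, 0) to (255, 255)")
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            if any(b < a for a, b in zip(xs, xs[1:])) or any(
                b < a for a, b in zip(ys, ys[1:])
            ):
                raise ValueError("piecewise control points must be monotone")

    # constructors ------------------------------------------------------
    @classmethod
    def linear_gamma(cls, gamma: float = 1.0) -> "TransferFunction":
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        return cls("linear_gamma", gamma=gamma)

    @classmethod
    def threshold(cls, t: float = 10.0) -> "TransferFunction":
        if t >= 255:
            raise ValueError("threshold must be below 255")
        return cls("threshold", t=t)

    @classmethod
    def power_increasing(cls, x: float = 3.0) -> "TransferFunction":
        if x < 1:
            raise ValueError("exponent must be >= 1")
        return cls("power_increasing", x=x)

    @classmethod
    def power_decreasing(cls, x: float = 3.0) -> "TransferFunction":
        if x < 1:
            raise ValueError("exponent must be >= 1")
        return cls("power_decreasing", x=x)

    @classmethod
    def piecewise(cls, points) -> "TransferFunction":
        pts = tuple((float(a), float(b)) for a, b in points)
        return cls("piecewise", points=pts)

    @classmethod
    def from_config(cls, cfg: dict) -> "TransferFunction":
        """Build from a config mapping, e.g. {kind: threshold, t: 10}."""
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        inverted = bool(cfg.pop("inverted", False))
        tf = getattr(cls, kind)(**cfg)
        return tf.invert() if inverted else tf

    # evaluation --------------------------------------------------------
    def lut(self) -> np.ndarray:
        """The full 256-entry uint8 lookup table."""
        a = 255.0 - _A if self.inverted else _A
        if self.kind == "linear_gamma":
            return tf_linear_gamma(a, self.gamma)
        if self.kind == "threshold":
            return tf_threshold(a, self.t)
        if self.kind == "power_increasing":
            return tf_power_increasing(a, self.x)
        if self.kind == "power_decreasing":
            return tf_power_decreasing(a, self.x)
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return quantize_u8(np.interp(a, xs, ys))

    def __call__(self, a):
        out = self.lut()[np.asarray(a, dtype=np.intp)]
        return out if np.ndim(a) else int(out)

    def invert(self) -> "TransferFunction":
        """f -> (A -> f(255 - A)); double inversion is the identity."""
        return TransferFunction(
            self.kind, self.gamma, self.t, self.x, self.points, not self.inverted
        )


def invert_transfer(tf: TransferFunction) -> TransferFunction:
    return tf.invert()


# ----------------------------------------------------------------------
# colormaps


@dataclass
class Colormap:
    """256-entry RGB lookup table with optional per-entry opacity."""

    name: str
    table: np.ndarray  # (256, 3) uint8
    opacity: np.ndarray | None = None  # (256,) uint8

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.uint8)
        if self.table.shape != (256, 3):
            raise ValueError("colormap table must have shape (256, 3)")
        if self.opacity is not None:
            self.opacity = np.asarray(self.opacity, dtype=np.uint8)
            if self.opacity.shape != (256,):
                raise ValueError("opacity must have shape (256,)")

    def to_text(self, path: str) -> None:
        """Write as a plain-text table: index, R, G, B[, A]."""
        with open(path, "w") as fh:
            fh.write(f"# colormap {self.name}\n")
            for i in range(256):
                r, g, b = self.table[i]
                if self.opacity is None:
                    fh.write(f"{i}\t{r}\t{g}\t{b}\n")
                else:
                    fh.write(f"{i}\t{r}\t{g}\t{b}\t{self.opacity[i]}\n")

    @classmethod
    def from_text(cls, path: str, name: str | None = None) -> "Colormap":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([int(v) for v in line.split()])
        rows.sort(key=lambda r: r[0])
        table = np.array([r[1:4] for r in rows], dtype=np.uint8)
        opacity = (
            np.array([r[4] for r in rows], dtype=np.uint8) if len(rows[0]) > 4 else None
        )
        return cls(name or "from_file", table, opacity)


#: Control points of the built-in glow ramp (package convention): a
#: black -> dark red -> orange -> pale yellow -> white ramp at equal
#: spacing, with monotone non-decreasing luminance.
GLOW_CONTROL_POINTS = (
    (0, 0, 0),
    (128, 0, 0),
    (255, 128, 0),
    (255, 255, 128),
    (255, 255, 255),
)


def glow_colormap(clip_top: int = 16) -> Colormap:
    """The built-in "glow" colormap for grayscale rendering.

    ``clip_top`` highest entries are flattened to the last unclipped
    colour, cutting off the brightest values so renderings are not glary.
    """
    if not (0 <= clip_top < 256):
        raise ValueError("clip_top must lie in [0, 256)")
    pts = np.array(GLOW_CONTROL_POINTS, dtype=np.float64)
    xs = np.linspace(0, 255, len(pts))
    table = np.stack(
        [np.interp(_A, xs, pts[:, c]) for c in range(3)], axis=-1
    )
    table = quantize_u8(table)
    if clip_top:
        table[256 - clip_top :] = table[255 - clip_top]
    return Colormap(f"glow(clip_top={clip_top})", table)


def invert_colormap(cmap: Colormap) -> Colormap:
    """Entry i becomes entry 255 - i (opacity included)."""
    return Colormap(
        f"inverted({cmap.name})",
        cmap.table[::-1].copy(),
        None if cmap.opacity is None else cmap.opacity[::-1].copy(),
    )


# ----------------------------------------------------------------------
# stack operations


def luminance_alpha(stack: ImageStack) -> ImageStack:
    """Attach an alpha channel computed by NTSC grayscale conversion.

    For the standard workflow the stack is colour-inverted first, so the
    background is black and receives alpha 0 — almost total transparency
    in the object background.
    """
    if stack.semantics is not Semantics.RGB:
        raise ValueError(f"luminance_alpha requires an RGB stack; got {stack.semantics.value}")
    alpha = luminance(stack.data.astype(np.float64))
    rgba = np.concatenate([stack.data, alpha[..., np.newaxis]], axis=-1)
    return stack.with_data(rgba)


def apply_transfer(stack: ImageStack, tf: TransferFunction) -> ImageStack:
    """Transform the alpha channel voxelwise; colour channels untouched."""
    if stack.semantics is not Semantics.RGBA:
        raise ValueError(f"apply_transfer requires an RGBA stack; got {stack.semantics.value}")
    data = stack.data.copy()
    data[..., 3] = tf.lut()[data[..., 3]]
    return stack.with_data(data)


def apply_colormap(
    stack: ImageStack,
    cmap: Colormap | None = None,
    tf: TransferFunction | None = None,
) -> ImageStack:
    """Map a grayscale stack to RGBA: RGB = map[gray], A = tf(gray).

    Defaults: the built-in glow map with a linear (gamma = 1)
    transparency function.  A colormap carrying per-entry opacity uses
    that opacity as the base alpha before ``tf`` is applied.
    """
    if stack.semantics is not Semantics.GRAY:
        raise ValueError(f"apply_colormap requires a grayscale stack; got {stack.semantics.value}")
    cmap = cmap or glow_colormap()
    tf = tf or TransferFunction.linear_gamma(1.0)
    gray = stack.data[..., 0]
    rgb = cmap.table[gray]
    base = cmap.opacity[gray] if cmap.opacity is not None else gray
    alpha = tf.lut()[base]
    rgba = np.concatenate([rgb, alpha[..., np.newaxis]], axis=-1)
    return stack.with_data(rgba)
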