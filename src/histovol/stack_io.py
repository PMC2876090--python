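"""Reading, writing, and converting serial-section image stacks.

A stack of digitised serial sections is held as a single z-ordered 8-bit
array together with its physical voxel spacing.  In-plane spacing comes
from the micrograph pixel size; spacing along z is the physical section
thickness, which is usually several times larger, so the voxels are
anisotropic.  All downstream stages (alignment, filtering, rendering)
operate on this container.
"""

from __future__ import annotations

import glob as _glob
import os
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Semantics",
    "ImageStack",
    "StackReport",
    "quantize_u8",
    "luminance",
    "read_stack",
    "write_stack",
    "load_stack",
    "to_grayscale",
    "GRAY_WEIGHTS",
]

#: NTSC luminance weights used for every grayscale conversion in the package.
GRAY_WEIGHTS = (0.3, 0.59, 0.11)

METADATA_FILENAME = "stack.meta"


class Semantics(str, Enum):
    """Channel interpretation of a stack."""

    GRAY = "gray"
    RGB = "rgb"
    RGBA = "rgba"


_CHANNELS_TO_SEMANTICS = {1: Semantics.GRAY, 3: Semantics.RGB, 4: Semantics.RGBA}


def quantize_u8(values: np.ndarray | float) -> np.ndarray:
    """Re-quantize floating point image data to 8 bit.

    The package-wide rounding rule: evaluate in double precision, round to
    nearest integer with ties away from zero, clamp to [0, 255].
    """
    x = np.asarray(values, dtype=np.float64)
    rounded = np.where(x >= 0.0, np.floor(x + 0.5), np.ceil(x - 0.5))
    return np.clip(rounded, 0.0, 255.0).astype(np.uint8)


def luminance(rgb: np.ndarray, *, quantize: bool = True) -> np.ndarray:
    """NTSC luminance ``0.3 R + 0.59 G + 0.11 B`` of an ``(..., 3)`` array.

    With ``quantize=False`` the double-precision value is returned.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] < 3:
        raise ValueError("luminance requires at least three channels")
    w = np.asarray(GRAY_WEIGHTS)
    lum = rgb[..., 0] * w[0] + rgb[..., 1] * w[1] + rgb[..., 2] * w[2]
    return quantize_u8(lum) if quantize else lum


@dataclass
class ImageStack:
    """A z-ordered stack of 8-bit section images with physical spacing.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, H, W, C)`` with ``C`` in {1, 3, 4},
        dtype ``uint8``.  A ``(n_slices, H, W)`` array is promoted to
        single-channel.
    spacing
        ``(sx, sy, sz)`` in micrometres; ``sz`` is the section thickness.
    inverted
        Whether values are colour-inverted relative to the original
        white-background micrographs.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    inverted: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:
            arr = arr[..., np.newaxis]
        if arr.ndim != 4:
            raise ValueError(f"stack data must be (Z, H, W, C); got shape {arr.shape}")
        if arr.dtype != np.uint8:
            raise ValueError(f"stack data must be uint8; got {arr.dtype}")
        if arr.shape[-1] not in _CHANNELS_TO_SEMANTICS:
            raise ValueError(f"channel count must be 1, 3 or 4; got {arr.shape[-1]}")
        if arr.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        self.data = arr
        sx, sy, sz = (float(s) for s in self.spacing)
        if min(sx, sy, sz) <= 0:
            raise ValueError(f"spacing must be positive; got {self.spacing}")
        self.spacing = (sx, sy, sz)

    # ------------------------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    @property
    def semantics(self) -> Semantics:
        return _CHANNELS_TO_SEMANTICS[self.n_channels]

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.spacing, self.inverted)

    def with_data(self, data: np.ndarray, *, inverted: bool | None = None) -> "ImageStack":
        """New stack sharing this stack's metadata but holding ``data``."""
        return ImageStack(
            data,
            self.spacing,
            self.inverted if inverted is None else inverted,
        )

    def report(self) -> "StackReport":
        return StackReport.from_stack(self)


@dataclass
class StackReport:
    """Summary of a stack's geometry and value distribution."""

    n_slices: int
    dims: tuple[int, int, int]  # (H, W, C)
    spacing: tuple[float, float, float]
    anisotropy_ratio: float
    semantics: Semantics
    value_min: int
    value_max: int
    value_mean: float

    @classmethod
    def from_stack(cls, stack: ImageStack) -> "StackReport":
        sx, sy, sz = stack.spacing
        return cls(
            n_slices=stack.n_slices,
            dims=stack.data.shape[1:],
            spacing=stack.spacing,
            anisotropy_ratio=sz / max(sx, sy),
            semantics=stack.semantics,
            value_min=int(stack.data.min()),
            value_max=int(stack.data.max()),
            value_mean=float(stack.data.mean()),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        h, w, c = self.dims
        return (
            f"stack: {self.n_slices} slices of {h}x{w} ({self.semantics.value}), "
            f"spacing {self.spacing} um, "
            f"anisotropy (thickness : pixel edge) = {self.anisotropy_ratio:.3g}, "
            f"values [{self.value_min}, {self.value_max}] mean {self.value_mean:.1f}"
        )


# ----------------------------------------------------------------------
# reading


def _numeric_key(name: str):
    stem = Path(name).stem
    digits = ""
    for ch in reversed(stem):
        if ch.isdigit():
            digits = ch + digits
        elif digits:
            break
    return (int(digits) if digits else -1, name)


def _read_image(path: str) -> np.ndarray:
    try:
        if path.lower().endswith((".tif", ".tiff")):
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"{path!r}: only 8-bit images are supported (got {img.dtype})")
    if img.ndim == 2:
        img = img[..., np.newaxis]
    if img.ndim != 3 or img.shape[-1] not in _CHANNELS_TO_SEMANTICS:
        raise ValueError(f"{path!r}: unsupported image shape {img.shape}")
    return img


def read_stack(
    path_pattern: str,
    spacing: tuple[float, float, float] | None = None,
    *,
    numeric_sort: bool = False,
    inverted: bool = False,
) -> ImageStack:
    """Read a numbered image sequence (TIFF or PNG) into a stack.

    Slices are ordered by zero-padded lexicographic filename order by
    default; ``numeric_sort=True`` sorts by trailing number instead.  If
    ``spacing`` is omitted, a sidecar metadata file written by
    :func:`write_stack` is consulted.
    """
    files = sorted(_glob.glob(path_pattern))
    if not files:
        raise IOError(f"pattern {path_pattern!r} matches no files")
    if numeric_sort:
        files = sorted(files, key=_numeric_key)

    if spacing is None:
        meta = _read_sidecar(os.path.join(os.path.dirname(path_pattern), METADATA_FILENAME))
        if meta is None:
            raise ValueError("no spacing given and no sidecar metadata file found")
        spacing = meta["spacing"]
        inverted = meta["inverted"]

    first = _read_image(files[0])
    slices = [first]
    for f in files[1:]:
        img = _read_image(f)
        if img.shape != first.shape:
            raise ValueError(
                f"dimension mismatch: {f!r} has shape {img.shape[:2]}x{img.shape[2]} "
                f"but {files[0]!r} has {first.shape[:2]}x{first.shape[2]}"
            )
        slices.append(img)
    return ImageStack(np.stack(slices, axis=0), spacing, inverted=inverted)


def _read_sidecar(path: str):
    if not os.path.exists(path):
        return None
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    return {
        "spacing": (
            float(values["spacing_x_um"]),
            float(values["spacing_y_um"]),
            float(values["spacing_z_um"]),
        ),
        "inverted": values.get("inverted", "false").lower() == "true",
    }


# ----------------------------------------------------------------------
# writing


def write_stack(stack: ImageStack, directory: str | Path, *, prefix: str = "slice") -> list[str]:
    """Write one uncompressed 8-bit TIFF per slice plus a sidecar metadata file.

    Returns the list of written image paths.  ``read_stack`` on the written
    directory reproduces the stack bit-exactly.
    """
    if stack.n_slices < 1:
        raise ValueError("refusing to write an empty stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(stack.n_slices - 1)))
    paths = []
    for i in range(stack.n_slices):
        img = stack.data[i]
        if img.shape[-1] == 1:
            img = img[..., 0]
        path = directory / f"{prefix}_{i:0{width}d}.tif"
        tifffile.imwrite(str(path), img, compression=None)
        paths.append(str(path))
    sx, sy, sz = stack.spacing
    with open(directory / METADATA_FILENAME, "w") as fh:
        fh.write("# histovol stack metadata\n")
        fh.write(f"spacing_x_um = {sx!r}\n")
        fh.write(f"spacing_y_um = {sy!r}\n")
        fh.write(f"spacing_z_um = {sz!r}\n")
        fh.write(f"semantics = {stack.semantics.value}\n")
        fh.write(f"inverted = {str(stack.inverted).lower()}\n")
    return paths


def load_stack(directory: str | Path, *, prefix: str = "slice") -> ImageStack:
    """Load a stack previously written with :func:`write_stack`."""
    return read_stack(str(Path(directory) / f"{prefix}_*.tif"))


# ----------------------------------------------------------------------
# conversion


def to_grayscale(stack: ImageStack) -> ImageStack:
    """Convert an RGB stack to grayscale with the NTSC weighting.

    Per voxel ``gray = round(0.3 R + 0.59 G + 0.11 B)``; spacing and the
    inverted flag are preserved.
    """
    if stack.semantics is not Semantics.RGB:
        raise ValueError(f"to_grayscale requires an RGB stack; got {stack.semantics.value}")
    gray = luminance(stack.data.astype(np.float64))
    return stack.with_data(gray[..., np.newaxis])
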