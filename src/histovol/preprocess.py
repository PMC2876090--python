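"""Automated pre-alignment editing of section micrographs.

Replaces the interactive editing steps of a typical serial-section
workflow with reproducible operations: colour inversion, background
white-point normalisation, slice-to-slice stain equalisation, in-plane
downsizing under the thickness-to-pixel anisotropy rule, and optional
speckle suppression on the background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack, Semantics, luminance, quantize_u8

__all__ = [
    "PreprocessConfig",
    "AnisotropyVerdict",
    "invert",
    "normalize_background",
    "equalize_slices",
    "downsample",
    "check_anisotropy",
    "despeckle",
    "FOREGROUND_FRACTION",
]

log = logging.getLogger(__name__)

#: Pixels with luminance below this fraction of the slice white point are
#: classified as foreground (stained tissue) during equalisation.
FOREGROUND_FRACTION = 0.9

#: Fraction of darkest pixels whose mean luminance defines a slice's
#: staining level.  Rank-based selection is stable under multiplicative
#: gain, so equalisation is idempotent; a threshold-classified set is
#: not, because boundary pixels drift in and out of it as the gain moves.
STAIN_LEVEL_QUANTILE = 0.10


@dataclass
class PreprocessConfig:
    """Options for the pre-alignment stage.

    ``background_percentile`` is the upper quantile (fraction in (0.5, 1])
    used to estimate the white point; ``max_anisotropy`` bounds the ratio
    of section thickness to in-plane pixel edge length (default 3:1);
    ``despeckle_radius`` of 0 disables speckle suppression.
    """

    invert: bool = True
    background_percentile: float = 0.95
    equalize: bool = False
    target_xy_spacing: float | str = "auto"
    max_anisotropy: float = 3.0
    despeckle_radius: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.background_percentile <= 1.0):
            raise ValueError("background_percentile must lie in (0.5, 1]")
        if self.max_anisotropy < 1.0:
            raise ValueError("max_anisotropy must be >= 1")


def invert(stack: ImageStack) -> ImageStack:
    """Colour-invert a stack: every channel value v becomes 255 - v.

    An alpha channel, if present, is left untouched.  The inverted flag is
    toggled, so applying the operation twice restores the input.
    """
    data = stack.data.copy()
    n_color = 3 if stack.n_channels >= 3 else 1
    data[..., :n_color] = 255 - data[..., :n_color]
    return stack.with_data(data, inverted=not stack.inverted)


def _slice_luminance(img: np.ndarray) -> np.ndarray:
    if img.shape[-1] >= 3:
        return luminance(img[..., :3].astype(np.float64), quantize=False)
    return img[..., 0].astype(np.float64)


def normalize_background(
    stack: ImageStack, background_percentile: float = 0.95
) -> ImageStack:
    """Set each slice's background to the white point (255).

    Per slice and channel, the value at the given upper percentile is
    mapped to 255 by a linear rescale of values above a preserved anchor
    (the slice's 1st percentile); values at or below the anchor are left
    in place.  Operates on the white-background micrograph convention,
    i.e. before inversion.
    """
    if stack.inverted:
        raise ValueError("normalize_background expects a non-inverted stack")
    if not (0.5 < background_percentile <= 1.0):
        raise ValueError("background_percentile must lie in (0.5, 1]")
    out = np.empty_like(stack.data)
    n_color = 3 if stack.n_channels >= 3 else 1
    for z in range(stack.n_slices):
        for c in range(stack.n_channels):
            chan = stack.data[z, :, :, c].astype(np.float64)
            if c >= n_color:  # alpha untouched
                out[z, :, :, c] = stack.data[z, :, :, c]
                continue
            anchor = np.percentile(chan, 1.0)
            white = np.percentile(chan, background_percentile * 100.0)
            if white <= anchor:
                warnings.warn(
                    f"slice {z} channel {c}: zero dynamic range, passed through"
                )
                out[z, :, :, c] = stack.data[z, :, :, c]
                continue
            scale = (255.0 - anchor) / (white - anchor)
            rescaled = np.where(chan > anchor, anchor + (chan - anchor) * scale, chan)
            out[z, :, :, c] = quantize_u8(rescaled)
    return stack.with_data(out)


def equalize_slices(
    stack: ImageStack, background_percentile: float = 0.95
) -> tuple[ImageStack, np.ndarray]:
    """Equalise staining intensity across slices by per-slice gain.

    A slice's staining level is the mean luminance of its darkest
    ``STAIN_LEVEL_QUANTILE`` fraction of pixels (a rank-based deep-
    foreground statistic: stable under the multiplicative gain being
    estimated, and insensitive to the anti-aliased tissue/background
    boundary).  Channels are multiplied by a gain chosen so every
    slice's level matches the stack-wide median level.  Slices with no
    pixels darker than ``FOREGROUND_FRACTION`` of the white point carry
    no foreground and keep gain 1.  Returns the adjusted stack and the
    per-slice gains.
    """
    if stack.n_slices < 2:
        raise ValueError("equalize_slices needs at least two slices")
    lum = np.stack([_slice_luminance(stack.data[z]) for z in range(stack.n_slices)])
    means = np.full(stack.n_slices, np.nan)
    for z in range(stack.n_slices):
        white = np.percentile(lum[z], background_percentile * 100.0)
        if not (lum[z] < FOREGROUND_FRACTION * white).any():
            continue  # no foreground on this slice
        flat = np.sort(lum[z].ravel())
        k = max(1, int(round(STAIN_LEVEL_QUANTILE * flat.size)))
        means[z] = flat[:k].mean()
    if np.isnan(means).all():
        warnings.warn("no slice has foreground pixels; gains all 1")
        return stack.copy(), np.ones(stack.n_slices)
    target = np.nanmedian(means)
    gains = np.ones(stack.n_slices)
    out = np.empty_like(stack.data)
    n_color = 3 if stack.n_channels >= 3 else 1
    for z in range(stack.n_slices):
        if np.isnan(means[z]) or means[z] <= 0:
            warnings.warn(f"slice {z} has no foreground pixels; gain 1")
            out[z] = stack.data[z]
            continue
        gains[z] = target / means[z]
        out[z] = stack.data[z]
        scaled = stack.data[z, :, :, :n_color].astype(np.float64) * gains[z]
        out[z, :, :, :n_color] = quantize_u8(scaled)
        log.info("equalize: slice %d gain %.4f", z, gains[z])
    return stack.with_data(out), gains


def downsample(stack: ImageStack, target_xy_spacing: float) -> ImageStack:
    """Reduce in-plane resolution by area-average resampling.

    Only x and y are resampled; the z axis (section thickness) is
    untouched.  ``target_xy_spacing`` must not be finer than the current
    in-plane spacing.
    """
    sx, sy, sz = stack.spacing
    if target_xy_spacing < max(sx, sy) - 1e-12:
        raise ValueError(
            f"target spacing {target_xy_spacing} um is finer than source ({sx}, {sy}) um"
        )
    fx = target_xy_spacing / sx
    fy = target_xy_spacing / sy
    if abs(fx - 1.0) < 1e-12 and abs(fy - 1.0) < 1e-12:
        return stack.copy()

    z, h, w, c = stack.data.shape
    if abs(fx - round(fx)) < 1e-9 and abs(fy - round(fy)) < 1e-9:
        bx, by = int(round(fx)), int(round(fy))
        h2, w2 = h // by, w // bx
        if h % by or w % bx:
            warnings.warn("image extent not divisible by downsampling factor; trimming edge")
        trimmed = stack.data[:, : h2 * by, : w2 * bx, :].astype(np.float64)
        blocks = trimmed.reshape(z, h2, by, w2, bx, c)
        result = blocks.mean(axis=(2, 4))
    else:
        from skimage.transform import resize

        h2 = max(1, int(round(h / fy)))
        w2 = max(1, int(round(w / fx)))
        result = np.empty((z, h2, w2, c))
        for i in range(z):
            result[i] = resize(
                stack.data[i].astype(np.float64),
                (h2, w2),
                anti_aliasing=True,
                preserve_range=True,
                mode="reflect",
            )
    return ImageStack(
        quantize_u8(result),
        (sx * fx, sy * fy, sz),
        inverted=stack.inverted,
    )


@dataclass
class AnisotropyVerdict:
    """Outcome of the thickness-to-pixel ratio check."""

    ratio: float
    max_anisotropy: float
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        state = "pass" if self.passed else "FAIL"
        return f"anisotropy {self.ratio:.3g} (bound {self.max_anisotropy:g}): {state}"


def check_anisotropy(
    spacing: tuple[float, float, float], max_anisotropy: float = 3.0
) -> AnisotropyVerdict:
    """Check the ratio of section thickness to in-plane pixel edge length.

    The verdict passes iff ``sz / max(sx, sy) <= max_anisotropy``; the
    bound is inclusive and defaults to 3:1.  Ratios above it produce
    elongated voxels and visibly anisotropic renderings.
    """
    sx, sy, sz = spacing
    if min(sx, sy, sz) <= 0:
        raise ValueError(f"spacing must be positive; got {spacing}")
    ratio = sz / max(sx, sy)
    return AnisotropyVerdict(ratio, max_anisotropy, ratio <= max_anisotropy)


def despeckle(
    stack: ImageStack,
    radius: int = 1,
    background_percentile: float = 0.95,
) -> ImageStack:
    """Suppress dark speckles (dust, stain precipitate) on the background.

    Background-classified pixels (luminance >= ``FOREGROUND_FRACTION`` of
    the slice white point in the median-filtered image) are replaced by
    their median-filtered value; tissue pixels are untouched.
    """
    if radius < 1:
        return stack.copy()
    size = 2 * radius + 1
    out = stack.data.copy()
    for z in range(stack.n_slices):
        img = stack.data[z]
        med = np.stack(
            [ndimage.median_filter(img[:, :, c], size=size) for c in range(img.shape[-1])],
            axis=-1,
        )
        lum_med = _slice_luminance(med)
        white = np.percentile(lum_med, background_percentile * 100.0)
        background = lum_med >= FOREGROUND_FRACTION * white
        out[z][background] = med[background]
    return stack.with_data(out)
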