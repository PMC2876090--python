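"""Seeded synthetic serial-section stacks with ground truth.

No real section series ships with the package, so every pipeline stage
is validated on phantoms: stacks of stained-section-like images built
from simple geometric primitives (ellipsoid, tube, shell) rasterised in
stain colours on a white background, then corrupted slice by slice with
the three artifact classes that plague real serial sections —

* per-slice rigid misalignment (random translation + rotation),
* smooth geometric distortion (a band-limited elastic displacement
  field, mimicking uneven stretching of paraffin sections), and
* staining variation: a multiplicative per-slice stain gain, a
  cumulative bleaching decay of stain density toward white, and dark
  salt speckles emulating dust or stain precipitate.

Every random draw comes from independent per-artifact streams spawned
from one seed, and everything applied is recorded in a
:class:`PhantomTruth`, so tests can score recovery exactly.  Disabling
one artifact class never changes the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .align import RigidTransform2D, resample_slice
from .stack_io import ImageStack, quantize_u8

__all__ = [
    "Primitive",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "degrade_only",
    "default_geometry",
]

#: Value of dark dust/precipitate speckles (8-bit).
SPECKLE_VALUE = 40


@dataclass(frozen=True)
class Primitive:
    """A rasterisable geometric primitive in voxel coordinates.

    ``kind`` is ``ellipsoid`` (filled), ``shell`` (ellipsoidal band of
    relative ``thickness``) or ``tube`` (elliptic cylinder along
    ``axis``).  ``center`` is (x, y, z); ``radii`` (rx, ry, rz) in
    voxels; ``color`` the stain RGB painted over what is below it.
    """

    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    color: tuple[int, int, int]
    thickness: float = 0.15
    axis: str = "z"

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "shell", "tube"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")
        if self.axis not in "xyz":
            raise ValueError("tube axis must be one of x, y, z")

    def coverage(self, x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
        """Anti-aliased membership of this primitive on one z plane."""
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        if self.kind == "tube":
            # drop the coordinate along the tube axis
            if self.axis == "z":
                f = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                r_eff = min(rx, ry)
            elif self.axis == "y":
                f = ((x - cx) / rx) ** 2 + ((z - cz) / rz) ** 2
                r_eff = min(rx, rz)
            else:
                f = ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
                r_eff = min(ry, rz)
        else:
            f = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
            r_eff = min(rx, ry, rz)
        rho = np.sqrt(np.maximum(f, 0.0))
        edge = 1.2 / max(r_eff, 1e-9)  # ~1.2 voxel wide smooth edge
        if self.kind == "shell":
            dist = np.abs(rho - 1.0) - self.thickness
            return np.clip(0.5 - dist / edge, 0.0, 1.0)
        return np.clip(0.5 - (rho - 1.0) / edge, 0.0, 1.0)

    def within(self, extent: tuple[int, int, int]) -> bool:
        w, h, d = extent
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        grow = 1.0 + (self.thickness if self.kind == "shell" else 0.0)
        lo = (cx - rx * grow, cy - ry * grow, cz - rz * grow)
        hi = (cx + rx * grow, cy + ry * grow, cz + rz * grow)
        if self.kind == "tube":  # infinite along its axis; clamp that axis
            i = "xyz".index(self.axis)
            lo = tuple(0 if j == i else lo[j] for j in range(3))
            hi = tuple(0 if j == i else hi[j] for j in range(3))
        return all(l >= -0.5 for l in lo) and all(
            h_ <= e - 0.5 for h_, e in zip(hi, (w, h, d))
        )


def default_geometry(extent: tuple[int, int, int]) -> tuple[Primitive, ...]:
    """Two-tone stained "specimen": body ellipsoid, membrane shell, gut tube.

    Colours emulate a two-colour histological stain (pale pink tissue,
    blue-purple nuclear/gut contrast) on the white slide background.
    """
    w, h, d = extent
    c = (w / 2.0 - 0.5, h / 2.0 - 0.5, d / 2.0 - 0.5)
    body_r = (0.36 * w, 0.30 * h, 0.40 * d)
    # gut tube and nucleus sit off-centre: real specimens are not
    # rotationally symmetric, and neither should the registration target be
    return (
        Primitive("ellipsoid", c, body_r, color=(210, 150, 170)),
        Primitive("shell", c, body_r, color=(120, 70, 160), thickness=0.12),
        Primitive(
            "tube",
            (0.60 * w, 0.42 * h, c[2]),
            (0.09 * w, 0.11 * h, 0.10 * d),
            color=(70, 50, 150),
            axis="z",
        ),
        Primitive(
            "ellipsoid",
            (0.38 * w, 0.58 * h, c[2]),
            (0.07 * w, 0.07 * h, 0.22 * d),
            color=(90, 60, 60),
        ),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded description of phantom geometry and artifact magnitudes.

    ``jitter`` is (sigma_t px, sigma_theta deg) of the per-slice rigid
    misalignment; ``elastic`` is (RMS amplitude px, smoothness px) of the
    per-slice displacement field; ``stain_gain`` the s.d. of the
    multiplicative per-slice gain; ``bleach_rate`` the per-slice
    fractional decay of stain density; ``speckle`` the per-slice density
    of dark speckles (fraction of pixels).  The same seed always yields
    bit-identical output.
    """

    extent: tuple[int, int, int] = (64, 64, 40)  # (W, H, n_slices)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    geometry: tuple[Primitive, ...] | None = None
    jitter: tuple[float, float] = (2.0, 1.0)
    elastic: tuple[float, float] = (1.5, 8.0)
    stain_gain: float = 0.05
    bleach_rate: float = 0.003
    speckle: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.extent) < 1:
            raise ValueError("extent must be positive")
        if min(self.jitter) < 0 or min(self.elastic) < 0:
            raise ValueError("artifact magnitudes must be >= 0")
        if self.stain_gain < 0 or self.bleach_rate < 0 or self.speckle < 0:
            raise ValueError("artifact magnitudes must be >= 0")

    def resolved_geometry(self) -> tuple[Primitive, ...]:
        return self.geometry if self.geometry is not None else default_geometry(self.extent)


@dataclass
class PhantomTruth:
    """Ground truth recorded while degrading a phantom."""

    clean: ImageStack
    transforms: list[RigidTransform2D]
    gains: np.ndarray
    bleach: np.ndarray
    speckle_coords: list[np.ndarray]  # per slice, (n, 2) row/col

    def __post_init__(self) -> None:
        n = self.clean.n_slices
        if not (
            len(self.transforms) == len(self.gains) == len(self.bleach) == len(self.speckle_coords) == n
        ):
            raise ValueError("truth record lengths must match n_slices")


# ----------------------------------------------------------------------


def rasterize_clean(spec: PhantomSpec) -> ImageStack:
    """Rasterise the primitives onto a white background, slice by slice."""
    w, h, d = spec.extent
    geometry = spec.resolved_geometry()
    for prim in geometry:
        if not prim.within(spec.extent):
            raise ValueError(f"primitive {prim.kind} extends outside the extent {spec.extent}")
    cols, rows = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    volume = np.empty((d, h, w, 3), dtype=np.uint8)
    for iz in range(d):
        img = np.full((h, w, 3), 255.0)
        for prim in geometry:
            cov = prim.coverage(cols, rows, float(iz))[..., np.newaxis]
            img = img * (1.0 - cov) + np.asarray(prim.color, dtype=np.float64) * cov
        volume[iz] = quantize_u8(img)
    return ImageStack(volume, spec.spacing, inverted=False)


def _draw_artifacts(spec: PhantomSpec, shape: tuple[int, int, int]):
    """Draw all artifact randomness from independent per-class streams."""
    d, h, w = shape
    ss = np.random.SeedSequence(spec.seed)
    s_rigid, s_elastic, s_gain, s_speckle = ss.spawn(4)
    rng_r = np.random.default_rng(s_rigid)
    rng_e = np.random.default_rng(s_elastic)
    rng_g = np.random.default_rng(s_gain)
    rng_s = np.random.default_rng(s_speckle)

    sigma_t, sigma_r = spec.jitter
    rigid_draws = rng_r.standard_normal((d, 3))  # (tx, ty, theta) std normals
    transforms = [
        RigidTransform2D(th * sigma_r, tx * sigma_t, ty * sigma_t)
        for tx, ty, th in rigid_draws
    ]

    amp, smooth = spec.elastic
    fields = []
    for _ in range(d):
        noise = rng_e.standard_normal((2, h, w))
        if amp > 0:
            f = ndimage.gaussian_filter(noise, (0, smooth, smooth), mode="reflect")
            rms = np.sqrt(np.mean(f * f))
            f = f * (amp / rms) if rms > 0 else f
        else:
            f = np.zeros_like(noise)
        fields.append(f)

    gains = 1.0 + spec.stain_gain * rng_g.standard_normal(d)
    gains = np.clip(gains, 0.05, None)
    bleach = (1.0 - spec.bleach_rate) ** np.arange(d)

    n_speckle = int(round(spec.speckle * h * w))
    speckle_coords = []
    for _ in range(d):
        rc = np.stack(
            [rng_s.integers(0, h, n_speckle), rng_s.integers(0, w, n_speckle)], axis=1
        )
        speckle_coords.append(rc if spec.speckle > 0 else rc[:0])
    return transforms, fields, gains, bleach, speckle_coords


def degrade_only(stack: ImageStack, spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Apply the artifact cascade to an existing (clean, aligned) stack.

    Per slice i: elastic distortion, then the rigid jitter transform,
    then the multiplicative stain gain, the cumulative bleach factor
    (1 - bleach_rate)^i fading stain density toward white, and finally
    dark speckles.  Returns the degraded stack and the exact truth.
    """
    d, h, w, c = stack.shape
    transforms, fields, gains, bleach, speckle_coords = _draw_artifacts(spec, (d, h, w))

    out = np.empty_like(stack.data)
    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    for i in range(d):
        img = stack.data[i].astype(np.float64)
        if spec.elastic[0] > 0:
            dy, dx = fields[i]
            coords = np.stack([rows + dy, cols + dx])
            img = np.stack(
                [
                    ndimage.map_coordinates(img[..., ch], coords, order=1, mode="nearest")
                    for ch in range(c)
                ],
                axis=-1,
            )
        t = transforms[i]
        if not t.is_identity:
            img = np.stack(
                [
                    _rigid_float(img[..., ch], t)
                    for ch in range(c)
                ],
                axis=-1,
            )
        img = np.clip(img * gains[i], 0.0, 255.0)
        img = 255.0 - bleach[i] * (255.0 - img)
        for r_, c_ in speckle_coords[i]:
            img[r_, c_, :3] = SPECKLE_VALUE
        out[i] = quantize_u8(img)

    truth = PhantomTruth(stack.copy(), transforms, gains, bleach, speckle_coords)
    return stack.with_data(out), truth


def _rigid_float(img: np.ndarray, t: RigidTransform2D) -> np.ndarray:
    from .align import _resample_float

    out, _ = _resample_float(img, t, 255.0)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Build the clean volume and apply the seeded artifact cascade.

    With all artifact magnitudes zero, every slice is exactly the planar
    section of the clean volume; identical specs give identical bytes.
    """
    clean = rasterize_clean(spec)
    return degrade_only(clean, spec)
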