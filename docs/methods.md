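# Methods

This note documents the models, numerical conventions, and design
choices behind `histovol`, in enough detail to reproduce or audit any
stage.

## The volume model

A stack is a z-ordered array of 8-bit slices (1, 3 or 4 channels) with
physical voxel spacing `(sx, sy, sz)` in μm; `sz` is the section
thickness.  Coordinates are x = column, y = row, z = slice index,
0-based, origin at the top-left of slice 0; ROIs are half-open index
boxes.  Voxels are anisotropic in general; the quality rule of thumb is
that the thickness-to-pixel ratio `sz / max(sx, sy)` should not exceed
3:1 (the bound is inclusive), since longer voxels produce visibly
anisotropic renderings.  Semithin resin sections (~0.5–1 μm) support
ratios near 2 at sub-micron pixel sizes; paraffin sections (3–15 μm)
force coarser in-plane sampling.

**Quantisation.** All 8-bit arithmetic is evaluated in double
precision, rounded to the nearest integer with ties away from zero, and
clamped to [0, 255].  Multi-stage filters quantise once, at the end.

**Grayscale conversion.** Everywhere the package needs luminance it
uses the NTSC weighting `gray = 0.3 R + 0.59 G + 0.11 B`.

## Preprocessing

* **Inversion** maps every colour value v to 255 − v (alpha untouched)
  and toggles a flag.  Downstream defaults (alignment fill, rendering
  background) key off this flag.  Rendering does not strictly require
  inversion — colormaps and transfer functions can be inverted instead —
  but most volume viewers and colormaps assume bright-object/dark-
  background data, so inversion is the default pathway.
* **Background normalisation** maps, per slice and channel, the value
  at an upper percentile (default 0.95) to 255 by a linear rescale
  anchored at the slice's 1st percentile, turning the slide background
  uniformly white.  Constant slices pass through with a warning.
* **Stain equalisation** estimates each slice's staining level as the
  mean luminance of its darkest 10 % of pixels and applies a
  multiplicative gain matching every level to the stack-wide median
  level.  The level statistic is rank-based deliberately: a
  threshold-classified foreground mean is biased by the anti-aliased
  tissue/background boundary (whose pixels drift in and out of the
  class as intensity varies) and is not idempotent, whereas rank
  selection is stable under the very gain being estimated.  Slices with
  no pixels below 0.9× the white point (or a fully saturated dark
  decile) keep gain 1 with a warning.  Gains are returned and logged.
  The statistic is identifiable only if adjacent sections carry
  comparable tissue content — true for real serial sections at 1–15 μm
  spacing, and for z-uniform phantoms; not for a ball phantom sampled
  pole to pole.
* **Downsizing** is area-average in-plane only (exact block means for
  integer spacing ratios, anti-aliased resampling otherwise); z is
  never resampled.
* **Despeckling** (optional, off by default) replaces
  background-classified pixels by their median-filtered value,
  automating the manual removal of dust and stain precipitate; tissue
  pixels are never touched.

## Rigid alignment

Sequential pairwise registration: slice 0 is the reference; slice i is
registered to the already aligned slice i−1, and the recovered
transform — rotation θ about the image centre plus translation
(tx, ty) — is applied once with bilinear interpolation.  The objective
is the mean squared gray difference over the overlap region (colour
slices are compared on their NTSC luminance; the transform is applied
to all channels).  Out-of-bounds pixels receive the fill value: 255
(white) for non-inverted stacks so the background stays uniform for any
later segmentation work, 0 (black) for inverted stacks.

The optimiser is an exhaustive coarse grid over (θ, tx, ty) (default
bounds ±15 px, ±10°; default grid step 2 px / 2°) followed by
Nelder–Mead refinement started from the five best grid candidates — the
SSD landscape of striped histological content is multi-modal, and a
single restart occasionally polishes into the wrong basin.  The
returned transform never scores worse than the identity, so per-pair
residuals are guaranteed not to increase.  Drift is not redistributed
(no global bundle adjustment): sequential propagation mirrors the
slice-by-slice workflow this package automates, and a per-slice manual
override table is the escape hatch for the occasional failure.

Accuracy: on smooth 8-bit synthetic slices the registration recovers
random transforms (|t| ≤ 5 px, |θ| ≤ 5°) to well within 0.25 px /
0.25°.  The validation generates the moving slice analytically from the
continuous scene rather than by resampling the fixed slice: resampling
would add interpolation blur to the moving image only, which measurably
shifts the SSD optimum away from the true transform.

## 3D filtering

**Gaussian.** Separable convolution with a sampled, truncated,
normalised Gaussian per axis, reflective boundaries, in voxel units.
Even kernel sizes have no centre voxel and would shift the volume by
half a voxel; they are promoted to the next odd size with a notice (the
nominal 6×6×6 default therefore runs as 7×7×7).  Defaults: 6×6×6, σ=1
per axis for paraffin material; 3×3×3, σ=1 as the modest option for
resin; resin stacks render well with no filtering at all.

**Edge-preserving.** Perona–Malik-type nonlinear diffusion:

    u ← u + dt · div( g(|∇u_σ|) ∇u ),   g(m) = exp(−(m/contrast)²)

with the gradient estimated on the Gaussian-presmoothed field (scale
`sigma`, voxels).  `contrast` (default 3.5 gray levels) is the edge
threshold: gradients well above it diffuse essentially not at all;
`step` (default 5) is the nominal time increment and `stop` (default
25) the total diffusion time, so the defaults run floor(stop/step) = 5
nominal iterations and `stop < step` performs none.  Each nominal step
is integrated with internal sub-steps at dt ≤ 1/(2·ndim) = 1/6: a
single explicit update of size 5 would be unconditionally unstable
wherever the field is flat (g ≈ 1), while at the stable sub-step the
update is a convex combination of neighbours, giving the maximum
principle (output range never exceeds input range) and exact
preservation of constants.  The conductance interpretation of the
parameter names (contrast/sigma/step/stop) is a documented reading of a
common commercial filter's controls, not a reproduction of proprietary
code; as contrast → ∞ the filter converges to linear diffusion.

**Colour stacks** are split into R, G, B; each channel is filtered
independently with identical parameters as a grayscale volume; on
recombination the alpha channel is recomputed as the NTSC luminance of
the filtered channels, so a recombined stack always carries a linear
transparency function without manual adjustment.

## Transparency and colormaps

Stored alpha is 8-bit; the renderer converts it to opacity at sampling
time.  The transfer families, all monotone on [0, 255]:

* `linear_gamma`: A' = 255 (A/255)^γ — γ = 1 exact identity, γ > 1
  softer, γ < 1 harder;
* `threshold`: A' = 255 if A > t (strict), else 0 — completely opaque
  object voxels over a completely transparent background;
* `power_increasing`: A' = A^x / 255^(x−1) — much softer than linear
  (default x = 3);
* `power_decreasing`: A' = 255 − (255−A)^x / 255^(x−1) — harder than
  linear, softer than threshold; the exact mirror of the increasing
  family;
* `piecewise`: monotone linear interpolation of user control points
  from (0,0) to (255,255).

The built-in "glow" colormap is a black → (128,0,0) → (255,128,0) →
(255,255,128) → white ramp at equal spacing with the top `clip_top`
(default 16) entries flattened to the last unclipped colour, preventing
glare in bright regions.  The exact ramp is a package convention: its
defining properties (wide black-to-white contrast range through
red/orange/yellow, monotone luminance, clipped top) are what the tests
pin down.  Both colormaps and transfer functions support inversion
(entry i ↦ entry 255−i; f ↦ f(255−A)), which renders non-inverted
stacks directly.

## Rendering

Orthographic ray casting with the emission–absorption model.  For each
pixel a ray is marched front to back at `sample_step` μm; RGBA is
sampled trilinearly in physical coordinates (nearest-neighbour mode
exists for oracle tests); each sample's stored alpha A becomes opacity

    a = 1 − (1 − A/255)^(sample_step / s_ref),   s_ref = min(sx, sy, sz)

which makes accumulated opacity independent of the sampling rate for
homogeneous regions, and is composited with the over operator
(C ← C + (1−α)·a·c, α ← α + (1−α)·a) with early termination at
α ≥ 0.995 (configurable; invisible at 8-bit output).  The background
colour is blended only after ray exit, so ROI cropping (implemented by
zeroing alpha outside the box) exposes interior structure without
introducing background walls.  Ray start positions share a common
origin projection, so axis-aligned views with pixel pitch equal to the
in-plane spacing sample voxel centres exactly.  Snapshots are 8-bit RGB
PNG with a sidecar view-parameter file; `reinvert_snapshot` (v ↦ 255−v)
recovers the original stain colours from renderings of inverted stacks;
`turntable` emits equally spaced azimuthal rotations as numbered
frames.  No perspective projection and no gradient shading: the
emission–absorption model here uses voxel colour and opacity only.

## Phantoms

The phantom generator is the package's test bed: it builds a clean RGB
volume by rasterising primitives (ellipsoid, shell, elliptic tube) in
stain colours on a white background with ~1-voxel anti-aliased edges,
then corrupts each slice with the three serial-section artifact
classes:

* rigid jitter — translation ~ N(0, σ_t) per axis and rotation
  ~ N(0, σ_θ) (defaults 2 px, 1°), applied last so alignment can be
  scored against the exact inverse;
* elastic distortion — a per-slice displacement field of
  Gaussian-smoothed white noise (smoothness 8 px) scaled to a target
  RMS amplitude (default 1.5 px), mimicking uneven stretching of
  paraffin sections; alignment is rigid-only, so this knob demonstrates
  why the 3D filters are needed;
* staining variation — a multiplicative per-slice gain ~ N(1, 0.05) on
  pixel values, a cumulative bleaching factor (1 − r)^i (default
  r = 0.003 per slice) decaying stain density toward white, and dark
  salt speckles (default density 5·10⁻⁴) emulating dust and
  precipitate.

The artifact magnitudes are package conventions chosen to be plausible
for stained paraffin material, not measurements.  All randomness comes
from independent per-class streams spawned from one seed, with every
draw made regardless of whether its class is enabled — so the same seed
is bit-reproducible and disabling one artifact class provably leaves
the others' draws unchanged.  Everything applied is recorded in a
`PhantomTruth` (clean volume, per-slice transforms, gains, bleach
factors, speckle coordinates).  The default geometry places the gut
tube and a nucleus off-centre: real specimens are not rotationally
symmetric, and a centred ellipsoid would leave the rotation component
of registration nearly unidentifiable.

What the phantoms do not emulate: optics (defocus, vignetting,
chromatic effects), staining chemistry, knife chatter or compression
folds, and section loss.  Passing the recovery tests therefore shows
the pipeline is correct under its own artifact model, not that the
model captures every failure mode of real material.

## Pipeline and problem sizes

The orchestrated order is read → normalise/equalise → invert → align →
filter (per embedding preset; per channel for colour) → alpha/colormap
→ transfer → render, with every intermediate written and a manifest
recording the config hash and seed; equalisation runs before alignment
because stain differences between adjacent slides are a known failure
mode of the least-squares objective, and inversion runs before
alignment so the fill default matches the background.  End-to-end runs
are deterministic under a fixed seed.

The validation suite runs phantoms at 32–64 px in-plane and 6–60
slices, registration trials at 48×48 px, and filter oracles at 8³ —
sizes chosen so the whole suite completes in a few minutes while every
oracle comparison stays exhaustive (brute-force convolution,
triple-loop diffusion, closed-form compositing, exhaustive 256-value
transfer checks).

## Known limitations

* Rigid-only alignment: no elastic correction and no external-marker
  congruencing; drift across very long series is not redistributed.
* The edge-preserving filter is an interpretation of the named
  parameters, not a bit-compatible reproduction of any commercial
  implementation ("step" could alternatively mean an iteration count;
  supply `step`/`stop` accordingly if you hold that reading).
* Stain equalisation assumes adjacent sections carry comparable tissue
  content and an approximately multiplicative intensity model; severe
  non-uniform bleaching within a slice is out of its reach.
* The renderer is a correctness-first CPU implementation; large stacks
  render in seconds-to-minutes, not interactively.
* 16-bit and floating-point stacks, proprietary mesh formats, video
  encoding, stereo pairs, and surface rendering are out of scope.
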