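# Methods

This note documents the models and procedures implemented by
`petct_label`, the parameters that matter, the numerical choices, and
what the synthetic phantoms do and do not demonstrate.

## Image model and conventions

All slices are single-frame grayscale rasters held as float arrays in
[0, 255], quantized (round half up) only on PNG export. Coordinates are
0-based with x = column, y = row, origin top-left; every point file and
the label JSON use this convention. DICOM stored values are converted to
display gray by a linear min–max rescale of the slice — deterministic
and parameter-free; no modality-specific windowing is attempted, and a
constant slice maps to zeros. Strong tracer uptake is rendered as LOW
gray on PET throughout.

## Enhancement

PET slices are enlarged to the CT grid with align-corners bilinear
interpolation: output corner pixels coincide with source corner pixels,
so upscaling an image to its own size is the identity and constants are
fixed points at any size. The interpolant is evaluated in the
`a + f·(b − a)` form, which keeps those identities exact in floating
point and confines every output value to the source range.

The piecewise gray stretch zeroes everything below a floor `PETmin` and
maps `[PETmin, 255]` linearly onto `[0, 255]`. It is computed as
`255·((F − PETmin)/(255 − PETmin))` so both endpoints are exact;
`PETmin = 255` is rejected (division by zero). `PETmin` is a config
value; the `"auto"` setting uses the nearest-rank 1st percentile of the
enlarged image, a parameter-free default that suppresses only the
darkest sliver of the histogram. Note its limits: when the dark uptake
of interest occupies less than 1 % of the pixels — typical for a single
small lesion on a quiet background, and exactly the situation in our
noise-free phantoms — the 1st percentile lands on the body intensity and
the stretch nulls the scene. For such inputs a fixed `PETmin` (0
disables the stretch entirely) is the right setting, and the end-to-end
tests use it; on clinical-like slices with full-range histograms the
auto rule behaves as intended.

## Registration

The six-parameter affine is fitted to ≥ 3 non-collinear landmark pairs
by least squares. Because the x′ and y′ rows decouple, each is an
independent bivariate regression; the closed form uses
centroid-centered second-moment sums (numerically better conditioned
than, and algebraically identical to, the raw-sum expressions) with the
translation recovered from the centroids. The tests verify agreement
with an independently constructed 2n×6 normal-equation solve to 1e-9
and exact recovery of generating transforms. Degeneracy (collinear
points, singular second-moment matrix) raises rather than returning an
ill-defined fit; two point pairs are not accepted since six parameters
would be underdetermined.

Frame pre-alignment maps the PET field-of-view bounding box onto the
CT's with an axis-aligned scale-and-shift. Foreground is defined as
pixels differing from the modal border value — parameter-free, but it
assumes the scanner field of view dominates the border. The full
transform is the landmark fit expressed in pre-aligned coordinates,
composed with the pre-alignment; with exact landmarks the composition
recovers the true transform regardless of the pre-alignment, which only
improves conditioning in the noisy case.

Resampling is pull-based: each output pixel samples the input at the
inverse-mapped location with bilinear interpolation, 0-filled outside
the input. This avoids holes under expansion.

## Fusion

Both registered images are decomposed with `sym8` (16 taps, near
symmetric, orthogonal — chosen for low phase distortion) at 3 levels by
default, symmetric boundary extension. Depth is configurable; the
feasibility rule is `2^levels ≤ min(width, height)`. Every subband —
approximation and details alike, the simplest reading of proportional
synthesis — is blended as a fixed convex combination at the configured
percentages (default 40:60 PET:CT, selectable per run; a sweep utility
emits the five candidate ratios 30:70 … 70:30 for visual selection). An
optional soft threshold shrinks detail coefficients toward zero before
blending (default off). Reconstruction is clipped to [0, 255].

Consequences tested: perfect reconstruction to < 1e-8, weight endpoints
returning the inputs, self-fusion identity, linearity before clipping,
and constant blends equal to the convex combination. With the published
float64 sym8 taps, a constant image's detail coefficients vanish only to
~6e-10 at intensity 100 (filter-normalization rounding times signal
scale), which is the precision floor for such identities.

Pseudocolor is display-only: a fixed 256-entry piecewise-linear ramp
black→blue→cyan→green→yellow→red→white indexed by the rounded gray
level. Segmentation never reads RGB.

## Segmentation and labeling

The click is refined to the minimum-gray pixel in a ±8-pixel window
(clipped at the borders), ties broken by first occurrence in row-major
order — deterministic and therefore reproducible across runs. Region
growth is stack-based over the 8-neighborhood: a pixel joins iff its
gray is strictly below `ValueMin·(1 + increase)` (default increase 1.0,
i.e. < 2·ValueMin, strict as specified) and its Chebyshev distance from
the refined seed is ≤ `max_radius`. The stop rule is read as a hard
Chebyshev radius cap (default 10 px) — the only deterministic reading —
and is configurable because real lesions can exceed it. A seed of value
0 makes the criterion unsatisfiable and degenerates to a single-pixel
region by design. Growth is verified against an independent
connected-component oracle under the same predicate.

The boundary is a clockwise Moore-neighbor trace from the
topmost-then-leftmost member, augmented so that on every diagonal step
the member "elbow" pixel is visited too: the path is then 4-connected
and covers all members 8-adjacent to the background in simply-connected
regions. Known limitation: interior holes are not traced (only the
outer contour); hole boundaries can occur for noisy growth but not for
the disk-like lesions the cap produces. The bounding rectangle is the
tight min/max of member coordinates. Since the PET has already been
resampled into CT space, region coordinates transfer to CT unchanged
(identity mapping); a general affine transfer (map, round half up,
recompute boundary and box) is provided for workflows that label on the
native PET grid.

SUV is `concentration / (dose / weight)` — the standard
per-kilogram-normalized convention, adopted because the bare division
chain "concentration / dose / weight" is ambiguous about grouping.
Classes: > 2.5 malignant, 2.0–2.5 critical (inclusive), < 2.0 benign;
the three intervals partition [0, ∞).

## Phantoms: what they emulate and what they do not

A phantom pair is generated analytically: the CT is a dim background
(30) with a brighter body ellipse (120) and lesion disks at body + 60;
the PET scene, evaluated at CT coordinates mapped through the known
PET→CT affine, is white (255, no uptake) outside the body, mid-gray
(180) inside, and dark (default 30, always < half the body gray) inside
lesions. Gaussian intensity noise (default σ = 2, clipped to [0, 255])
is added last; all randomness comes from one seed. Landmarks sit at the
body-ellipse extrema plus its center — mimicking the 4–5 manually
chosen points of a real session — and are exactly consistent with the
generating transform, so fitting them recovers it to machine precision.
The default misalignment composes the align-corners 168→512 scaling
with a fixed mild perturbation (1 % scale, 0.3 % shear, ~3 px shift),
on the order of the few-mm offsets reported for sequential PET/CT
acquisition.

What passing phantom tests show: the geometry chain (fit → warp → grow
→ trace → box → export) is exact where exactness is mathematically
attainable, and each stage honors its contract. What they do not show:
performance on real tracer statistics (no sinogram/reconstruction
physics, no partial-volume blur, no physiologic uptake organs), or
label quality under inter-reader variability.

**End-to-end exactness regime.** Bilinear resampling across *different*
grid resolutions blurs lesion edges, so strict mask equality after a
168→512 chain is impossible for any method; the end-to-end recovery
test therefore uses equal PET/CT grids with an integer-translation
misalignment, where warping is exact and the grown region can (and
does) match the truth disk pixel-for-pixel — recognition 100 %, false
positives 0 % by the agreement formulas. The lesion radius (5 px) is
chosen so the whole disk lies within the Chebyshev cap of the refined
seed, which lands on the disk's topmost pixel by the row-major
tie-break. The full-resolution 168→512 chain is exercised separately
without exactness claims.

## Problem sizes in the test suite

Randomized identities run on 64×64 images (wavelets, region growing)
and ≤ 9-point landmark sets (100 draws); end-to-end phantoms use
128×128 grids, with the default 168×168/512×512 geometry covered by the
enlargement and CLI tests. These sizes make every property exercised at
full fidelity while keeping the suite fast.
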