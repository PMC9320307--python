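"""Synthetic PET/CT phantom pairs with known ground truth.

No patient scans ship with the package, so every pipeline stage is
exercised on analytic phantoms: a CT-like 512x512 slice (dim background,
brighter elliptical body, brighter lesion disks) paired with a PET-like
168x168 slice in which strong tracer uptake appears as LOW gray — lesions
are dark disks on a mid-gray body, with the no-uptake surround rendered
white.  The PET grid is related to the CT grid by a known affine
(``misalign``), landmark pairs exactly consistent with that transform are
emitted, and the per-lesion truth masks are exact disks in CT
coordinates; everything is deterministic given the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ValidationError
from .image_io import ControlPointSet, GrayImage
from .register import AffineParams, compose


@dataclass
class Lesion:
    """A circular lesion: center (CT coordinates), radius in CT pixels,
    and its LOW PET gray value (strong uptake)."""

    cx: float
    cy: float
    radius: float
    pet_intensity: float = 30.0


@dataclass
class BodyEllipse:
    cx: float
    cy: float
    semi_x: float
    semi_y: float
    ct_intensity: float = 120.0


def _default_lesions() -> list[Lesion]:
    return [Lesion(300.0, 220.0, 8.0, 30.0)]


@dataclass
class PhantomSpec:
    """Ground-truth geometry and acquisition conditions for one pair."""

    ct_size: tuple[int, int] = (512, 512)   # (width, height)
    pet_size: tuple[int, int] = (168, 168)
    lesions: list[Lesion] = field(default_factory=_default_lesions)
    body_ellipse: BodyEllipse | None = None
    ct_background: float = 30.0
    pet_background: float = 180.0  # body uptake gray; surround is 255
    misalign: AffineParams | None = None  # full PET-grid -> CT-grid affine
    noise_sigma: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(*self.ct_size, *self.pet_size) < 8:
            raise ValidationError("phantom grids must be at least 8 pixels")
        if self.body_ellipse is None:
            w, h = self.ct_size
            self.body_ellipse = BodyEllipse(w / 2.0, h / 2.0,
                                            0.35 * w, 0.30 * h)
        self.validate()

    def validate(self) -> None:
        body = self.body_ellipse
        for i, les in enumerate(self.lesions):
            if les.radius < 2:
                raise ValidationError(f"lesion {i}: radius must be >= 2 px")
            if les.pet_intensity >= self.pet_background / 2.0:
                raise ValidationError(
                    f"lesion {i}: PET gray {les.pet_intensity} must stay "
                    f"below half the body gray {self.pet_background} so the "
                    "2xValueMin growth criterion can separate it"
                )
            # conservative containment: disk inside the shrunken ellipse
            ax, ay = body.semi_x - les.radius, body.semi_y - les.radius
            if ax <= 0 or ay <= 0 or (
                ((les.cx - body.cx) / ax) ** 2
                + ((les.cy - body.cy) / ay) ** 2 > 1.0
            ):
                raise ValidationError(
                    f"lesion {i} at ({les.cx}, {les.cy}) r={les.radius} "
                    "does not fit inside the body ellipse"
                )

    def base_scale(self) -> AffineParams:
        """Align-corners PET-grid -> CT-grid scaling (no misalignment)."""
        (cw, ch), (pw, ph) = self.ct_size, self.pet_size
        return AffineParams((cw - 1) / (pw - 1), 0.0, 0.0,
                            (ch - 1) / (ph - 1), 0.0, 0.0)

    def pet_to_ct(self) -> AffineParams:
        """The resolved full PET->CT transform.

        Defaults to the align-corners scaling composed with a mild fixed
        perturbation (1% scale error, slight shear, a few pixels of
        shift) emulating the residual misalignment of sequential PET and
        CT acquisitions.
        """
        if self.misalign is not None:
            return self.misalign
        perturb = AffineParams(1.01, 0.003, -0.003, 0.99, 3.0, -2.0)
        return compose(perturb, self.base_scale())


def disk_mask(shape_hw: tuple[int, int], cx: float, cy: float,
              radius: float) -> np.ndarray:
    """Boolean raster of pixels whose centers lie within ``radius`` of
    (cx, cy); works for any radius (0.5 gives a single pixel)."""
    h, w = shape_hw
    ys, xs = np.mgrid[0:h, 0:w]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2


@dataclass
class PhantomPair:
    pet: GrayImage
    ct: GrayImage
    truth_masks: list  # per-lesion boolean arrays in CT coordinates
    points: ControlPointSet
    pet_to_ct: AffineParams
    spec: PhantomSpec


def _pet_scene(spec: PhantomSpec, xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """PET gray at continuous CT coordinates: 255 outside the body (no
    uptake), body gray inside, lesion gray inside lesion disks."""
    body = spec.body_ellipse
    inside = (((xc - body.cx) / body.semi_x) ** 2
              + ((yc - body.cy) / body.semi_y) ** 2) <= 1.0
    val = np.where(inside, spec.pet_background, 255.0)
    for les in spec.lesions:
        in_les = (xc - les.cx) ** 2 + (yc - les.cy) ** 2 <= les.radius ** 2
        val = np.where(in_les, les.pet_intensity, val)
    return val


def make_phantom_pair(spec: PhantomSpec | None = None) -> PhantomPair:
    """Generate one paired slice set with truth masks and landmarks."""
    spec = spec or PhantomSpec()
    body = spec.body_ellipse
    cw, ch = spec.ct_size
    pw, ph = spec.pet_size
    transform = spec.pet_to_ct()
    rng = np.random.default_rng(spec.rng_seed)

    # CT: background + body ellipse + brighter lesion disks
    ys, xs = np.mgrid[0:ch, 0:cw].astype(float)
    inside = (((xs - body.cx) / body.semi_x) ** 2
              + ((ys - body.cy) / body.semi_y) ** 2) <= 1.0
    ct_px = np.where(inside, body.ct_intensity, spec.ct_background)
    lesion_ct = min(255.0, body.ct_intensity + 60.0)
    truth_masks = []
    for les in spec.lesions:
        mask = disk_mask((ch, cw), les.cx, les.cy, les.radius)
        ct_px = np.where(mask, lesion_ct, ct_px)
        truth_masks.append(mask)

    # PET: evaluate the scene analytically at the mapped grid locations
    pys, pxs = np.mgrid[0:ph, 0:pw].astype(float)
    xc = transform.a * pxs + transform.b * pys + transform.h
    yc = transform.c * pxs + transform.d * pys + transform.k
    pet_px = _pet_scene(spec, xc, yc)

    if spec.noise_sigma > 0:
        ct_px = ct_px + rng.normal(0.0, spec.noise_sigma, ct_px.shape)
        pet_px = pet_px + rng.normal(0.0, spec.noise_sigma, pet_px.shape)
    ct_px = np.clip(ct_px, 0.0, 255.0)
    pet_px = np.clip(pet_px, 0.0, 255.0)

    # landmarks at the body-ellipse extrema plus its center (CT coords),
    # with source points exactly consistent with the generating transform
    targets = np.array(
        [
            (body.cx - body.semi_x, body.cy),
            (body.cx + body.semi_x, body.cy),
            (body.cx, body.cy - body.semi_y),
            (body.cx, body.cy + body.semi_y),
            (body.cx, body.cy),
        ],
        dtype=float,
    )
    sources = transform.invert().apply(targets)
    points = ControlPointSet(sources, targets)

    return PhantomPair(
        pet=GrayImage(pet_px, "PET", "phantom-pet"),
        ct=GrayImage(ct_px, "CT", "phantom-ct"),
        truth_masks=truth_masks,
        points=points,
        pet_to_ct=transform,
        spec=spec,
    )


def truth_mask_area(spec: PhantomSpec, lesion_index: int) -> int:
    """Pixel count of one ground-truth disk mask (CT coordinates)."""
    if not 0 <= lesion_index < len(spec.lesions):
        raise BoundsError(f"no lesion with index {lesion_index}")
    les = spec.lesions[lesion_index]
    cw, ch = spec.ct_size
    return int(disk_mask((ch, cw), les.cx, les.cy, les.radius).sum())
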