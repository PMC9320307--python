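"""PET enlargement and piecewise grayscale enhancement.

PET slices (128x128 or 168x168) are upsampled to the CT grid (512x512 by
default) with align-corners bilinear interpolation, then contrast in the
uptake range is stretched by a piecewise linear transform: everything
below a floor PETmin is mapped to 0 and [PETmin, 255] is stretched to the
full [0, 255] range,

    G = 0                               if F <  PETmin
    G = 255 / (255 - PETmin) * (F - PETmin)  if F >= PETmin

so that G(PETmin) = 0 and G(255) = 255 exactly.  PETmin can be a fixed
intensity or ``"auto"``, the nearest-rank 1st percentile of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from .errors import ValidationError
from .image_io import GrayImage

AUTO = "auto"


@dataclass
class EnhanceConfig:
    target_size: tuple[int, int] = (512, 512)  # (width, height)
    pet_min: float | str = AUTO

    def __post_init__(self) -> None:
        w, h = self.target_size
        if w < 1 or h < 1:
            raise ValidationError("target_size must be positive")
        if self.pet_min != AUTO:
            self.pet_min = float(self.pet_min)
            if not 0 <= self.pet_min < 255:
                raise ValidationError("pet_min must lie in [0, 255)")


def upscale_bilinear(img: GrayImage, target_size: tuple[int, int]) -> GrayImage:
    """Enlarge to ``target_size`` (width, height) by align-corners bilinear
    interpolation: output corner pixels coincide with source corners, and
    values never leave the source range."""
    tw, th = int(target_size[0]), int(target_size[1])
    if tw < img.width or th < img.height:
        raise ValidationError(
            f"target size {tw}x{th} smaller than source {img.width}x{img.height}"
        )
    if (tw, th) == (img.width, img.height):
        return GrayImage(img.pixels.copy(), img.modality, img.source_id)
    ys = np.linspace(0.0, img.height - 1, th) if th > 1 else np.zeros(1)
    xs = np.linspace(0.0, img.width - 1, tw) if tw > 1 else np.zeros(1)
    # separable lerp in the a + f*(b-a) form: exact for constant images
    # and at the corner samples
    y0 = np.minimum(ys.astype(int), img.height - 1)
    x0 = np.minimum(xs.astype(int), img.width - 1)
    y1 = np.minimum(y0 + 1, img.height - 1)
    x1 = np.minimum(x0 + 1, img.width - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    p = img.pixels
    top = p[np.ix_(y0, x0)] + fx * (p[np.ix_(y0, x1)] - p[np.ix_(y0, x0)])
    bot = p[np.ix_(y1, x0)] + fx * (p[np.ix_(y1, x1)] - p[np.ix_(y1, x0)])
    out = top + fy * (bot - top)
    return GrayImage(out, img.modality, img.source_id)


def auto_pet_min(img: GrayImage) -> float:
    """Nearest-rank 1st percentile of the intensity distribution."""
    flat = np.sort(img.pixels, axis=None)
    rank = max(1, math.ceil(0.01 * flat.size))
    return float(flat[rank - 1])


def piecewise_enhance(img: GrayImage, pet_min: float) -> GrayImage:
    """Apply the piecewise gray-level stretch (float output, clipped)."""
    pet_min = float(pet_min)
    if not 0 <= pet_min < 255:
        raise ValidationError("pet_min must lie in [0, 255); 255 divides by zero")
    f = img.pixels
    # ratio form keeps the endpoints exact: G(pet_min) = 0, G(255) = 255
    g = np.where(f < pet_min, 0.0, 255.0 * ((f - pet_min) / (255.0 - pet_min)))
    return GrayImage(np.clip(g, 0.0, 255.0), img.modality, img.source_id)


def enhance_pet(img: GrayImage, cfg: EnhanceConfig | None = None) -> GrayImage:
    """Enlarge then enhance a PET slice; resolves ``pet_min="auto"`` on the
    enlarged image."""
    cfg = cfg or EnhanceConfig()
    big = upscale_bilinear(img, cfg.target_size)
    pet_min = auto_pet_min(big) if cfg.pet_min == AUTO else float(cfg.pet_min)
    return piecewise_enhance(big, pet_min)
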