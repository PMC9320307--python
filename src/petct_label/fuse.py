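"""Wavelet-domain PET/CT fusion.

Both registered images are decomposed with a multilevel 2-D discrete
wavelet transform (sym8 by default — a near-symmetric orthogonal filter
bank with 16 taps, chosen for its low phase distortion), every subband is
blended as a fixed convex combination

    W_fused = (a/100) * W_PET + (b/100) * W_CT,   a + b = 100,

optionally after soft-shrinking the detail coefficients, and the result
is reconstructed and clipped to [0, 255].  A 40:60 PET:CT ratio is the
default blend.  A fixed 256-entry pseudocolor lookup table is provided
for display of the fused slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ValidationError
from .image_io import GrayImage, round_half_up

CoeffPyramid = list  # [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]


@dataclass
class FusionWeights:
    """PET/CT blend percentages; must sum to 100."""

    pet_pct: float = 40.0
    ct_pct: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.pet_pct <= 100 and 0 <= self.ct_pct <= 100):
            raise ValidationError("fusion percentages must lie in [0, 100]")
        if abs(self.pet_pct + self.ct_pct - 100.0) > 1e-9:
            raise ValidationError(
                f"fusion percentages must sum to 100, got "
                f"{self.pet_pct} + {self.ct_pct}"
            )


@dataclass
class WaveletConfig:
    wavelet_name: str = "sym8"
    levels: int = 3
    soft_threshold: float = 0.0
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValidationError("decomposition depth must be >= 1")
        if self.soft_threshold < 0:
            raise ValidationError("soft_threshold must be non-negative")

    def check_feasible(self, width: int, height: int) -> None:
        if 2 ** self.levels > min(width, height):
            raise ValidationError(
                f"{self.levels} levels infeasible for a {width}x{height} image"
            )


def dwt_decompose(img: GrayImage, cfg: WaveletConfig | None = None) -> CoeffPyramid:
    """Multilevel 2-D DWT: one approximation band plus per-level
    horizontal/vertical/diagonal detail bands."""
    cfg = cfg or WaveletConfig()
    cfg.check_feasible(img.width, img.height)
    with warnings.catch_warnings():
        # our feasibility rule (2^levels <= min dim) intentionally allows
        # deeper trees than pywt's conservative boundary-effect advisory
        warnings.filterwarnings("ignore", message="Level value of .*")
        return pywt.wavedec2(img.pixels, cfg.wavelet_name,
                             mode=cfg.extension_mode, level=cfg.levels)


def dwt_reconstruct(coeffs: CoeffPyramid, cfg: WaveletConfig | None = None,
                    out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Inverse of :func:`dwt_decompose`; crops to ``out_shape`` (height,
    width) when the synthesis bank pads odd dimensions."""
    cfg = cfg or WaveletConfig()
    rec = pywt.waverec2(coeffs, cfg.wavelet_name, mode=cfg.extension_mode)
    if out_shape is not None:
        rec = rec[: out_shape[0], : out_shape[1]]
    return rec


def _pyramids_match(p1: CoeffPyramid, p2: CoeffPyramid) -> bool:
    if len(p1) != len(p2) or p1[0].shape != p2[0].shape:
        return False
    for lev1, lev2 in zip(p1[1:], p2[1:]):
        if any(b1.shape != b2.shape for b1, b2 in zip(lev1, lev2)):
            return False
    return True


def combine_coeffs(pet_coeffs: CoeffPyramid, ct_coeffs: CoeffPyramid,
                   w: FusionWeights,
                   cfg: WaveletConfig | None = None) -> CoeffPyramid:
    """Blend two coefficient pyramids band by band.

    Every band (approximation and details alike) is the convex combination
    at the configured percentages; when ``cfg.soft_threshold`` > 0 the
    detail bands are first shrunk toward zero by that amount.
    """
    cfg = cfg or WaveletConfig()
    if not _pyramids_match(pet_coeffs, ct_coeffs):
        raise ValidationError("coefficient pyramids have mismatched shapes")
    wa, wb = w.pet_pct / 100.0, w.ct_pct / 100.0
    t = cfg.soft_threshold

    def detail(band_p, band_c):
        if t > 0:
            band_p = pywt.threshold(band_p, t, mode="soft")
            band_c = pywt.threshold(band_c, t, mode="soft")
        return wa * band_p + wb * band_c

    fused: CoeffPyramid = [wa * pet_coeffs[0] + wb * ct_coeffs[0]]
    for lev_p, lev_c in zip(pet_coeffs[1:], ct_coeffs[1:]):
        fused.append(tuple(detail(bp, bc) for bp, bc in zip(lev_p, lev_c)))
    return fused


def fuse_images(pet: GrayImage, ct: GrayImage, w: FusionWeights | None = None,
                cfg: WaveletConfig | None = None) -> GrayImage:
    """Decompose both registered images, blend, reconstruct, clip."""
    w = w or FusionWeights()
    cfg = cfg or WaveletConfig()
    if pet.size != ct.size:
        raise ValidationError(
            f"cannot fuse {pet.width}x{pet.height} with {ct.width}x{ct.height}"
        )
    fused = combine_coeffs(dwt_decompose(pet, cfg), dwt_decompose(ct, cfg),
                           w, cfg)
    rec = dwt_reconstruct(fused, cfg, out_shape=pet.pixels.shape)
    return GrayImage(np.clip(rec, 0.0, 255.0), "FUSED",
                     f"{pet.source_id}+{ct.source_id}")


# ---------------------------------------------------------------------------
# pseudocolor
# ---------------------------------------------------------------------------

_ANCHOR_POS = np.array([0, 42, 85, 128, 170, 212, 255], dtype=float)
_ANCHOR_RGB = np.array(
    [
        (0, 0, 0),        # black
        (0, 0, 255),      # blue
        (0, 255, 255),    # cyan
        (0, 255, 0),      # green
        (255, 255, 0),    # yellow
        (255, 0, 0),      # red
        (255, 255, 255),  # white
    ],
    dtype=float,
)


def pseudocolor_lut() -> np.ndarray:
    """The fixed 256-entry RGB table: a piecewise-linear ramp
    black->blue->cyan->green->yellow->red->white."""
    levels = np.arange(256, dtype=float)
    lut = np.stack(
        [np.interp(levels, _ANCHOR_POS, _ANCHOR_RGB[:, ch]) for ch in range(3)],
        axis=1,
    )
    return round_half_up(lut).astype(np.uint8)


_LUT = pseudocolor_lut()


def pseudocolor(img: GrayImage) -> np.ndarray:
    """Map rounded 8-bit gray levels through the fixed LUT; deterministic,
    equal grays map to identical RGB triples.  Returns (H, W, 3) uint8."""
    return _LUT[img.to_uint8()]
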