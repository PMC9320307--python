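"""Landmark affine registration of PET to CT.

A six-parameter affine transform

    x' = a*x + b*y + h
    y' = c*x + d*y + k

is fitted to paired control points by minimizing the sum of squared
translation residuals

    C(a,b,c,d,h,k) = sum_i (a*x_i + b*y_i + h - x'_i)^2
                   + sum_i (c*x_i + d*y_i + k - y'_i)^2.

The solution is closed form: with centroid-centered second-moment sums
S_xx, S_xy, S_yy and cross sums against the target coordinates, each row
of the transform is an independent bivariate least-squares fit; the
translation follows from the centroids (h = x̄' - a·x̄ - b·ȳ).  Because
x and y rows decouple, this is identical to solving the 2n x 6 normal
equations.

An axis-aligned pre-alignment from the image outer frames (field-of-view
bounding boxes) is available to remove the gross scale/shift before the
landmark fit refines it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError
from .image_io import ControlPointSet, GrayImage, round_half_up

_DEGENERACY_RTOL = 1e-12


@dataclass
class AffineParams:
    """Six affine coefficients: linear part (a, b; c, d), translation (h, k)."""

    a: float
    b: float
    c: float
    d: float
    h: float
    k: float

    def __post_init__(self) -> None:
        for name in "abcdhk":
            setattr(self, name, float(getattr(self, name)))

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.h, self.k], dtype=float)

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.h, self.k)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points (x, y) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def invert(self) -> "AffineParams":
        if abs(self.det) < _DEGENERACY_RTOL:
            raise DegenerateGeometryError("affine linear part is singular")
        minv = np.linalg.inv(self.matrix)
        t = -minv @ self.translation
        return AffineParams(minv[0, 0], minv[0, 1], minv[1, 0], minv[1, 1],
                            t[0], t[1])


def compose(outer: AffineParams, inner: AffineParams) -> AffineParams:
    """The transform applying ``inner`` first, then ``outer``."""
    m = outer.matrix @ inner.matrix
    t = outer.matrix @ inner.translation + outer.translation
    return AffineParams(m[0, 0], m[0, 1], m[1, 0], m[1, 1], t[0], t[1])


@dataclass
class ResidualReport:
    """Per-landmark residuals of a fitted transform, their sum of squares
    and the root-mean-square over all 2n residual components."""

    per_point_residuals: np.ndarray  # (n, 2): (rx, ry) in pixels
    ssr: float
    rms: float


def fit_affine_ls(points: ControlPointSet) -> AffineParams:
    """Closed-form least-squares fit of the six affine parameters.

    Requires >= 3 non-collinear source points (enforced by
    :class:`ControlPointSet`); raises :class:`DegenerateGeometryError`
    if the second-moment matrix is numerically singular anyway.
    """
    x, y = points.source[:, 0], points.source[:, 1]
    xp, yp = points.target[:, 0], points.target[:, 1]
    xb, yb, xpb, ypb = x.mean(), y.mean(), xp.mean(), yp.mean()
    cx, cy = x - xb, y - yb

    s_xx = float(cx @ cx)
    s_yy = float(cy @ cy)
    s_xy = float(cx @ cy)
    det = s_xx * s_yy - s_xy * s_xy
    if abs(det) <= _DEGENERACY_RTOL * max(1.0, (s_xx + s_yy) ** 2):
        raise DegenerateGeometryError(
            "control points are collinear; affine fit is not unique"
        )

    s_xxp = float(cx @ (xp - xpb))
    s_yxp = float(cy @ (xp - xpb))
    s_xyp = float(cx @ (yp - ypb))
    s_yyp = float(cy @ (yp - ypb))

    a = (s_xxp * s_yy - s_yxp * s_xy) / det
    b = (s_yxp * s_xx - s_xxp * s_xy) / det
    c = (s_xyp * s_yy - s_yyp * s_xy) / det
    d = (s_yyp * s_xx - s_xyp * s_xy) / det
    h = xpb - a * xb - b * yb
    k = ypb - c * xb - d * yb
    return AffineParams(a, b, c, d, h, k)


def compute_residuals(points: ControlPointSet,
                      params: AffineParams) -> ResidualReport:
    """Translation residuals r = T(source) - target at each landmark."""
    res = params.apply(points.source) - points.target
    ssr = float(np.sum(res * res))
    n = len(points)
    return ResidualReport(per_point_residuals=res, ssr=ssr,
                          rms=float(np.sqrt(ssr / (2 * n))))


def _foreground_bbox(img: GrayImage) -> tuple[float, float, float, float]:
    """Bounding box (x_min, y_min, x_max, y_max) of pixels differing from
    the modal border value (parameter-free field-of-view detection)."""
    px = round_half_up(img.pixels).astype(np.int64)
    border = np.concatenate([px[0, :], px[-1, :], px[1:-1, 0], px[1:-1, -1]]) \
        if px.shape[0] > 1 and px.shape[1] > 1 else px.ravel()
    modal = np.bincount(border - border.min()).argmax() + border.min()
    fg_y, fg_x = np.nonzero(px != modal)
    if fg_x.size == 0:
        raise DegenerateGeometryError("image has no foreground (constant frame)")
    return (float(fg_x.min()), float(fg_y.min()),
            float(fg_x.max()), float(fg_y.max()))


def frame_prealign(pet: GrayImage, ct: GrayImage) -> AffineParams:
    """Axis-aligned scale-and-shift mapping the PET foreground bounding box
    onto the CT foreground bounding box (b = c = 0)."""
    px0, py0, px1, py1 = _foreground_bbox(pet)
    cx0, cy0, cx1, cy1 = _foreground_bbox(ct)
    if px1 == px0 or py1 == py0:
        raise DegenerateGeometryError("PET foreground box has zero extent")
    a = (cx1 - cx0) / (px1 - px0)
    d = (cy1 - cy0) / (py1 - py0)
    return AffineParams(a, 0.0, 0.0, d, cx0 - a * px0, cy0 - d * py0)


def register_landmarks(pet: GrayImage, ct: GrayImage,
                       points: ControlPointSet,
                       prealign: bool = True) -> AffineParams:
    """Full PET->CT transform: optional frame pre-alignment composed with
    the landmark least-squares refinement expressed in pre-aligned
    coordinates."""
    if prealign:
        pre = frame_prealign(pet, ct)
        moved = ControlPointSet(pre.apply(points.source), points.target)
        return compose(fit_affine_ls(moved), pre)
    return fit_affine_ls(points)


def apply_affine(img: GrayImage, params: AffineParams,
                 out_size: tuple[int, int]) -> GrayImage:
    """Resample ``img`` into the target grid by pull-based warping: each
    output pixel samples the input at the inverse-mapped location with
    bilinear interpolation, 0-filled outside the input."""
    inv = params.invert()  # raises on singular linear part
    ow, oh = int(out_size[0]), int(out_size[1])
    gx, gy = np.meshgrid(np.arange(ow, dtype=float),
                         np.arange(oh, dtype=float), indexing="xy")
    sx = inv.a * gx + inv.b * gy + inv.h
    sy = inv.c * gx + inv.d * gy + inv.k
    out = ndimage.map_coordinates(img.pixels, [sy, sx], order=1,
                                  mode="constant", cval=0.0)
    return GrayImage(out, img.modality, img.source_id)
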