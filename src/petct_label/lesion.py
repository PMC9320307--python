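"""Click-seeded lesion segmentation, labeling geometry and SUV handling.

A professional clicks once inside a suspected lesion on the fused image.
Strong FDG uptake appears as LOW gray values on the PET, so the seed is
refined to the darkest pixel in a window around the click; an
8-neighborhood region grows from that seed, accepting pixels strictly
darker than twice the seed value (ValueMin + 100% of ValueMin) and no
farther than a Chebyshev radius cap from the seed.  The grown region is
traced into a boundary polygon (Moore-neighbor tracing) and boxed by its
tight bounding rectangle, which becomes the deep-learning label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import BoundsError, ValidationError
from .image_io import GrayImage, round_half_up
from .register import AffineParams

Pixel = tuple[int, int]  # (x, y)


@dataclass
class GrowConfig:
    """Seed-refinement window halfwidth, threshold increase fraction
    (1.0 = +100%, i.e. accept gray < 2*ValueMin) and Chebyshev radius cap."""

    search_halfwidth: int = 8
    threshold_increase: float = 1.0
    max_radius: int = 10

    def __post_init__(self) -> None:
        if self.search_halfwidth <= 0 or self.threshold_increase <= 0 \
                or self.max_radius <= 0:
            raise ValidationError("all growth parameters must be positive")


@dataclass
class LesionRegion:
    seed: Pixel
    value_min: float
    members: frozenset = field(default_factory=frozenset)
    boundary: list = field(default_factory=list)
    bbox: tuple = (0, 0, 0, 0)


def refine_seed(pet: GrayImage, click: Pixel,
                cfg: GrowConfig | None = None) -> tuple[Pixel, float]:
    """Darkest pixel in the window ``click +- search_halfwidth`` (clipped
    to the image); ties broken by first occurrence in row-major order."""
    cfg = cfg or GrowConfig()
    x0, y0 = int(click[0]), int(click[1])
    if not (0 <= x0 < pet.width and 0 <= y0 < pet.height):
        raise BoundsError(f"click ({x0}, {y0}) outside "
                          f"{pet.width}x{pet.height} image")
    s = cfg.search_halfwidth
    x1, x2 = max(0, x0 - s), min(pet.width - 1, x0 + s)
    y1, y2 = max(0, y0 - s), min(pet.height - 1, y0 + s)
    window = pet.pixels[y1:y2 + 1, x1:x2 + 1]
    flat_idx = int(np.argmin(window))  # first occurrence, row-major
    dy, dx = divmod(flat_idx, window.shape[1])
    return (x1 + dx, y1 + dy), float(window[dy, dx])


_NEIGHBORS_8 = ((-1, -1), (0, -1), (1, -1), (-1, 0),
                (1, 0), (-1, 1), (0, 1), (1, 1))


def region_grow(pet: GrayImage, seed: Pixel, value_min: float,
                cfg: GrowConfig | None = None) -> LesionRegion:
    """Stack-based 8-neighborhood growth from the refined seed.

    A pixel joins iff its gray value is strictly below
    ``value_min * (1 + threshold_increase)`` and its Chebyshev distance
    from the seed is at most ``max_radius``.  The seed itself is always a
    member, so a seed of value 0 degenerates to a single-pixel region.
    """
    cfg = cfg or GrowConfig()
    sx, sy = int(seed[0]), int(seed[1])
    if not (0 <= sx < pet.width and 0 <= sy < pet.height):
        raise BoundsError(f"seed ({sx}, {sy}) outside image")
    if abs(pet.pixels[sy, sx] - value_min) > 1e-9:
        raise ValidationError(
            f"value_min {value_min} does not match seed intensity "
            f"{pet.pixels[sy, sx]}"
        )
    threshold = value_min * (1.0 + cfg.threshold_increase)
    r = cfg.max_radius
    px = pet.pixels
    members = {(sx, sy)}
    stack = [(sx, sy)]
    while stack:
        x, y = stack.pop()
        for dx, dy in _NEIGHBORS_8:
            nx, ny = x + dx, y + dy
            if (nx, ny) in members:
                continue
            if not (0 <= nx < pet.width and 0 <= ny < pet.height):
                continue
            if max(abs(nx - sx), abs(ny - sy)) > r:
                continue
            if px[ny, nx] < threshold:  # strict, as specified
                members.add((nx, ny))
                stack.append((nx, ny))
    fmembers = frozenset(members)
    return LesionRegion(seed=(sx, sy), value_min=float(value_min),
                        members=fmembers,
                        boundary=_trace_members(fmembers),
                        bbox=_bbox_of(fmembers))


# ---------------------------------------------------------------------------
# boundary and rectangle
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order (y axis points down) starting west.
_CLOCKWISE = ((-1, 0), (-1, -1), (0, -1), (1, -1),
              (1, 0), (1, 1), (0, 1), (-1, 1))
_DIR_INDEX = {d: i for i, d in enumerate(_CLOCKWISE)}


def _trace_members(members: frozenset) -> list[Pixel]:
    """Moore-neighbor trace of the outer contour, clockwise, starting at
    the topmost-then-leftmost member pixel."""
    start = min(members, key=lambda p: (p[1], p[0]))
    path = [start]
    cur, back = start, 0  # backtrack direction: west of the start pixel
    initial_state = (start, 0)
    for _ in range(8 * len(members) + 8):
        nxt = None
        for step in range(1, 9):
            d = (back + step) % 8
            nb = (cur[0] + _CLOCKWISE[d][0], cur[1] + _CLOCKWISE[d][1])
            if nb in members:
                nxt = (nb, d)
                break
        if nxt is None:
            break  # isolated pixel
        nb, d = nxt
        prev_d = (d - 1) % 8
        prev_pix = (cur[0] + _CLOCKWISE[prev_d][0],
                    cur[1] + _CLOCKWISE[prev_d][1])
        ddx, ddy = _CLOCKWISE[d]
        if ddx and ddy:
            # diagonal step: visit the member "elbow" pixel so the path is
            # 4-connected and covers members exposed only at a corner
            for elbow in ((cur[0] + ddx, cur[1]), (cur[0], cur[1] + ddy)):
                if elbow != prev_pix and elbow in members:
                    path.append(elbow)
        back = _DIR_INDEX[(prev_pix[0] - nb[0], prev_pix[1] - nb[1])]
        cur = nb
        if (cur, back) == initial_state:
            break
        path.append(cur)
    return path


def trace_boundary(region: LesionRegion) -> list[Pixel]:
    """Ordered boundary polygon of the member set (outer Moore contour);
    every vertex is a member 8-adjacent to a non-member or the border."""
    if not region.members:
        raise ValidationError("cannot trace an empty region")
    return _trace_members(region.members)


def _bbox_of(members: Iterable[Pixel]) -> tuple[int, int, int, int]:
    xs = [p[0] for p in members]
    ys = [p[1] for p in members]
    return (min(xs), min(ys), max(xs), max(ys))


def bounding_rect(region: LesionRegion) -> tuple[int, int, int, int]:
    """Tight (x_min, y_min, x_max, y_max) over the member pixels; the
    rectangle with those extrema as vertices contains every member."""
    if not region.members:
        raise ValidationError("cannot box an empty region")
    return _bbox_of(region.members)


def map_region_to_ct(region: LesionRegion,
                     pet_to_ct: AffineParams) -> LesionRegion:
    """Carry a region into CT coordinates.

    After in-pipeline resampling the transform is the identity and
    coordinates transfer unchanged; otherwise each member is mapped and
    rounded half up, and boundary/bbox are recomputed.  (Under strongly
    expanding transforms the mapped set can fragment; the traced boundary
    then follows the component containing the topmost-leftmost pixel.)
    """
    if not region.members:
        raise ValidationError("cannot map an empty region")
    pet_to_ct.invert()  # raises DegenerateGeometryError if singular
    if pet_to_ct.as_tuple() == (1.0, 0.0, 0.0, 1.0, 0.0, 0.0):
        return LesionRegion(region.seed, region.value_min, region.members,
                            list(region.boundary), region.bbox)
    pts = np.array(sorted(region.members), dtype=float)
    mapped = round_half_up(pet_to_ct.apply(pts)).astype(int)
    members = frozenset((int(x), int(y)) for x, y in mapped)
    seed = tuple(round_half_up(
        pet_to_ct.apply(np.array([region.seed], dtype=float))
    ).astype(int)[0])
    return LesionRegion(seed=(int(seed[0]), int(seed[1])),
                        value_min=region.value_min, members=members,
                        boundary=_trace_members(members),
                        bbox=_bbox_of(members))


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

@dataclass
class SuvReading:
    """Tracer reading for a lesion: radioactivity concentration (kBq/mL),
    injected dose (MBq) and body weight (kg)."""

    concentration: float
    dose: float
    weight: float

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.weight <= 0:
            raise ValidationError("dose and weight must be positive")
        if self.concentration < 0:
            raise ValidationError("concentration must be non-negative")

    @property
    def suv(self) -> float:
        # concentration normalized by dose per kilogram of body weight
        return self.concentration / (self.dose / self.weight)


def compute_suv(reading: SuvReading) -> float:
    return reading.suv


def classify_suv(suv: float) -> str:
    """SUV > 2.5 -> malignant; 2.0 <= SUV <= 2.5 -> critical range;
    SUV < 2.0 -> benign."""
    if suv < 0:
        raise ValidationError("SUV must be non-negative")
    if suv > 2.5:
        return "malignant"
    if suv >= 2.0:
        return "critical"
    return "benign"


# ---------------------------------------------------------------------------
# agreement with manual labeling
# ---------------------------------------------------------------------------

def _as_pixel_set(mask) -> set:
    if isinstance(mask, np.ndarray):
        ys, xs = np.nonzero(mask)
        return {(int(x), int(y)) for x, y in zip(xs, ys)}
    return {(int(x), int(y)) for x, y in mask}


def agreement_metrics(system_mask, manual_mask) -> tuple[float, float]:
    """Pixel-overlap agreement against a manual reference.

    recognition_rate   = |system AND manual| / |manual| * 100
    false_positive_rate = |system \\ manual| / |manual| * 100

    Masks may be boolean arrays (nonzero = member) or iterables of (x, y).
    """
    system = _as_pixel_set(system_mask)
    manual = _as_pixel_set(manual_mask)
    if not manual:
        raise ValidationError("manual mask must be nonempty")
    n = len(manual)
    return (100.0 * len(system & manual) / n,
            100.0 * len(system - manual) / n)
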