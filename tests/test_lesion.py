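import numpy as np
import pytest
from scipy import ndimage

from petct_label import (AffineParams, BoundsError, GrayImage, GrowConfig,
                         LesionRegion, SuvReading, ValidationError,
                         agreement_metrics, bounding_rect, classify_suv,
                         compute_suv, map_region_to_ct, refine_seed,
                         region_grow, trace_boundary)


def _img(pixels):
    return GrayImage(np.asarray(pixels, dtype=float), "PET")


def _disk_image(n=64, center=(32, 32), radius=5, inside=10.0, outside=200.0):
    ys, xs = np.mgrid[0:n, 0:n]
    px = np.full((n, n), outside)
    mask = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2
    px[mask] = inside
    return GrayImage(px, "PET"), mask


# ---------------------------------------------------------------------------
# seed refinement
# ---------------------------------------------------------------------------

def test_refine_seed_flat_window_row_major_tiebreak():
    img = _img(np.full((64, 64), 77.0))
    seed, vmin = refine_seed(img, (20, 20))
    assert seed == (12, 12)
    assert vmin == 77.0


def test_refine_seed_finds_unique_minimum():
    px = np.full((64, 64), 100.0)
    px[18, 25] = 3.0  # (x=25, y=18)
    seed, vmin = refine_seed(_img(px), (20, 20))
    assert seed == (25, 18)
    assert vmin == 3.0


def test_refine_seed_window_clipped_at_origin():
    img = _img(np.full((64, 64), 9.0))
    seed, vmin = refine_seed(img, (0, 0))
    assert seed == (0, 0)
    assert vmin == 9.0


def test_refine_seed_click_outside_raises():
    with pytest.raises(BoundsError):
        refine_seed(_img(np.zeros((16, 16))), (16, 3))


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def test_uniform_image_growth_capped_at_radius():
    img = _img(np.full((64, 64), 40.0))
    region = region_grow(img, (30, 30), 40.0)
    assert len(region.members) == 441  # (2*10+1)^2
    assert region.bbox == (20, 20, 40, 40)


def test_growth_criterion_is_strict():
    px = np.full((32, 32), 200.0)
    px[10, 10] = 50.0
    px[10, 11] = 99.0   # < 100: joins
    px[11, 10] = 100.0  # not < 100: excluded
    region = region_grow(_img(px), (10, 10), 50.0)
    assert (11, 10) in region.members
    assert (10, 11) not in region.members
    assert region.members == {(10, 10), (11, 10)}


def test_dark_disk_grows_to_exactly_the_disk():
    img, mask = _disk_image()
    region = region_grow(img, (32, 32), 10.0)
    expected = {(int(x), int(y)) for y, x in zip(*np.nonzero(mask))}
    assert region.members == expected


def test_zero_seed_degenerates_to_single_pixel():
    px = np.full((32, 32), 10.0)
    px[5, 5] = 0.0
    region = region_grow(_img(px), (5, 5), 0.0)
    assert region.members == {(5, 5)}


def test_value_min_mismatch_rejected():
    with pytest.raises(ValidationError):
        region_grow(_img(np.full((16, 16), 30.0)), (5, 5), 10.0)


def _flood_fill_oracle(pixels, seed, threshold, max_radius):
    """Connected-component flood fill under the same predicate, via an
    independent route (scipy labeling of the predicate mask)."""
    h, w = pixels.shape
    sx, sy = seed
    ys, xs = np.mgrid[0:h, 0:w]
    cheb = np.maximum(np.abs(xs - sx), np.abs(ys - sy))
    mask = (pixels < threshold) & (cheb <= max_radius)
    mask[sy, sx] = True  # the seed is a member by definition
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    comp = labels == labels[sy, sx]
    return {(int(x), int(y)) for y, x in zip(*np.nonzero(comp))}


def test_region_grow_matches_flood_fill_oracle(rng):
    for _ in range(20):
        px = rng.integers(0, 256, (64, 64)).astype(float)
        x, y = int(rng.integers(0, 64)), int(rng.integers(0, 64))
        vmin = float(px[y, x])
        region = region_grow(GrayImage(px, "PET"), (x, y), vmin)
        assert region.members == _flood_fill_oracle(px, (x, y), 2 * vmin, 10)


def test_members_satisfy_criterion_and_nonmembers_violate(rng):
    px = rng.integers(0, 256, (48, 48)).astype(float)
    x, y = 24, 24
    vmin = float(px[y, x])
    cfg = GrowConfig()
    region = region_grow(GrayImage(px, "PET"), (x, y), vmin, cfg)
    t = 2 * vmin
    for (mx, my) in region.members:
        assert (mx, my) == (x, y) or px[my, mx] < t
        assert max(abs(mx - x), abs(my - y)) <= cfg.max_radius
    for (mx, my) in region.members:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                nx, ny = mx + dx, my + dy
                if (nx, ny) in region.members:
                    continue
                if not (0 <= nx < 48 and 0 <= ny < 48):
                    continue
                assert (px[ny, nx] >= t
                        or max(abs(nx - x), abs(ny - y)) > cfg.max_radius)


# ---------------------------------------------------------------------------
# boundary tracing and rectangle
# ---------------------------------------------------------------------------

def _region_from(members, seed=None):
    members = frozenset(members)
    seed = seed or next(iter(members))
    return LesionRegion(seed=seed, value_min=0.0, members=members)


def test_trace_single_pixel():
    assert trace_boundary(_region_from({(5, 5)})) == [(5, 5)]


def test_trace_3x3_square_clockwise():
    square = {(x, y) for x in range(3) for y in range(3)}
    trace = trace_boundary(_region_from(square, seed=(1, 1)))
    assert trace == [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2),
                     (1, 2), (0, 2), (0, 1)]


def test_trace_covers_all_boundary_pixels_of_simply_connected_regions():
    img, mask = _disk_image(radius=8, inside=10.0)
    region = region_grow(img, (32, 32), 10.0, GrowConfig(max_radius=20))
    traced = set(trace_boundary(region))
    oracle = set()
    for (x, y) in region.members:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if (dx or dy) and (x + dx, y + dy) not in region.members:
                    oracle.add((x, y))
    assert traced == oracle


def test_trace_empty_region_rejected():
    with pytest.raises(ValidationError):
        trace_boundary(LesionRegion(seed=(0, 0), value_min=0.0,
                                    members=frozenset()))


@pytest.mark.parametrize(
    "members,expected",
    [
        ({(3, 4), (9, 12), (5, 5)}, (3, 4, 9, 12)),
        ({(7, 7)}, (7, 7, 7, 7)),
    ],
)
def test_bounding_rect_min_max(members, expected):
    assert bounding_rect(_region_from(members)) == expected


def test_bounding_rect_full_image():
    w, h = 12, 9
    members = {(x, y) for x in range(w) for y in range(h)}
    assert bounding_rect(_region_from(members)) == (0, 0, w - 1, h - 1)


def test_bounding_rect_is_tight(rng):
    px = rng.integers(0, 256, (48, 48)).astype(float)
    region = region_grow(GrayImage(px, "PET"), (20, 20), float(px[20, 20]))
    x0, y0, x1, y1 = bounding_rect(region)
    xs = [p[0] for p in region.members]
    ys = [p[1] for p in region.members]
    assert x0 in xs and x1 in xs and y0 in ys and y1 in ys


# ---------------------------------------------------------------------------
# mapping to CT
# ---------------------------------------------------------------------------

def test_map_identity_preserves_region():
    img, _ = _disk_image()
    region = region_grow(img, (32, 32), 10.0)
    mapped = map_region_to_ct(region, AffineParams.identity())
    assert mapped.members == region.members
    assert mapped.boundary == region.boundary
    assert mapped.bbox == region.bbox


def test_map_translation_shifts_coordinates():
    img, _ = _disk_image()
    region = region_grow(img, (32, 32), 10.0)
    mapped = map_region_to_ct(region, AffineParams(1, 0, 0, 1, 10, 0))
    assert mapped.members == {(x + 10, y) for x, y in region.members}
    assert mapped.seed == (region.seed[0] + 10, region.seed[1])


def test_mapped_bbox_recomputed_from_members():
    img, _ = _disk_image()
    region = region_grow(img, (32, 32), 10.0)
    mapped = map_region_to_ct(region, AffineParams(1.1, 0, 0, 0.9, 5, -3))
    assert mapped.bbox == (min(x for x, _ in mapped.members),
                           min(y for _, y in mapped.members),
                           max(x for x, _ in mapped.members),
                           max(y for _, y in mapped.members))


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

def test_suv_hand_example():
    assert compute_suv(SuvReading(5.0, 370.0, 74.0)) == pytest.approx(1.0)


def test_suv_zero_concentration():
    assert compute_suv(SuvReading(0.0, 370.0, 74.0)) == 0.0


def test_suv_proportional_to_weight():
    one = compute_suv(SuvReading(5.0, 370.0, 74.0))
    two = compute_suv(SuvReading(5.0, 370.0, 148.0))
    assert two == pytest.approx(2 * one)


def test_suv_nonpositive_dose_or_weight_rejected():
    with pytest.raises(ValidationError):
        SuvReading(5.0, 0.0, 74.0)
    with pytest.raises(ValidationError):
        SuvReading(5.0, 370.0, -1.0)


@pytest.mark.parametrize("suv,expected", [
    (3.0, "malignant"),
    (2.2, "critical"),
    (1.9, "benign"),
    (2.5, "critical"),
    (2.0, "critical"),
    (0.0, "benign"),
])
def test_classify_suv(suv, expected):
    assert classify_suv(suv) == expected


def test_classify_negative_suv_rejected():
    with pytest.raises(ValidationError):
        classify_suv(-0.1)


def test_classify_is_a_partition():
    for suv in np.linspace(0, 5, 501):
        assert classify_suv(float(suv)) in {"malignant", "critical", "benign"}


# ---------------------------------------------------------------------------
# agreement metrics
# ---------------------------------------------------------------------------

def test_agreement_perfect_match():
    manual = {(x, y) for x in range(10) for y in range(10)}
    assert agreement_metrics(manual, manual) == (100.0, 0.0)


def test_agreement_half_coverage():
    manual = {(x, 0) for x in range(10)}
    system = {(x, 0) for x in range(5)}
    assert agreement_metrics(system, manual) == (50.0, 0.0)


def test_agreement_with_extra_pixels():
    manual = {(x, y) for x in range(10) for y in range(10)}
    system = manual | {(100 + i, 0) for i in range(10)}
    assert agreement_metrics(system, manual) == (100.0, 10.0)


def test_agreement_accepts_boolean_masks():
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:4, 2:4] = True
    assert agreement_metrics(mask, mask) == (100.0, 0.0)


def test_agreement_empty_manual_rejected():
    with pytest.raises(ValidationError):
        agreement_metrics({(0, 0)}, set())
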