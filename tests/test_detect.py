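"""Detection pipeline: thresholding, labelling, hole filling, size filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyspot.detect import (
    Component,
    DetectionParams,
    RgbImage,
    adaptive_threshold,
    detect_spots,
    fill_holes,
    filter_by_size,
    label_components,
    to_greyscale,
)
from flyspot.synth import score_detection

from conftest import grey_image


# ---------------------------------------------------------------- oracles

def brute_force_threshold(grey, window, offset):
    """Literal per-pixel sliding-window mean rule with reflected padding."""
    pad = window // 2
    padded = np.pad(grey, pad, mode="symmetric")
    out = np.zeros_like(grey, dtype=np.uint8)
    h, w = grey.shape
    for y in range(h):
        for x in range(w):
            local = padded[y : y + window, x : x + window].mean()
            out[y, x] = 1 if grey[y, x] < local - offset else 0
    return out


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def union_find_labels(mask):
    """Independent 8-connected labelling by union-find over pixel pairs."""
    h, w = mask.shape
    uf = UnionFind(h * w)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                    uf.union(y * w + x, ny * w + nx)
    groups = {}
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                groups.setdefault(uf.find(y * w + x), set()).add((x, y))
    return sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda g: min(y * w + x for x, y in g),
    )


def border_flood_background(mask):
    """Background pixels reachable from the border (4-connected flood fill)."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]
    ]
    for p in stack:
        reach[p] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not reach[ny, nx]:
                reach[ny, nx] = True
                stack.append((ny, nx))
    return reach


def component_from_mask(mask):
    ys, xs = np.nonzero(mask)
    return Component(label=1, pixel_set=np.column_stack([xs, ys]))


# ------------------------------------------------------------- greyscale

def test_greyscale_weighted_sum():
    img = RgbImage(np.array([[[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]]))
    grey = to_greyscale(img, (0.299, 0.587, 0.114))
    assert grey[0, 0] == pytest.approx(1.0)
    assert grey[0, 1] == pytest.approx(0.0)
    assert grey[0, 2] == pytest.approx(0.299)


def test_greyscale_rejects_bad_weights():
    img = RgbImage(np.zeros((2, 2, 3)))
    with pytest.raises(ValueError):
        to_greyscale(img, (0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        to_greyscale(img, (1.5, -0.5, 0.0))


# ---------------------------------------------------------- thresholding

def test_uniform_image_yields_empty_map():
    grey = np.full((40, 40), 0.7)
    assert adaptive_threshold(grey, 9, 0.05).sum() == 0


def test_offset_above_range_yields_empty_map():
    rng = np.random.default_rng(0)
    grey = rng.uniform(size=(30, 30))
    assert adaptive_threshold(grey, 9, 1.0).sum() == 0


def test_threshold_matches_brute_force_on_disc():
    yy, xx = np.mgrid[0:64, 0:64]
    grey = np.full((64, 64), 0.9)
    grey[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25] = 0.2
    got = adaptive_threshold(grey, 31, 0.1)
    expected = brute_force_threshold(grey, 31, 0.1)
    np.testing.assert_array_equal(got, expected)
    assert got.sum() > 0  # the dark disc is detected


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from([3, 5, 9, 15]))
def test_threshold_matches_brute_force_on_random_images(seed, window):
    rng = np.random.default_rng(seed)
    grey = rng.uniform(size=(17, 23))
    np.testing.assert_array_equal(
        adaptive_threshold(grey, window, 0.05),
        brute_force_threshold(grey, window, 0.05),
    )


def test_threshold_offset_invariance():
    rng = np.random.default_rng(3)
    grey = np.round(rng.uniform(0.1, 0.7, size=(48, 48)), 2)
    base = adaptive_threshold(grey, 15, 0.0734)  # offset avoids exact ties
    shifted = adaptive_threshold(grey + 0.2, 15, 0.0734)
    np.testing.assert_array_equal(base, shifted)


def test_threshold_parameter_validation():
    grey = np.zeros((10, 10))
    with pytest.raises(ValueError):
        adaptive_threshold(grey, 4, 0.05)  # even window
    with pytest.raises(ValueError):
        adaptive_threshold(grey, 21, 0.05)  # larger than both dimensions


# ------------------------------------------------------------- labelling

def test_two_separated_discs_two_components():
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[5:10, 5:10] = 1
    mask[20:26, 20:26] = 1
    comps = label_components(mask)
    assert [c.label for c in comps] == [1, 2]
    assert {c.area for c in comps} == {25, 36}


def test_single_pixel_component():
    mask = np.zeros((5, 5), dtype=np.uint8)
    mask[2, 3] = 1
    comps = label_components(mask)
    assert len(comps) == 1 and comps[0].area == 1
    assert tuple(comps[0].pixel_set[0]) == (3, 2)


def test_diagonal_touch_is_one_component():
    mask = np.zeros((4, 4), dtype=np.uint8)
    mask[1, 1] = mask[2, 2] = 1
    assert len(label_components(mask)) == 1


def test_empty_map_empty_list():
    assert label_components(np.zeros((8, 8), dtype=np.uint8)) == []


def test_labels_follow_raster_order_of_first_pixel():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[0, 8] = 1       # first raster pixel overall
    mask[3:6, 1:3] = 1   # starts later in raster order
    comps = label_components(mask)
    assert comps[0].pixel_set.tolist() == [[8, 0]]
    assert comps[1].area == 6


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.2, 0.7))
def test_labelling_matches_union_find(seed, density):
    rng = np.random.default_rng(seed)
    mask = (rng.uniform(size=(14, 17)) < density).astype(np.uint8)
    comps = label_components(mask)
    got = [frozenset(map(tuple, c.pixel_set)) for c in comps]
    assert got == union_find_labels(mask.astype(bool))
    # partition: component areas sum to the foreground count
    assert sum(c.area for c in comps) == int(mask.sum())


# ---------------------------------------------------------- hole filling

def test_annulus_fills_to_disc():
    yy, xx = np.mgrid[0:31, 0:31]
    d2 = (xx - 15) ** 2 + (yy - 15) ** 2
    ring = (d2 <= 144) & (d2 >= 49)
    filled = fill_holes(component_from_mask(ring))
    disc = d2 <= 144
    assert filled.area == int(disc.sum())


def test_solid_disc_unchanged_and_idempotent():
    yy, xx = np.mgrid[0:21, 0:21]
    disc = (xx - 10) ** 2 + (yy - 10) ** 2 <= 64
    comp = component_from_mask(disc)
    once = fill_holes(comp)
    assert once.area == comp.area
    assert fill_holes(once).area == once.area


def test_open_cavity_not_filled():
    # C-shape: the cavity opens to the border, so border flood reaches it
    mask = np.zeros((12, 12), dtype=bool)
    mask[2:10, 2:10] = True
    mask[4:8, 4:12] = False  # cavity open to the right edge
    comp = component_from_mask(mask)
    filled = fill_holes(comp)
    reach = border_flood_background(mask)
    holes = ~mask & ~reach
    assert filled.area == comp.area + int(holes.sum())
    assert holes.sum() == 0  # flood-fill oracle agrees nothing is enclosed


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fill_holes_matches_border_flood_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(12, 12)) < 0.55
    for comp in label_components(mask.astype(np.uint8)):
        local, (x0, y0) = comp.local_mask(pad=1)
        reach = border_flood_background(local)
        expected = comp.area + int((~local & ~reach).sum())
        filled = fill_holes(comp)
        assert filled.area == expected
        # never removes pixels
        got = set(map(tuple, filled.pixel_set))
        assert got >= set(map(tuple, comp.pixel_set))


# ------------------------------------------------------------ size filter

def test_size_filter_inclusive_bounds():
    comps = [
        Component(label=i + 1, pixel_set=np.column_stack([np.arange(n), np.zeros(n, int)]))
        for i, n in enumerate([2, 5, 50, 10000])
    ]
    kept = filter_by_size(comps, 5, 5000)
    assert [c.area for c in kept] == [5, 50]  # min_area itself is kept
    assert filter_by_size(comps, 0, 10**9) == comps


# --------------------------------------------------------- full pipeline

def test_blank_plate_detects_nothing():
    img = grey_image(np.full((200, 200), 0.9))
    assert detect_spots(img, DetectionParams()) == []


def test_detects_all_synthetic_spots(sparse_plate):
    image, truth = sparse_plate
    comps = detect_spots(image, DetectionParams())
    assert len(comps) == len(truth)


def test_detection_invariant_to_global_intensity_shift(sparse_plate):
    image, _ = sparse_plate
    comps = detect_spots(image, DetectionParams())
    shifted = RgbImage(np.clip(image.pixels + 0.05, 0, 1), dpi=image.dpi)
    comps2 = detect_spots(shifted, DetectionParams())
    assert len(comps) == len(comps2)
    for a, b in zip(comps, comps2):
        assert np.array_equal(a.pixel_set, b.pixel_set)


def test_detection_recall_precision_on_default_plate(default_plate):
    from flyspot.io_batch import analyze_image

    image, truth = default_plate
    deposits = analyze_image(image, "plate")
    score = score_detection(truth, deposits)
    assert score.recall >= 0.95
    assert score.precision >= 0.95


def test_dpi_rescaling_of_size_bounds():
    params = DetectionParams(min_area=40, max_area=50000)
    scaled = params.scaled_to_dpi(600.0)
    assert scaled.min_area == 10 and scaled.max_area == 12500
    assert params.scaled_to_dpi(1200.0) is params
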