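"""Tissue segmentation: every stage against an independent brute-force
oracle on tiny inputs, plus the end-to-end overlap contract on a generated
slide."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfquant import tissue as T
from nfquant.tissue import (absorb_enclosed_regions, downscale, estimate_brightness_levels,
                            quadtree_segment, segment_tissue, surface_tension_grow,
                            synchronize_full_resolution, threshold_tissue)


# ---------------------------------------------------------------- downscale

def test_downscale_identity_and_constant():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (9, 7, 3)).astype(np.uint8)
    assert np.allclose(downscale(img, 1.0), img)
    const = np.full((8, 8, 3), 37, np.uint8)
    out = downscale(const, 0.125)
    assert out.shape == (1, 1, 3) and np.allclose(out, 37)


def test_downscale_matches_direct_block_means():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, (16, 16)).astype(float)
    out = downscale(img, 0.25)
    expected = np.array([[img[4 * i:4 * i + 4, 4 * j:4 * j + 4].mean() for j in range(4)]
                         for i in range(4)])
    assert np.allclose(out, expected)


def test_downscale_rejects_bad_factor():
    img = np.zeros((4, 4, 3), np.uint8)
    for factor in (0.0, -1.0, 1.5):
        with pytest.raises(ValueError):
            downscale(img, factor)


# ----------------------------------------------------------------- quadtree

def _quadtree_oracle(b, r0, c0, side, hsd, min_side):
    """Independent recursive reference: returns [(r0, c0, side), ...]."""
    h, w = b.shape
    if r0 >= h or c0 >= w:
        return []
    sub = b[r0:r0 + side, c0:c0 + side]
    if sub.std() > hsd and side > min_side and side > 1:
        half = side // 2
        out = []
        for dr in (0, half):
            for dc in (0, half):
                out += _quadtree_oracle(b, r0 + dr, c0 + dc, half, hsd, min_side)
        return out
    return [(r0, c0, side)]


def test_quadtree_constant_image_is_single_root():
    seg = quadtree_segment(np.full((16, 16, 3), 50, np.uint8), homogeneity_sd=5, min_side=1)
    assert len(seg.blocks) == 1 and seg.blocks[0].side == 16


def test_quadtree_one_noisy_quadrant_oracle():
    img = np.zeros((4, 4), float)
    img[:2, :2] = [[0, 100], [100, 0]]  # SD far above threshold
    seg = quadtree_segment(img, homogeneity_sd=5.0, min_side=1)
    got = sorted((b.row, b.col, b.side) for b in seg.blocks)
    expected = sorted(_quadtree_oracle(img, 0, 0, 4, 5.0, 1))
    assert got == expected
    # the noisy quadrant split to unit blocks, the three flat ones did not
    assert (0, 0, 1) in got and (2, 2, 2) in got


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_quadtree_matches_oracle_on_random_images(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (16, 16)).astype(float)
    img[8:, :] = 200.0  # a homogeneous half
    seg = quadtree_segment(img, homogeneity_sd=20.0, min_side=2)
    got = sorted((b.row, b.col, b.side) for b in seg.blocks)
    assert got == sorted(_quadtree_oracle(img, 0, 0, 16, 20.0, 2))


@pytest.mark.parametrize("shape", [(16, 16), (12, 9), (33, 64)])
def test_quadtree_blocks_tile_the_image(shape):
    rng = np.random.default_rng(4)
    img = rng.integers(0, 256, shape).astype(float)
    seg = quadtree_segment(img, homogeneity_sd=10.0, min_side=2)
    cover = np.zeros(shape, int)
    for b in seg.blocks:
        cover[b.row:b.row + b.height, b.col:b.col + b.width] += 1
    assert np.all(cover == 1)  # no overlap, no gap
    assert seg.tiled_area() == img.size


# ------------------------------------------------------ brightness estimates

def test_brightness_estimates_computed_from_block_table():
    img = np.zeros((16, 16), float)
    img[:, 8:] = 240.0  # flat white half
    rng = np.random.default_rng(5)
    img[:, :8] = 120.0 + rng.normal(0, 30, (16, 8))  # textured grey half
    seg = quadtree_segment(img, homogeneity_sd=5.0, min_side=2)
    levels = estimate_brightness_levels(seg)
    max_side = max(b.side for b in seg.blocks)
    assert levels.background == np.median([b.mean for b in seg.blocks if b.side == max_side])
    assert levels.tissue == np.median([b.mean for b in seg.blocks])
    assert levels.background > levels.tissue and not levels.degenerate


def test_single_block_segmentation_is_degenerate():
    seg = quadtree_segment(np.full((8, 8), 100.0), homogeneity_sd=5.0, min_side=2)
    levels = estimate_brightness_levels(seg)
    assert levels.background == levels.tissue == 100.0
    assert levels.degenerate


def test_estimates_invariant_to_block_order():
    rng = np.random.default_rng(6)
    img = rng.integers(0, 256, (16, 16)).astype(float)
    seg = quadtree_segment(img, homogeneity_sd=10.0, min_side=2)
    shuffled = T.QuadtreeSegmentation(blocks=list(reversed(seg.blocks)),
                                      homogeneity_sd=10.0, min_side=2, shape=seg.shape)
    a, b = estimate_brightness_levels(seg), estimate_brightness_levels(shuffled)
    assert (a.background, a.tissue) == (b.background, b.tissue)


# ---------------------------------------------------------------- threshold

def test_threshold_matches_pixelwise_oracle():
    rng = np.random.default_rng(7)
    img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
    bg, tis = 220.0, 100.0
    mask = threshold_tissue(img, bg, tis)
    mid = (bg + tis) / 2
    for r in range(8):
        for c in range(8):
            assert mask[r, c] == (img[r, c].astype(float).mean() < mid)


def test_threshold_all_bright_is_empty_and_precondition():
    img = np.full((4, 4, 3), 255, np.uint8)
    assert not threshold_tissue(img, 240.0, 200.0).any()
    with pytest.raises(ValueError):
        threshold_tissue(img, 100.0, 200.0)


def test_threshold_recovers_generated_tissue(small_slide):
    """Working-resolution threshold covers >=99% of true tissue and <=1% of
    background at default noise."""
    slide, _, truth = small_slide
    working = downscale(slide.pixels, 0.125)
    seg = quadtree_segment(working)
    levels = estimate_brightness_levels(seg)
    mask = threshold_tissue(working, levels.background, levels.tissue)
    gt_working = downscale(truth.tissue_mask.astype(float), 0.125) > 0.5
    assert np.sum(mask & gt_working) / np.sum(gt_working) >= 0.99
    assert np.sum(mask & ~gt_working) / np.sum(~gt_working) <= 0.01


# -------------------------------------------------------- enclosed regions

def _enclosed_oracle(mask, max_fraction):
    """Flood-fill reference for enclosed-speck absorption (4-connectivity)."""
    mask = mask.copy()
    h, w = mask.shape
    seen = np.zeros_like(mask, bool)
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, comp, touches = [(r0, c0)], [], False
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                if r in (0, h - 1) or c in (0, w - 1):
                    touches = True
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            if not touches and len(comp) <= max_fraction * mask.size:
                for r, c in comp:
                    mask[r, c] = False
    return mask


def test_speck_removed_blob_kept():
    mask = np.zeros((20, 20), bool)
    mask[2:12, 2:12] = True  # large blob (happens to be enclosed but too big)
    mask[15, 15] = mask[15, 16] = mask[16, 15] = True  # 3-px speck
    out = absorb_enclosed_regions(mask, max_fraction=0.02)
    assert out[5, 5] and not out[15, 15]


def test_speck_at_exact_size_limit_is_removed():
    """The limit is inclusive: area == max_fraction * image area absorbs."""
    mask = np.zeros((10, 10), bool)
    mask[4, 4] = mask[4, 5] = True  # area 2 == 0.02 * 100
    assert not absorb_enclosed_regions(mask, max_fraction=0.02).any()
    assert np.array_equal(absorb_enclosed_regions(mask, max_fraction=0.019), mask)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_absorption_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((16, 16)) < 0.4
    for frac in (0.01, 0.05, 0.2):
        assert np.array_equal(absorb_enclosed_regions(mask, frac), _enclosed_oracle(mask, frac))


def test_no_background_means_nothing_enclosed():
    mask = np.ones((8, 8), bool)
    assert absorb_enclosed_regions(mask, 1.0).all()


# ------------------------------------------------------- surface tension

def _majority_oracle(mask, radius):
    """One relaxation step: brute-force disc majority vote per boundary pixel."""
    h, w = mask.shape
    out = mask.copy()
    for r in range(h):
        for c in range(w):
            on_boundary = False
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                nb = mask[min(max(rr, 0), h - 1), min(max(cc, 0), w - 1)]
                if nb != mask[r, c]:
                    on_boundary = True
            if not on_boundary:
                continue
            votes_t = votes = 0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr * dr + dc * dc > radius * radius:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        votes += 1
                        votes_t += int(mask[rr, cc])
            if votes_t * 2 > votes:
                out[r, c] = True
            elif votes_t * 2 < votes:
                out[r, c] = False
    return out


def _perimeter(mask):
    return int(np.sum(mask[1:] != mask[:-1]) + np.sum(mask[:, 1:] != mask[:, :-1]))


def test_zero_iterations_is_identity_and_full_mask_unchanged():
    rng = np.random.default_rng(8)
    mask = rng.random((10, 10)) < 0.5
    assert np.array_equal(surface_tension_grow(mask, iterations=0), mask)
    full = np.ones((10, 10), bool)
    assert surface_tension_grow(full, iterations=5).all()


def test_notch_filled_and_perimeter_decreases():
    mask = np.zeros((16, 16), bool)
    mask[4:12, 4:12] = True
    mask[4, 7] = False  # 1-px staircase notch on the top edge
    out = surface_tension_grow(mask, iterations=3, radius=2)
    assert out[4, 7]
    assert _perimeter(out) < _perimeter(mask)
    # first iteration agrees with the brute-force majority oracle
    one = surface_tension_grow(mask, iterations=1, radius=2)
    assert np.array_equal(one, _majority_oracle(mask, 2))


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_perimeter_never_increases(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((14, 14)) < 0.5
    prev = _perimeter(mask)
    cur = mask
    for _ in range(4):
        cur = surface_tension_grow(cur, iterations=1, radius=2)
        assert _perimeter(cur) <= prev
        prev = _perimeter(cur)


# ------------------------------------------------------- synchronization

def test_sync_single_pixel_and_count_conservation():
    full = synchronize_full_resolution(np.array([[True]]), (8, 8))
    assert full.shape == (8, 8) and full.all()
    rng = np.random.default_rng(9)
    mask = rng.random((4, 4)) < 0.5
    up = synchronize_full_resolution(mask, (16, 16))
    assert up.sum() == mask.sum() * 16  # factor^-2 exactly for aligned shapes


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sync_roundtrip_by_majority(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((6, 5)) < 0.5
    up = synchronize_full_resolution(mask, (24, 20))
    down = downscale(up.astype(float), 0.25) > 0.5
    assert np.array_equal(down, mask)


def test_sync_rejects_incompatible_shapes():
    mask = np.zeros((4, 4), bool)
    with pytest.raises(ValueError):
        synchronize_full_resolution(mask, (2, 2))
    with pytest.raises(ValueError):
        synchronize_full_resolution(mask, (8, 40))


# ------------------------------------------------------------- end to end

def test_end_to_end_jaccard_against_ground_truth(small_slide):
    slide, _, truth = small_slide
    result = segment_tissue(slide.pixels)
    inter = np.sum(result.full & truth.tissue_mask)
    union = np.sum(result.full | truth.tissue_mask)
    assert inter / union >= 0.95
    assert result.background_brightness > result.tissue_brightness
    # nearest-neighbour consistency between the two resolutions
    assert np.array_equal(result.full,
                          synchronize_full_resolution(result.working, result.full.shape))
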