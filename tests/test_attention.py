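"""Attention-map localization against brute-force oracles."""

import numpy as np
import pytest

from finebird.attention import (
    BoundingBox,
    EmptyMaskError,
    PartWindow,
    attention_threshold,
    binarize,
    compute_attention_map,
    crop_and_resize,
    iou,
    largest_component_bbox,
    localize_object,
    map_box_to_image,
    propose_part_windows,
    select_part_windows,
    window_mean_attention,
)
from finebird.backbones import IdentityBackbone


# ---------------------------------------------------------------------------
# oracles


def flood_fill_components(mask):
    """Brute-force 8-connected labeling."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, cells = [(sy, sx)], []
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    cells.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(cells)
    return comps


def greedy_oracle(cands, max_iou, top_n):
    """Independent greedy selection, written against the box tuples only."""
    def key(c):
        return (-c.mean_attention, c.scale_id, c.box.y0, c.box.x0)

    kept = []
    for c in sorted(cands, key=key):
        if len(kept) == top_n:
            break
        ok = True
        for k in kept:
            ix = max(0, min(c.box.x1, k.box.x1) - max(c.box.x0, k.box.x0))
            iy = max(0, min(c.box.y1, k.box.y1) - max(c.box.y0, k.box.y0))
            inter = ix * iy
            if inter / (c.box.area + k.box.area - inter) > max_iou:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# attention map and threshold


def test_attention_map_single_channel_is_identity(rng):
    stack = rng.random((1, 4, 6))
    np.testing.assert_array_equal(compute_attention_map(stack), stack[0])


def test_attention_map_constant_sum():
    stack = np.ones((2, 2, 2))
    np.testing.assert_array_equal(compute_attention_map(stack), np.full((2, 2), 2.0))


def test_attention_map_matches_loop_oracle(rng):
    stack = rng.random((8, 5, 5))
    expected = np.zeros((5, 5))
    for c in range(8):
        for y in range(5):
            for x in range(5):
                expected[y, x] += stack[c, y, x]
    np.testing.assert_allclose(compute_attention_map(stack), expected, atol=1e-12)


def test_attention_map_is_linear(rng):
    f, g = rng.random((4, 3, 3)), rng.random((4, 3, 3))
    np.testing.assert_allclose(
        compute_attention_map(f + g),
        compute_attention_map(f) + compute_attention_map(g),
        atol=1e-12,
    )


def test_attention_map_rejects_empty():
    with pytest.raises(ValueError):
        compute_attention_map(np.empty((0, 2, 2)))


@pytest.mark.parametrize(
    "grid,expected",
    [
        (np.full((3, 5), 3.7), 3.7),
        (np.zeros((4, 4)), 0.0),
        (np.array([[0.0, 2.0], [4.0, 6.0]]), 3.0),
    ],
)
def test_attention_threshold_is_global_mean(grid, expected):
    assert attention_threshold(grid) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# mask and components


def test_binarize_strict_inequality():
    grid = np.array([[1.0, 0.0], [0.0, 0.0]])
    np.testing.assert_array_equal(
        binarize(grid, 0.25), np.array([[True, False], [False, False]])
    )


def test_constant_map_yields_empty_mask():
    grid = np.full((5, 5), 2.5)
    assert not binarize(grid, attention_threshold(grid)).any()


def test_binarize_matches_elementwise_oracle(rng):
    grid = rng.random((7, 9))
    theta = attention_threshold(grid)
    mask = binarize(grid, theta)
    for y in range(7):
        for x in range(9):
            assert mask[y, x] == (grid[y, x] > theta)


def test_largest_component_all_true():
    assert largest_component_bbox(np.ones((3, 4), bool)) == BoundingBox(0, 0, 4, 3)


def test_largest_component_single_cell():
    mask = np.zeros((5, 6), bool)
    mask[2, 3] = True
    assert largest_component_bbox(mask) == BoundingBox(3, 2, 4, 3)


def test_largest_component_picks_bigger_blob():
    mask = np.zeros((8, 8), bool)
    mask[0:1, 0:3] = True  # 3-cell blob
    mask[4:6, 4:7] = True
    mask[5, 4] = False  # 5-cell blob
    box = largest_component_bbox(mask)
    comps = flood_fill_components(mask)
    biggest = max(comps, key=len)
    ys = [c[0] for c in biggest]
    xs = [c[1] for c in biggest]
    assert box == BoundingBox(min(xs), min(ys), max(xs) + 1, max(ys) + 1)


def test_largest_component_contains_winning_cells(rng):
    for _ in range(20):
        mask = rng.random((10, 10)) > 0.7
        if not mask.any():
            continue
        box = largest_component_bbox(mask)
        biggest = max(flood_fill_components(mask), key=len)
        for y, x in biggest:
            assert box.x0 <= x < box.x1 and box.y0 <= y < box.y1


def test_largest_component_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        largest_component_bbox(np.zeros((3, 3), bool))


# ---------------------------------------------------------------------------
# coordinate mapping and cropping


def test_map_box_identity_when_shapes_match():
    box = BoundingBox(1, 2, 3, 4)
    assert map_box_to_image(box, (6, 6), (6, 6)) == box


def test_map_box_full_map_gives_full_image():
    assert map_box_to_image(BoundingBox(0, 0, 14, 14), (14, 14), (448, 448)) == BoundingBox(
        0, 0, 448, 448
    )


def test_map_box_stride_32():
    out = map_box_to_image(BoundingBox(2, 3, 5, 6), (14, 14), (448, 448))
    assert out == BoundingBox(64, 96, 160, 192)


def test_map_box_rejects_degenerate_shape():
    with pytest.raises(ValueError):
        map_box_to_image(BoundingBox(0, 0, 1, 1), (0, 4), (8, 8))


def test_crop_full_image_identity(rng):
    img = rng.random((6, 8, 3))
    out = crop_and_resize(img, BoundingBox(0, 0, 8, 6), (6, 8))
    np.testing.assert_array_equal(out, img)


def test_crop_nearest_upscale_checkerboard():
    img = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = crop_and_resize(img, BoundingBox(0, 0, 2, 2), (4, 4), interpolation="nearest")
    expected = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
    )
    np.testing.assert_array_equal(out, expected)


def test_crop_matches_slice_then_resample(rng):
    from skimage.transform import resize

    img = rng.random((20, 24, 3))
    box = BoundingBox(3, 2, 15, 11)
    out = crop_and_resize(img, box, (7, 9))
    expected = resize(img[2:11, 3:15], (7, 9, 3), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_crop_rejects_out_of_bounds(rng):
    with pytest.raises(ValueError):
        crop_and_resize(rng.random((4, 4)), BoundingBox(0, 0, 5, 4), (2, 2))


# ---------------------------------------------------------------------------
# window scoring, IoU, selection


def test_window_mean_constant_map():
    grid = np.full((6, 6), 1.25)
    assert window_mean_attention(grid, BoundingBox(1, 2, 4, 5)) == pytest.approx(1.25)


def test_whole_map_window_equals_threshold(rng):
    grid = rng.random((5, 7))
    assert window_mean_attention(grid, BoundingBox(0, 0, 7, 5)) == pytest.approx(
        attention_threshold(grid), abs=1e-12
    )


def test_window_mean_matches_loop_oracle(rng):
    grid = rng.random((6, 6))
    box = BoundingBox(1, 1, 4, 3)
    total = 0.0
    for y in range(1, 3):
        for x in range(1, 4):
            total += grid[y, x]
    assert window_mean_attention(grid, box) == pytest.approx(total / 6, abs=1e-12)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 2, 2), 1.0),
        (BoundingBox(0, 0, 2, 2), BoundingBox(5, 5, 7, 7), 0.0),
        (BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3), 1 / 7),
    ],
)
def test_iou(a, b, expected):
    assert iou(a, b) == pytest.approx(expected, abs=1e-12)


def test_propose_single_full_window(rng):
    cands = propose_part_windows(rng.random((3, 3)), [(3, 3)], 1)
    assert len(cands) == 1
    assert cands[0].box == BoundingBox(0, 0, 3, 3)


def test_propose_counts_grid():
    cands = propose_part_windows(np.zeros((4, 4)), [(2, 2)], 1)
    assert len(cands) == 9


def test_propose_matches_double_loop_oracle(rng):
    grid = rng.random((7, 8))
    sizes = [(3, 3), (2, 4)]
    cands = propose_part_windows(grid, sizes, 1)
    expected = []
    for sid, (wh, ww) in enumerate(sizes):
        for y0 in range(7 - wh + 1):
            for x0 in range(8 - ww + 1):
                expected.append((sid, y0, x0, grid[y0 : y0 + wh, x0 : x0 + ww].mean()))
    assert len(cands) == len(expected)
    for c, (sid, y0, x0, v) in zip(cands, expected):
        assert (c.scale_id, c.box.y0, c.box.x0) == (sid, y0, x0)
        assert c.mean_attention == pytest.approx(v, abs=1e-9)


def test_propose_rejects_oversized_window():
    with pytest.raises(ValueError):
        propose_part_windows(np.zeros((3, 3)), [(4, 4)], 1)


def test_select_single_candidate():
    c = PartWindow(BoundingBox(0, 0, 2, 2), 1.0, 0)
    assert select_part_windows([c], 0.25, 3) == [c]


def test_select_suppresses_duplicate():
    a = PartWindow(BoundingBox(0, 0, 2, 2), 2.0, 0)
    b = PartWindow(BoundingBox(0, 0, 2, 2), 1.0, 0)
    assert select_part_windows([b, a], 0.25, 5) == [a]


def test_select_matches_independent_greedy_oracle(rng):
    for _ in range(10):
        cands = [
            PartWindow(
                BoundingBox(x0, y0, x0 + int(rng.integers(1, 4)), y0 + int(rng.integers(1, 4))),
                float(rng.random()),
                int(rng.integers(0, 3)),
            )
            for x0, y0 in rng.integers(0, 6, size=(20, 2))
        ]
        got = select_part_windows(cands, 0.25, 4)
        assert got == greedy_oracle(cands, 0.25, 4)


def test_selection_sorted_and_pairwise_separated(rng):
    cands = [
        PartWindow(BoundingBox(x, y, x + 3, y + 3), float(rng.random()), 0)
        for x, y in rng.integers(0, 8, size=(30, 2))
    ]
    got = select_part_windows(cands, 0.3, 6)
    scores = [w.mean_attention for w in got]
    assert scores == sorted(scores, reverse=True)
    for i in range(len(got)):
        for j in range(i + 1, len(got)):
            assert iou(got[i].box, got[j].box) <= 0.3


# ---------------------------------------------------------------------------
# end-to-end localization


def test_localize_recovers_bright_rectangle():
    img = np.zeros((32, 32, 3))
    img[8:20, 10:26] = 1.0
    box = localize_object(img, IdentityBackbone())
    assert box == BoundingBox(10, 8, 26, 20)


def test_localize_uniform_image_falls_back_to_full_box():
    img = np.full((16, 24, 3), 0.5)
    assert localize_object(img, IdentityBackbone()) == BoundingBox(0, 0, 24, 16)


def test_localize_prefers_larger_blob():
    img = np.zeros((40, 40, 3))
    img[2:6, 2:6] = 1.0        # 16 cells
    img[20:28, 20:28] = 1.0    # 64 cells
    assert localize_object(img, IdentityBackbone()) == BoundingBox(20, 20, 28, 28)
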