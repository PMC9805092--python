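"""Segmentation and ring-peeling: oracle equivalence, tiling, size filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

import surfquant as sq
from surfquant.segmentation import CORE, CellLabelMap, SegmentationError
from surfquant.synthetic import SceneSpec, generate_micrograph


def erosion_depth_oracle(mask, n_in, n_out, structure="cross"):
    """Brute-force ring labelling by iterated binary erosion/dilation."""
    se = ndi.generate_binary_structure(2, 1 if structure == "cross" else 2)
    ring = np.full(mask.shape, 99, dtype=int)
    current = mask.copy()
    for k in range(n_in):
        eroded = ndi.binary_erosion(current, se, border_value=0)
        ring[current & ~eroded] = -k
        current = eroded
    ring[current] = CORE
    grown = mask.copy()
    for k in range(1, n_out + 1):
        dilated = ndi.binary_dilation(grown, se)
        ring[dilated & ~grown] = k
        grown = dilated
    return ring


def disk_mask(radius, pad=6):
    size = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:size, :size] - (radius + pad)
    return (yy**2 + xx**2) <= radius**2


def ring_battery_masks():
    """Deterministic mask battery, bounding boxes up to 41x41 px."""
    masks = [disk_mask(r) for r in range(1, 18)]
    yy, xx = np.mgrid[:41, :41] - 20.0
    masks.append((yy / 18) ** 2 + (xx / 11) ** 2 <= 1)        # ellipse
    masks.append((np.abs(yy) <= 14) & (np.abs(xx) <= 9))      # rectangle
    masks.append((np.abs(yy) + np.abs(xx)) <= 16)             # diamond
    rng = np.random.default_rng(7)
    for _ in range(25):                                        # random blobs
        blob = rng.random((41, 41)) < 0.35
        blob = ndi.binary_closing(ndi.binary_opening(blob))
        masks.append(blob)
    return masks


def assert_matches_oracle(mask, n_in=10, n_out=4):
    labels, _ = ndi.label(mask, structure=ndi.generate_binary_structure(2, 1))
    rings = sq.peel_rings(CellLabelMap(labels), n_in=n_in, n_out=n_out)
    oracle = erosion_depth_oracle(mask, n_in, n_out)
    inside = labels > 0
    assert np.array_equal(rings.ring[inside], oracle[inside])
    # outward shells: same coordinates, regardless of owner assignment
    out_impl = np.where((rings.ring > 0) & (rings.cell > 0), rings.ring, 0)
    out_oracle = np.where((oracle >= 1) & (oracle <= n_out), oracle, 0)
    assert np.array_equal(out_impl, out_oracle)


@pytest.mark.parametrize("mask", ring_battery_masks(), ids=lambda m: f"area{int(m.sum())}")
def test_peel_matches_erosion_depth_oracle(mask):
    assert_matches_oracle(mask)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.2, 0.6))
def test_peel_matches_oracle_on_random_masks(seed, density):
    rng = np.random.default_rng(seed)
    mask = rng.random((23, 23)) < density
    assert_matches_oracle(mask, n_in=6, n_out=3)


def test_inward_rings_and_core_tile_each_cell():
    mg, gt = generate_micrograph(SceneSpec(n_cells=12, seed=3))
    cells = CellLabelMap(gt.labels)
    rings = sq.peel_rings(cells)
    areas = cells.areas()
    counts = rings.counts()
    inward = counts[(counts.ring <= 0) | (counts.ring == CORE)]
    per_cell = inward.groupby("cell_id")["n_pixels"].sum()
    assert (per_cell == areas).all()
    # rings pairwise disjoint by construction (single ring value per pixel);
    # deeper ring empty implies all deeper ones empty
    for cid, group in counts.groupby("cell_id"):
        present = set(group.ring)
        ks = sorted(-r for r in present if r <= 0 and r != CORE)
        assert ks == list(range(len(ks)))


def test_small_cell_exhausts_rings_without_core():
    # 5-px-wide digital disk: three erosions empty it, CORE never reached
    yy, xx = np.mgrid[:15, :15] - 7
    mask = (yy**2 + xx**2) < 9
    rings = sq.peel_rings(CellLabelMap(mask.astype(int)), n_in=10)
    counts = rings.counts()
    inward = set(counts.loc[counts.ring <= 0, "ring"]) - {CORE}
    assert inward == {0, -1, -2}
    assert CORE not in set(counts.ring)


def test_ring_counts_monotone_for_disks():
    for radius in (8, 12, 20):
        rings = sq.peel_rings(CellLabelMap(disk_mask(radius, pad=8).astype(int)))
        counts = rings.counts().set_index("ring")["n_pixels"]
        inward = [counts.get(r, 0) for r in rings.inward_coordinates]
        assert all(a >= b for a, b in zip(inward, inward[1:]))


def test_blank_image_yields_no_cells():
    cells = sq.segment_cells(np.full((128, 128), 100.0))
    assert cells.n_cells == 0


def test_segmentation_recovers_synthetic_cells():
    mg, gt = generate_micrograph(SceneSpec(n_cells=5, seed=9, image_shape=(360, 360)))
    cells = sq.segment_cells(mg.cona)
    assert cells.n_cells == 5
    for cid in range(1, 6):
        truth = gt.labels == cid
        ids, overlap = np.unique(cells.labels[truth], return_counts=True)
        keep = ids > 0
        assert keep.any()
        best = ids[keep][np.argmax(overlap[keep])]
        seg = cells.labels == best
        iou = (truth & seg).sum() / (truth | seg).sum()
        assert iou >= 0.9


def test_size_filter_drops_specks():
    image = np.full((128, 128), 100.0)
    image[60:63, 60:63] = 2000.0  # 9-px speck
    cells = sq.segment_cells(image, min_area=100, max_area=5000, shrink_px=0)
    assert cells.n_cells == 0


def test_non_2d_input_rejected():
    with pytest.raises(SegmentationError):
        sq.segment_cells(np.zeros((4, 4, 4)))
    with pytest.raises(SegmentationError):
        sq.peel_rings(CellLabelMap(disk_mask(4).astype(int)), n_in=0)
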