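"""Background estimation, ring profiles, peak localization, FB estimation."""

import numpy as np
import pandas as pd
import pytest

import surfquant as sq
from surfquant.profiles import InsufficientCellsError, ProfileError
from surfquant.segmentation import CORE, CellLabelMap
from surfquant.synthetic import SceneSpec, generate_micrograph

from conftest import analyse_scene, scene_profiles


def _disk_labels(radius=15, size=64):
    yy, xx = np.mgrid[:size, :size] - size // 2
    return CellLabelMap(((yy**2 + xx**2) <= radius**2).astype(int))


def test_background_of_constant_image():
    cells = _disk_labels()
    rings = sq.peel_rings(cells)
    assert sq.estimate_background(np.full((64, 64), 100.0), rings) == 100.0


def test_background_matches_generator_level(control_scene):
    mg, gt = control_scene
    spec_level = 100.0
    noiseless, _ = generate_micrograph(
        SceneSpec(n_cells=30, surface_fraction_true=0.0, seed=1, gaussian_sd=0.0)
    )
    _, rings, bg, _ = analyse_scene(noiseless)
    assert bg == spec_level
    # with noise sd 10 the median over ~2e5 free pixels stays within +-1
    _, _, bg_noisy, _ = analyse_scene(mg)
    assert abs(bg_noisy - spec_level) < 1.0


def test_background_requires_free_pixels():
    cells = CellLabelMap(np.ones((32, 32), dtype=int))
    rings = sq.peel_rings(cells)
    with pytest.raises(ProfileError):
        sq.estimate_background(np.zeros((32, 32)), rings)


def test_flat_cell_profile_normalizes_to_one():
    cells = _disk_labels()
    rings = sq.peel_rings(cells)
    image = np.full((64, 64), 40.0)
    image[cells.labels > 0] = 300.0
    prof = sq.ring_profile(image, rings, background=40.0)
    inward = prof.data[(prof.data.ring <= 0)]
    assert np.allclose(inward.normalized, 1.0)


def test_degenerate_denominator_flags_cell_invalid():
    cells = _disk_labels()
    rings = sq.peel_rings(cells)
    prof = sq.ring_profile(np.full((64, 64), 50.0), rings, background=50.0)
    assert not prof.cells["valid"].any()
    assert len(prof.valid_cell_ids()) == 0


def test_profile_invariant_to_constant_offset(control_scene):
    mg, gt = control_scene
    cells = CellLabelMap(gt.labels)
    rings = sq.peel_rings(cells)
    bg = sq.estimate_background(mg.gfp, rings)
    prof = sq.ring_profile(mg.gfp, rings, bg)
    prof_shift = sq.ring_profile(mg.gfp + 500.0, rings, bg + 500.0)
    pd.testing.assert_series_equal(
        prof.data.normalized, prof_shift.data.normalized, atol=1e-12, rtol=0
    )


@pytest.mark.parametrize("depth", [4, 5])
def test_peak_ring_tracks_shell_depth(depth):
    spec = SceneSpec(
        n_cells=8, surface_fraction_true=1.0, wall_peak_depth=float(depth),
        seed=20 + depth, gaussian_sd=5.0,
    )
    mg, gt = generate_micrograph(spec)
    _, rings, bg, prof = analyse_scene(mg, use_truth_labels=gt.labels)
    # pure-surface cells have no interior signal: normalize by raw medians
    data = prof.data.copy()
    data["normalized"] = data["median_corr"]
    peaks = sq.locate_peak(data)
    assert (peaks == -depth).all()


def test_peak_tie_breaks_to_outermost_and_errors_when_empty():
    data = pd.DataFrame(
        {"cell_id": 1, "ring": [0, -1, -2, -3, -4], "normalized": [0.1, 0.2, 0.9, 0.9, 0.3]}
    )
    assert sq.locate_peak(data) .iloc[0] == -2
    with pytest.raises(ProfileError):
        sq.locate_peak(data.iloc[:0])


def test_intracellular_pattern_peaks_at_innermost_ring(control_scene):
    mg, gt = control_scene
    _, rings, bg, prof = analyse_scene(mg, use_truth_labels=gt.labels)
    peaks = sq.locate_peak(prof)
    assert (peaks <= -6).mean() > 0.9  # deep-interior plateau, no surface peak


def test_uniform_fill_without_blur_gives_unit_fb():
    spec = SceneSpec(
        n_cells=10, surface_fraction_true=0.0, fill_margin=0.0,
        psf_sigma=0.0, gaussian_sd=0.0, seed=3,
    )
    mg, gt = generate_micrograph(spec)
    _, rings, bg, prof = analyse_scene(mg, use_truth_labels=gt.labels)
    fb = sq.BleedthroughEstimator(min_cells=5).fit(prof)
    assert np.allclose(fb.fb_, 1.0)


def test_fb_matches_characterized_bleed_geometry(fb_model):
    # intracellular signal bleeds ~half into ring -4 and ~90% into ring -5
    assert fb_model.fb_[-4] == pytest.approx(0.5, abs=0.1)
    assert fb_model.fb_[-5] == pytest.approx(0.9, abs=0.1)
    ordered = fb_model.fb_.sort_index(ascending=False).to_numpy()
    assert (np.diff(ordered) >= -0.02).all()  # non-decreasing toward interior


def test_fb_matches_generator_truth(fb_model):
    _, gt = generate_micrograph(
        SceneSpec(n_cells=20, surface_fraction_true=0.0, seed=33, gaussian_sd=0.0)
    )
    for ring, value in gt.fb_true.items():
        assert fb_model.fb_[ring] == pytest.approx(value, abs=0.05)


def test_fb_requires_minimum_cells():
    prof = scene_profiles(0.0, seeds=[41], n_cells=10, shape=(360, 360))[0][3]
    with pytest.raises(InsufficientCellsError, match="deficit"):
        sq.BleedthroughEstimator(min_cells=40).fit(prof)


def test_fb_pooling_consistent_across_strains():
    single = scene_profiles(0.0, seeds=[51, 52])
    pooled = scene_profiles(0.0, seeds=[51, 52, 53, 54, 55, 56])
    fb_one = sq.BleedthroughEstimator().fit([p for *_, p in single])
    fb_pool = sq.BleedthroughEstimator().fit([p for *_, p in pooled])
    sem_one = fb_one.sd_ / np.sqrt(fb_one.n_cells_)
    assert (np.abs(fb_one.fb_ - fb_pool.fb_) <= 2 * sem_one + 1e-3).all()
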