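"""Generator invariants: determinism, conservation, geometry, validation."""

import numpy as np
import pandas as pd
import pytest

import surfquant as sq
from surfquant.synthetic import (
    AssaySpec,
    SceneGenerationError,
    SceneSpec,
    SyntheticDataError,
    generate_calibration_table,
    generate_growth_curves,
    generate_kinetics_dataset,
    generate_micrograph,
)


def test_identical_seeds_give_bit_identical_scenes():
    spec = SceneSpec(n_cells=20, surface_fraction_true=0.3, seed=1)
    a, _ = generate_micrograph(spec)
    b, _ = generate_micrograph(SceneSpec(n_cells=20, surface_fraction_true=0.3, seed=1))
    assert np.array_equal(a.gfp, b.gfp) and np.array_equal(a.cona, b.cona)


def test_empty_scene_is_pure_background():
    spec = SceneSpec(n_cells=0, gaussian_sd=0.0, seed=0)
    mg, gt = generate_micrograph(spec)
    assert np.all(mg.gfp == spec.background_level)
    assert gt.labels.max() == 0 and gt.fb_true is None


def test_pure_surface_no_blur_keeps_core_at_background():
    spec = SceneSpec(
        n_cells=8, surface_fraction_true=1.0, psf_sigma=0.0, gaussian_sd=0.0, seed=4
    )
    mg, gt = generate_micrograph(spec)
    rings = sq.peel_rings(sq.CellLabelMap(gt.labels))
    core = rings.ring == sq.CORE
    assert core.any()
    assert np.all(mg.gfp[core] == spec.background_level)


def test_total_gfp_flux_is_conserved():
    spec = SceneSpec(n_cells=15, surface_fraction_true=0.4, gaussian_sd=0.0, seed=6)
    mg, gt = generate_micrograph(spec)
    rendered = (mg.gfp - spec.background_level).sum()
    expected = gt.total_gfp_true.sum()
    assert rendered == pytest.approx(expected, rel=1e-3)


def test_cona_profile_peaks_at_wall_depth():
    spec = SceneSpec(
        n_cells=10, radius_range=(12.0, 20.0), gaussian_sd=0.0, seed=8
    )
    mg, gt = generate_micrograph(spec)
    rings = sq.peel_rings(sq.CellLabelMap(gt.labels))
    prof = sq.ring_profile(mg.cona, rings, spec.background_level)
    peaks = sq.locate_peak(prof)
    assert (peaks == -int(spec.wall_peak_depth)).all()


def test_cells_do_not_overlap():
    _, gt = generate_micrograph(SceneSpec(n_cells=40, seed=2, image_shape=(700, 700)))
    dists = np.hypot(
        *(gt.centers[:, None, :] - gt.centers[None, :, :]).transpose(2, 0, 1)
    )
    np.fill_diagonal(dists, np.inf)
    limits = gt.radii[:, None] + gt.radii[None, :]
    assert (dists > limits).all()
    labels = np.unique(gt.labels)
    assert np.array_equal(labels, np.arange(labels.max() + 1))


def test_placement_failure_raises():
    with pytest.raises(SceneGenerationError):
        generate_micrograph(SceneSpec(n_cells=50, image_shape=(128, 128), seed=0))


def test_invalid_specs_rejected():
    with pytest.raises(SyntheticDataError):
        SceneSpec(surface_fraction_true=1.5).validate()
    with pytest.raises(SyntheticDataError):
        SceneSpec(radius_range=(10.0, 5.0)).validate()
    with pytest.raises(SyntheticDataError):
        AssaySpec(km_true=-1.0).validate()
    with pytest.raises(SyntheticDataError):
        AssaySpec(substrate_concentrations=(5.0, 1.0)).validate()


def test_fb_true_bounded_and_monotone_toward_interior():
    _, gt = generate_micrograph(SceneSpec(n_cells=15, seed=5, gaussian_sd=0.0))
    fb = gt.fb_true.sort_index(ascending=False)  # ring 0 first, then deeper
    assert ((fb >= 0) & (fb <= 1.5)).all()
    assert (np.diff(fb.to_numpy()) >= -1e-9).all()


def test_calibration_table_noiseless_lies_on_power_law():
    table = generate_calibration_table([1e4, 1e5, 1e6], noise_sd=0.0, seed=0)
    strains = table[table.strain_id != "control"]
    control = table[table.strain_id == "control"]
    gc = sq.gfp_corr(strains.gfp, strains.od600)
    gn = sq.gfp_norm(gc, sq.gfp_corr(control.gfp, control.od600).mean())
    model = sq.fit_calibration(
        strains.molecules_per_cell_true.to_numpy(), np.asarray(gn)
    )
    assert model.r_squared_ == pytest.approx(1.0, abs=1e-12)
    assert model.slope_ == pytest.approx(1.0, abs=1e-9)


def test_calibration_rejects_nonpositive_abundance():
    with pytest.raises(SyntheticDataError):
        generate_calibration_table([1e4, -2.0])


def test_kinetics_saturation_and_half_saturation_identities():
    km = 25.0
    spec = AssaySpec(
        km_true=km,
        substrate_concentrations=(km, 1000.0 * km),
        autohydrolysis_rate=0.0,
        read_noise_sd=0.0,
        n_replicates=1,
    )
    table = generate_kinetics_dataset(spec)
    scale = spec.epsilon * spec.pathlength * 1e-6 * spec.duration_min
    rates = table[~table.is_control].set_index("substrate_uM")["a405"] / scale
    assert rates[1000.0 * km] == pytest.approx(spec.vmax_true, rel=1e-3)
    assert rates[km] == pytest.approx(spec.vmax_true / 2.0, rel=1e-12)


def test_kinetics_dataset_includes_paired_controls_and_is_deterministic():
    spec = AssaySpec(seed=11)
    a = generate_kinetics_dataset(spec)
    b = generate_kinetics_dataset(AssaySpec(seed=11))
    pd.testing.assert_frame_equal(a, b)
    per_s = a.groupby("substrate_uM")["is_control"].agg(["sum", "size"])
    assert (per_s["sum"] * 2 == per_s["size"]).all()


def test_growth_curves_validation_and_exponential_recovery():
    with pytest.raises(SyntheticDataError):
        generate_growth_curves([0.4], od0=0.0)
    # effectively exponential segment: huge carrying capacity, no noise
    table = generate_growth_curves(
        [0.693], od0=0.01, duration_h=6.0, noise_sd=0.0, carrying_capacity=1e9
    )
    mu = sq.growth_rate(table.time_min.to_numpy(), table.od600.to_numpy())
    assert mu == pytest.approx(0.693, rel=1e-6)
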