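import numpy as np
import pandas as pd
import pytest

import surfquant as sq
from surfquant.synthetic import SceneSpec, generate_micrograph


def analyse_scene(micrograph, *, use_truth_labels=None):
    """Segment (or adopt truth labels), peel, estimate background, profile."""
    if use_truth_labels is not None:
        cells = sq.CellLabelMap(use_truth_labels)
    else:
        cells = sq.segment_cells(micrograph.cona)
    rings = sq.peel_rings(cells)
    background = sq.estimate_background(micrograph.gfp, rings)
    prof = sq.ring_profile(micrograph.gfp, rings, background)
    return cells, rings, background, prof


def scene_profiles(f_true, seeds, n_cells=50, shape=(700, 700), **spec_kwargs):
    """Render scenes and return (gfp, rings, background, profiles) per scene."""
    out = []
    for seed in seeds:
        spec = SceneSpec(
            image_shape=shape, n_cells=n_cells,
            surface_fraction_true=f_true, seed=seed, **spec_kwargs,
        )
        mg, _ = generate_micrograph(spec)
        _, rings, bg, prof = analyse_scene(mg)
        out.append((mg.gfp, rings, bg, prof))
    return out


@pytest.fixture(scope="session")
def fb_model():
    """FB estimated from ~100 segmented intracellular-control cells."""
    ctrl = scene_profiles(0.0, seeds=[11, 12])
    return sq.BleedthroughEstimator().fit([p for *_, p in ctrl])


@pytest.fixture(scope="session")
def control_scene():
    spec = SceneSpec(n_cells=30, surface_fraction_true=0.0, seed=1)
    return generate_micrograph(spec)


def pooled_display_records(f_true, seeds, fb, **kwargs):
    recs = []
    for gfp, rings, bg, prof in scene_profiles(f_true, seeds, **kwargs):
        recs.append(sq.quantify_display(gfp, rings, fb, bg, profiles=prof))
    return pd.concat(recs, ignore_index=True)
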