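"""Synthetic ground-truth data for every pipeline stage.

The micrograph generator renders disk-shaped yeast cells in two registered
channels. The wall stain (conA) is a Gaussian shell in distance-to-boundary
space peaking ``wall_peak_depth`` pixels inside the segmented border. The
reporter (GFP) channel mixes two per-cell components: a cytoplasmic fill
whose edge sits ``fill_margin`` pixels inside the border (the plasma
membrane lies inside the cell wall, so intracellular protein never reaches
the outermost rings) and a surface shell co-located with the wall stain,
weighted (1 - f) : f by the cell's true displayed fraction. Bleed-through of
intracellular signal into the wall rings is produced mechanistically by
Gaussian PSF blur of the fill, not imposed; the per-ring bleed fractions
``fb_true`` are measured from a noiseless intracellular-only render of the
same scene so that FB estimation can be validated against them.

Distance-to-boundary is measured in the same metric as the analysis peel
(city-block erosion depth for the default 3x3 cross element), so the shell's
peak ring and the core's emptiness are exact by construction.

The default geometry (``fill_margin`` 4.4 px, ``psf_sigma`` 0.8 px) is
calibrated so that intracellular controls bleed roughly half of the inner
signal into ring -4 and ~90% into ring -5, the operating regime the method
was characterized in.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .profiles import ring_profile
from .segmentation import CellLabelMap, peel_rings


class SyntheticDataError(ValueError):
    pass


class SceneGenerationError(SyntheticDataError):
    """Raised when non-overlapping cell placement fails after bounded retries."""


def _per_cell(value, n_cells: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_cells, float(arr))
    if arr.shape != (n_cells,):
        raise SyntheticDataError(f"{name} must be scalar or length n_cells")
    return arr


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic two-channel scene.

    Intensities are in arbitrary detector units (ADU), lengths in pixels.
    ``surface_fraction_true`` and ``inner_intensity`` may be scalars or
    per-cell sequences.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 30
    radius_range: tuple[float, float] = (14.0, 20.0)
    wall_peak_depth: float = 4.0
    wall_shell_sigma: float = 1.5
    surface_fraction_true: float | Sequence[float] = 0.2
    inner_intensity: float | Sequence[float] = 2.0e5
    fill_margin: float = 4.4
    psf_sigma: float = 0.8
    background_level: float = 100.0
    gaussian_sd: float = 10.0
    poisson: bool = False
    cona_intensity: float = 3.0e5
    placement_margin: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise SyntheticDataError("n_cells must be >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise SyntheticDataError("radius_range must be positive and ordered")
        f = _per_cell(self.surface_fraction_true, max(self.n_cells, 1), "surface_fraction_true")
        if ((f < 0) | (f > 1)).any():
            raise SyntheticDataError("surface_fraction_true must lie in [0, 1]")
        for name in ("inner_intensity", "background_level", "gaussian_sd",
                     "wall_shell_sigma", "cona_intensity"):
            val = np.asarray(getattr(self, name), dtype=float)
            if (val < 0).any():
                raise SyntheticDataError(f"{name} must be >= 0")
        if self.psf_sigma < 0:
            raise SyntheticDataError("psf_sigma must be >= 0")


@dataclasses.dataclass(frozen=True)
class Micrograph:
    """Registered two-channel image (GFP reporter + conA wall stain)."""

    gfp: np.ndarray
    cona: np.ndarray
    pixel_size_um: float = 0.1
    meta: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Truth channel for recovery tests: masks, per-cell parameters, bleed."""

    labels: np.ndarray
    surface_fraction_true: np.ndarray
    total_gfp_true: np.ndarray
    fb_true: pd.Series | None
    centers: np.ndarray = dataclasses.field(default=None)
    radii: np.ndarray = dataclasses.field(default=None)

    @property
    def label_map(self) -> CellLabelMap:
        return CellLabelMap(self.labels)


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centers; bounded retries."""
    h, w = spec.image_shape
    pad = 6.0 + 4.0 * spec.psf_sigma  # keep outward rings and PSF halo in frame
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 1000 * max(spec.n_cells, 1)
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise SceneGenerationError(
                f"placed only {len(centers)}/{spec.n_cells} cells after "
                f"{max_attempts} attempts; reduce n_cells or enlarge the image"
            )
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        lo_y, hi_y = r + pad, h - r - pad
        lo_x, hi_x = r + pad, w - r - pad
        if lo_y >= hi_y or lo_x >= hi_x:
            raise SceneGenerationError("image too small for the requested radii")
        cy, cx = rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)
        ok = all(
            np.hypot(cy - py, cx - px) > r + pr + spec.placement_margin
            for (py, px), pr in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


def _render_components(spec: SceneSpec, labels: np.ndarray):
    """Per-scene unit-mass fill and shell component images (pre-PSF).

    Both are defined on the city-block erosion depth of the rendered masks:
    the shell is a Gaussian of the depth centred at ``wall_peak_depth``
    (support truncated at 3 sigma and at the mask border), the fill is the
    region deeper than ``fill_margin``. Each component is normalized to unit
    total intensity per cell.
    """
    fg = labels > 0
    fill = np.zeros(labels.shape, dtype=float)
    shell = np.zeros(labels.shape, dtype=float)
    if not fg.any():
        return fill, shell
    depth = (ndi.distance_transform_cdt(fg, metric="taxicab") - 1).astype(float)

    lo = max(0.0, spec.wall_peak_depth - 3.0 * spec.wall_shell_sigma)
    hi = spec.wall_peak_depth + 3.0 * spec.wall_shell_sigma
    band = fg & (depth >= lo) & (depth <= hi)
    shell[band] = np.exp(
        -((depth[band] - spec.wall_peak_depth) ** 2) / (2.0 * spec.wall_shell_sigma**2)
    )
    # partial-volume edge: the ring straddling fill_margin gets fractional weight
    fill[fg] = np.clip(depth[fg] - spec.fill_margin + 1.0, 0.0, 1.0)

    for comp in (fill, shell):
        sums = ndi.sum_labels(comp, labels, index=np.arange(1, labels.max() + 1))
        sums = np.concatenate([[1.0], np.where(sums > 0, sums, 1.0)])
        comp /= sums[labels]
    return fill, shell


def generate_micrograph(spec: SceneSpec) -> tuple[Micrograph, GroundTruth]:
    """Render one scene and its ground truth. Identical specs (same seed)
    produce bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    labels = np.zeros((h, w), dtype=np.int32)
    if spec.n_cells > 0:
        centers, radii = _place_cells(spec, rng)
        yy, xx = np.mgrid[0:h, 0:w]
        for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = i
    else:
        centers = np.zeros((0, 2))
        radii = np.zeros(0)

    f_true = _per_cell(spec.surface_fraction_true, spec.n_cells, "surface_fraction_true")
    totals = _per_cell(spec.inner_intensity, spec.n_cells, "inner_intensity")

    fill, shell = _render_components(spec, labels)
    weights_fill = np.concatenate([[0.0], totals * (1.0 - f_true)])
    weights_shell = np.concatenate([[0.0], totals * f_true])
    gfp_signal = weights_fill[labels] * fill + weights_shell[labels] * shell
    cona_signal = spec.cona_intensity * shell

    def _blur(img):
        return ndi.gaussian_filter(img, spec.psf_sigma, mode="constant") if spec.psf_sigma > 0 else img

    gfp_signal = _blur(gfp_signal)
    cona_signal = _blur(cona_signal)

    # bleed truth from the noiseless intracellular-only render
    fb_true = None
    if spec.n_cells > 0:
        all_totals = np.concatenate([[0.0], totals])
        intra = _blur(all_totals[labels] * fill)
        rings = peel_rings(CellLabelMap(labels))
        prof = ring_profile(intra, rings, background=0.0, eps_floor=0.0)
        mat = prof.normalized_matrix(
            [r for r in rings.inward_coordinates if r in prof.data["ring"].unique()]
        )
        fb_true = mat.mean(axis=0).rename("fb_true")

    def _finish(signal):
        img = signal + spec.background_level
        if spec.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
        return img

    micrograph = Micrograph(
        gfp=_finish(gfp_signal),
        cona=_finish(cona_signal),
        meta={"seed": spec.seed, "n_cells": spec.n_cells},
    )
    truth = GroundTruth(
        labels=labels,
        surface_fraction_true=f_true,
        total_gfp_true=totals,
        fb_true=fb_true,
        centers=centers,
        radii=radii,
    )
    return micrograph, truth


def write_scene(outdir, micrograph: Micrograph, truth: GroundTruth, stem: str = "scene"):
    """Write 16-bit TIFF channel pairs plus a JSON ground-truth sidecar."""
    import json
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in (("gfp", micrograph.gfp), ("cona", micrograph.cona)):
        if np.nanmax(img) > 65535:
            warnings.warn(f"{name} channel saturates the 16-bit range; clipping")
        path = outdir / f"{stem}_{name}.tif"
        tifffile.imwrite(path, np.clip(np.round(img), 0, 65535).astype(np.uint16))
        paths[name] = str(path)
    tifffile.imwrite(outdir / f"{stem}_labels.tif", truth.labels.astype(np.uint16))
    sidecar = {
        "meta": micrograph.meta,
        "surface_fraction_true": truth.surface_fraction_true.tolist(),
        "total_gfp_true": truth.total_gfp_true.tolist(),
        "fb_true": None if truth.fb_true is None
        else {int(k): float(v) for k, v in truth.fb_true.items()},
        "paths": paths,
    }
    (outdir / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def generate_calibration_table(
    abundances: Sequence[float],
    slope: float = 1.0,
    intercept: float = -4.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    n_replicates: int = 7,
    control_gfp_per_od: float = 1000.0,
) -> pd.DataFrame:
    """Plate-reader table for reference strains of known molecules/cell.

    Readings follow log10(GFP_norm) = slope * log10(abundance) + intercept
    + N(0, noise_sd); raw GFP is reconstituted from a simulated OD600 and the
    autofluorescence of a negative-control strain, whose rows are appended
    (strain_id ``"control"``, molecules_per_cell_true = 0).
    """
    abundances = np.asarray(abundances, dtype=float)
    if (abundances <= 0).any():
        raise SyntheticDataError("abundances must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(abundances):
        for rep in range(n_replicates):
            log_norm = slope * np.log10(a) + intercept + rng.normal(0.0, noise_sd)
            od = rng.uniform(0.8, 1.6)
            gfp = 10.0**log_norm * control_gfp_per_od * od
            rows.append((f"ref{i:02d}", a, rep, gfp, od))
    for rep in range(n_replicates):
        od = rng.uniform(0.8, 1.6)
        rows.append(("control", 0.0, rep, control_gfp_per_od * od, od))
    return pd.DataFrame(
        rows, columns=["strain_id", "molecules_per_cell_true", "replicate", "gfp", "od600"]
    )


def default_calibration_abundances(
    n: int = 30, low: float = 2.3e3, high: float = 7.5e5
) -> np.ndarray:
    """Log-uniformly spaced reference abundances spanning the standard-curve
    range (2.3e3 to 7.5e5 molecules/cell)."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclasses.dataclass
class AssaySpec:
    """Parameters of a synthetic chromogenic (pNP-release) kinetics assay."""

    vmax_true: float = 0.6           # uM/min
    km_true: float = 25.0            # uM
    substrate_concentrations: Sequence[float] = tuple(
        np.round(np.logspace(np.log10(0.07), np.log10(134.1), 12), 3)
    )
    autohydrolysis_rate: float = 0.005  # uM/min
    epsilon: float = 18000.0            # 1/(M cm)
    pathlength: float = 1.0             # cm
    duration_min: float = 10.0
    read_noise_sd: float = 0.003        # absorbance units
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        s = np.asarray(self.substrate_concentrations, dtype=float)
        if (s <= 0).any() or not (np.diff(s) > 0).all():
            raise SyntheticDataError("substrate_concentrations must be positive and sorted")
        if self.vmax_true <= 0 or self.km_true <= 0:
            raise SyntheticDataError("vmax_true and km_true must be > 0")
        if self.epsilon <= 0 or self.pathlength <= 0 or self.duration_min <= 0:
            raise SyntheticDataError("epsilon, pathlength and duration must be > 0")


def generate_kinetics_dataset(spec: AssaySpec) -> pd.DataFrame:
    """Endpoint A405 table with paired autohydrolysis-control rows.

    Reaction rows follow A405 = eps * l * (v(S) + autohydrolysis) * t (in M)
    plus read noise, with v(S) = Vmax * S / (Km + S); control rows (substrate
    in buffer only) carry the autohydrolysis term alone.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scale = spec.epsilon * spec.pathlength * 1e-6  # absorbance per uM product
    rows = []
    for s in np.asarray(spec.substrate_concentrations, dtype=float):
        v = spec.vmax_true * s / (spec.km_true + s)
        for rep in range(spec.n_replicates):
            for is_control in (False, True):
                rate = spec.autohydrolysis_rate if is_control else v + spec.autohydrolysis_rate
                a405 = scale * rate * spec.duration_min
                if spec.read_noise_sd > 0:
                    a405 += rng.normal(0.0, spec.read_noise_sd)
                rows.append((s, rep, is_control, a405))
    out = pd.DataFrame(rows, columns=["substrate_uM", "replicate", "is_control", "a405"])
    out.attrs.update(
        {"epsilon": spec.epsilon, "pathlength": spec.pathlength,
         "duration_min": spec.duration_min, "seed": spec.seed}
    )
    return out


def generate_growth_curves(
    mu_list: Sequence[float],
    od0: float = 0.02,
    interval_min: float = 15.0,
    duration_h: float = 24.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    *,
    carrying_capacity: float = 1.5,
) -> pd.DataFrame:
    """Logistic OD600 trajectories sampled every ``interval_min`` minutes
    with multiplicative log-normal noise. One strain per growth rate."""
    mu = np.asarray(mu_list, dtype=float)
    if (mu <= 0).any():
        raise SyntheticDataError("growth rates must be positive")
    if od0 <= 0:
        raise SyntheticDataError("od0 must be > 0")
    if interval_min <= 0 or duration_h <= 0:
        raise SyntheticDataError("interval and duration must be > 0")
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_h * 60.0 + 0.5 * interval_min, interval_min)
    t_h = t_min / 60.0
    rows = []
    for i, m in enumerate(mu):
        growth = np.exp(m * t_h)
        od = carrying_capacity * od0 * growth / (carrying_capacity + od0 * (growth - 1.0))
        if noise_sd > 0:
            od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
        for tm, o in zip(t_min, od):
            rows.append((f"strain{i:02d}", m, tm, o))
    return pd.DataFrame(rows, columns=["strain_id", "mu_true", "time_min", "od600"])
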