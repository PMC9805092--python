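"""Per-cell displayed-fraction quantification.

The displayed fraction (display efficiency) of a cell is the ratio of
bleed-corrected integrated reporter intensity in the wall rings to the
background-corrected integrated intensity of the whole cell:

  corr1_i  = int_i - bg * P_i                 (background correction)
  corr2_i  = corr1_i - inner * FB_i * P_i     (intracellular bleed correction)
  fraction = sum_{i in wall} corr2_i / corr1_total

where ``int_i`` is the raw integrated intensity of ring i, ``P_i`` its pixel
count, ``bg`` the median background of the image, ``inner`` the
background-corrected CORE median of the same cell and ``FB_i`` the
fluorescence-bleed factor of ring i estimated from intracellular controls.
Negative corr2 values are kept in the sum (flooring them would bias the
intracellular null upward); only the final reported fraction is clamped to
[0, 1], the raw value is preserved alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .profiles import BleedthroughEstimator, RadialProfiles, ring_profile
from .segmentation import CORE, RingDecomposition

DEFAULT_WALL_SPAN: tuple[int, ...] = tuple(range(0, -10, -1))


class DisplayQuantError(ValueError):
    pass


def corrected_integrated_intensity(region_pixels, background: float) -> float:
    """Raw integrated intensity of a pixel region minus background * P_i.

    May be negative; the value is preserved, not floored.
    """
    pixels = np.asarray(region_pixels, dtype=float)
    return float(pixels.sum() - background * pixels.size)


def bleed_corrected_ring_intensity(
    corr1: float, inner_median_corr: float, fb_i: float, n_pixels: int
) -> float:
    """corr1 minus the predicted intracellular contribution inner * FB_i * P_i."""
    return float(corr1 - inner_median_corr * fb_i * n_pixels)


def quantify_display(
    image: np.ndarray,
    rings: RingDecomposition,
    fb: BleedthroughEstimator,
    background: float,
    *,
    wall_span: tuple[int, ...] = DEFAULT_WALL_SPAN,
    profiles: RadialProfiles | None = None,
) -> pd.DataFrame:
    """Per-cell display-fraction records.

    Returns a DataFrame indexed by cell_id with columns ``area``,
    ``corr1_total``, ``corr2_wall``, ``inner_median_corr``,
    ``displayed_fraction_raw``, ``displayed_fraction`` (clamped to [0, 1])
    and ``valid``. Cells with a degenerate CORE median or non-positive total
    are flagged invalid and carry NaN fractions.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != rings.cell.shape:
        raise DisplayQuantError("image and ring decomposition shapes differ")
    wall_span = tuple(wall_span)
    if not set(wall_span) <= set(rings.inward_coordinates):
        raise DisplayQuantError("wall_span must be a subset of the inward rings")
    missing = [r for r in wall_span if r not in fb.fb_.index]
    if missing:
        raise DisplayQuantError(f"FB model lacks coefficients for rings {missing}")

    if profiles is None:
        profiles = ring_profile(image, rings, background)

    sel = rings.cell > 0
    long = pd.DataFrame(
        {"cell_id": rings.cell[sel], "ring": rings.ring[sel], "value": image[sel]}
    )
    sums = (
        long.groupby(["cell_id", "ring"])["value"]
        .agg(n_pixels="size", total="sum")
        .reset_index()
    )
    sums["corr1"] = sums["total"] - background * sums["n_pixels"]

    inside = sums[(sums["ring"] <= 0) | (sums["ring"] == CORE)]
    records = inside.groupby("cell_id")[["n_pixels", "corr1"]].sum()
    records = records.rename(columns={"n_pixels": "area", "corr1": "corr1_total"})
    records["inner_median_corr"] = profiles.cells["inner_median_corr"]

    wall = sums[sums["ring"].isin(wall_span)].copy()
    wall["fb"] = wall["ring"].map(fb.fb_)
    inner = wall["cell_id"].map(profiles.cells["inner_median_corr"])
    wall["corr2"] = wall["corr1"] - inner * wall["fb"] * wall["n_pixels"]
    records["corr2_wall"] = wall.groupby("cell_id")["corr2"].sum()

    # validity hinges on the display denominator (total corrected intensity),
    # not on the profile-normalization denominator: a pure-surface cell has a
    # CORE median at background, which is a legitimate (near-zero) bleed term
    records["valid"] = (
        (records["corr1_total"] > 0)
        & records["inner_median_corr"].notna()
        & records["corr2_wall"].notna()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = records["corr2_wall"] / records["corr1_total"]
    records["displayed_fraction_raw"] = raw.where(records["valid"])
    records["displayed_fraction"] = records["displayed_fraction_raw"].clip(0.0, 1.0)
    records.index.name = "cell_id"
    return records


def display_fraction(record: pd.Series) -> float:
    """Clamped displayed fraction of a single quantification record."""
    if not record["valid"]:
        raise DisplayQuantError("cell flagged invalid (degenerate denominator)")
    return float(np.clip(record["corr2_wall"] / record["corr1_total"], 0.0, 1.0))


@dataclasses.dataclass(frozen=True)
class StrainDisplaySummary:
    strain_id: str
    n_cells: int
    mean_fraction: float
    sd_fraction: float
    mean_fraction_raw: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_strain(
    records: pd.DataFrame, min_cells: int = 200, strain_id: str = ""
) -> StrainDisplaySummary:
    """Mean/SD displayed fraction over the valid cells of one strain.

    Raises if fewer than ``min_cells`` valid cells are available, reporting
    the count (the method's per-replicate minimum).
    """
    valid = records[records["valid"]]
    if len(valid) < min_cells:
        raise DisplayQuantError(
            f"strain {strain_id or '<unnamed>'}: {len(valid)} valid cells < "
            f"required minimum {min_cells}"
        )
    return StrainDisplaySummary(
        strain_id=strain_id,
        n_cells=len(valid),
        mean_fraction=float(valid["displayed_fraction"].mean()),
        sd_fraction=float(valid["displayed_fraction"].std(ddof=1)),
        mean_fraction_raw=float(valid["displayed_fraction_raw"].mean()),
    )
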