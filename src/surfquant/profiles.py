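"""Ring fluorescence profiles and bleed-through (FB) estimation.

For every cell the median fluorescence of each concentric ring is background
corrected and normalized by the background-corrected median of the CORE (the
residual inner portion of the cell). Profiles of intracellular-control cells
yield the fluorescence-bleed factors ``FB_i``: the fraction of intracellular
signal detected in wall ring ``i``, later subtracted when quantifying
surface display.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator

from .segmentation import CORE, CellLabelMap, RingDecomposition


class ProfileError(ValueError):
    pass


class InsufficientCellsError(ProfileError):
    pass


def estimate_background(
    image: np.ndarray, regions: RingDecomposition | CellLabelMap
) -> float:
    """Median intensity of the cell-free area of the image.

    Pixels inside any cell mask or any outward ring are excluded; with a bare
    label map the masks are padded by 4 px instead.
    """
    image = np.asarray(image, dtype=float)
    if isinstance(regions, RingDecomposition):
        if image.shape != regions.cell.shape:
            raise ProfileError("image and ring decomposition shapes differ")
        free = regions.cell == 0
    else:
        if image.shape != regions.labels.shape:
            raise ProfileError("image and label map shapes differ")
        free = ~ndi.binary_dilation(regions.labels > 0, iterations=4)
    if not free.any():
        raise ProfileError("no cell-free pixels available for background estimation")
    return float(np.median(image[free]))


@dataclasses.dataclass(frozen=True)
class RadialProfiles:
    """Per-cell ring medians with background-corrected, CORE-normalized values.

    ``data`` is a long table (cell_id, ring, n_pixels, median, median_corr,
    normalized); ``cells`` holds per-cell inner medians and validity flags.
    Cells whose corrected CORE median does not exceed ``eps_floor`` are
    flagged invalid (degenerate normalization denominator) and must be
    excluded downstream.
    """

    data: pd.DataFrame
    cells: pd.DataFrame
    background: float

    def valid_cell_ids(self) -> np.ndarray:
        return self.cells.index[self.cells["valid"]].to_numpy()

    def normalized_matrix(self, rings: list[int] | None = None) -> pd.DataFrame:
        """Wide (cell x ring) matrix of normalized values for valid cells."""
        pivot = self.data.pivot(index="cell_id", columns="ring", values="normalized")
        pivot = pivot.loc[self.valid_cell_ids()]
        return pivot[rings] if rings is not None else pivot


def ring_profile(
    image: np.ndarray,
    rings: RingDecomposition,
    background: float,
    *,
    eps_floor: float | None = None,
) -> RadialProfiles:
    """Median ring fluorescence per cell, background corrected and normalized
    by the CORE median.

    ``eps_floor`` guards the normalization against non-positive denominators;
    it defaults to 1e-6 of the image dynamic range.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != rings.cell.shape:
        raise ProfileError("image and ring decomposition shapes differ")
    if eps_floor is None:
        eps_floor = 1e-6 * float(image.max() - image.min())

    sel = rings.cell > 0
    long = pd.DataFrame(
        {"cell_id": rings.cell[sel], "ring": rings.ring[sel], "value": image[sel]}
    )
    grouped = long.groupby(["cell_id", "ring"], sort=True)["value"]
    data = grouped.agg(n_pixels="size", median="median").reset_index()
    data["median_corr"] = data["median"] - background

    inner = (
        data.loc[data["ring"] == CORE, ["cell_id", "median_corr"]]
        .set_index("cell_id")["median_corr"]
        .rename("inner_median_corr")
    )
    all_ids = pd.Index(np.unique(rings.cell[sel]), name="cell_id")
    cells = inner.reindex(all_ids).to_frame()
    cells["valid"] = cells["inner_median_corr"] > eps_floor

    denom = data["cell_id"].map(cells["inner_median_corr"])
    with np.errstate(divide="ignore", invalid="ignore"):
        data["normalized"] = np.where(
            data["cell_id"].map(cells["valid"]).fillna(False),
            data["median_corr"] / denom,
            np.nan,
        )
    return RadialProfiles(data=data, cells=cells, background=float(background))


def locate_peak(profile: RadialProfiles | pd.DataFrame, cell_id: int | None = None):
    """Ring coordinate of the maximum normalized value over the inward rings.

    Ties are resolved toward the outermost ring (larger coordinate). With a
    :class:`RadialProfiles` and no ``cell_id``, returns a Series over valid
    cells. A peak at the innermost ring signals an intracellular pattern
    ("no surface peak"); a peak at -4/-5 distinguishes wall from membrane
    localization.
    """
    if isinstance(profile, RadialProfiles):
        data = profile.data[profile.data["cell_id"].isin(profile.valid_cell_ids())]
    else:
        data = profile
    inward = data[(data["ring"] <= 0) & (data["ring"] != CORE)]
    if cell_id is not None:
        inward = inward[inward["cell_id"] == cell_id]
    if inward.empty or inward["normalized"].isna().all():
        raise ProfileError("no inward-ring values to locate a peak in")

    def _argmax(group: pd.DataFrame) -> int:
        best = group["normalized"].max()
        return int(group.loc[group["normalized"] == best, "ring"].max())

    peaks = inward.groupby("cell_id")[["ring", "normalized"]].apply(_argmax)
    if cell_id is not None:
        return int(peaks.iloc[0])
    return peaks.rename("peak_ring")


class BleedthroughEstimator(BaseEstimator):
    """Estimate fluorescence-bleed factors FB_i from intracellular controls.

    FB_i is the mean (optionally median) over control cells of the normalized
    profile value at wall ring ``i``. Fitting requires at least ``min_cells``
    valid cells (the number of cells the method was established on per
    replicate in practice).

    Attributes (after ``fit``)
    --------------------------
    fb_ : pd.Series
        FB value per wall-ring coordinate.
    sd_ : pd.Series
        Between-cell standard deviation per ring.
    n_cells_ : int
    source_strains_ : list
    """

    def __init__(self, min_cells: int = 40, wall_rings: tuple[int, ...] = tuple(range(0, -10, -1)), aggregate: str = "mean"):
        self.min_cells = min_cells
        self.wall_rings = wall_rings
        self.aggregate = aggregate

    def fit(self, profiles: RadialProfiles | list[RadialProfiles], strain_ids=None):
        if isinstance(profiles, RadialProfiles):
            profiles = [profiles]
        mats = []
        for k, prof in enumerate(profiles):
            mat = prof.normalized_matrix()
            mat = mat[[r for r in self.wall_rings if r in mat.columns]]
            mat.index = pd.MultiIndex.from_product([[k], mat.index])
            mats.append(mat)
        stacked = pd.concat(mats)
        stacked = stacked.dropna(how="all")
        n = len(stacked)
        if n < self.min_cells:
            raise InsufficientCellsError(
                f"FB estimation needs >= {self.min_cells} valid intracellular-control "
                f"cells, got {n} (deficit {self.min_cells - n})"
            )
        if self.aggregate == "mean":
            self.fb_ = stacked.mean(axis=0)
        elif self.aggregate == "median":
            self.fb_ = stacked.median(axis=0)
        else:
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        self.fb_.name = "fb"
        if not np.isfinite(self.fb_).all():
            raise ProfileError("FB estimates must be finite")
        # noise can pull near-zero rings slightly negative; FB is a fraction
        self.fb_ = self.fb_.clip(lower=0.0)
        self.sd_ = stacked.std(axis=0, ddof=1).rename("sd")
        self.n_cells_ = n
        self.source_strains_ = list(strain_ids) if strain_ids is not None else []
        return self

    def to_dict(self) -> dict:
        return {
            "rings": [int(r) for r in self.fb_.index],
            "fb": [float(v) for v in self.fb_],
            "sd": [float(v) for v in self.sd_],
            "n_cells": self.n_cells_,
            "source_strains": self.source_strains_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BleedthroughEstimator":
        est = cls(min_cells=0)
        idx = pd.Index(payload["rings"], name="ring")
        est.fb_ = pd.Series(payload["fb"], index=idx, name="fb")
        est.sd_ = pd.Series(payload["sd"], index=idx, name="sd")
        est.n_cells_ = payload["n_cells"]
        est.source_strains_ = payload.get("source_strains", [])
        return est


def estimate_bleedthrough(
    profiles, min_cells: int = 40, strain_ids=None, **kwargs
) -> BleedthroughEstimator:
    """Functional wrapper over :class:`BleedthroughEstimator`."""
    return BleedthroughEstimator(min_cells=min_cells, **kwargs).fit(
        profiles, strain_ids=strain_ids
    )
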