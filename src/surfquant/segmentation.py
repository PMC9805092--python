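"""Cell segmentation from the wall-stain channel and concentric ring peeling.

Cells are identified on the concanavalin-A (wall stain) channel and each cell
mask is partitioned into signed one-pixel rings relative to the segmented
border: ring 0 is the outermost ring inside the mask, negative coordinates go
deeper inside (down to ``-(n_in - 1)``), the residual interior is the CORE,
and positive coordinates ``+1 .. +n_out`` are successive one-pixel shells
outside the mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu, threshold_triangle
from skimage.morphology import closing, disk
from skimage.segmentation import watershed

#: Ring-coordinate sentinel for the residual inner portion of the cell.
CORE: int = -128

_STRUCTURES = {
    "cross": ndi.generate_binary_structure(2, 1),
    "square": ndi.generate_binary_structure(2, 2),
}
_CDT_METRIC = {"cross": "taxicab", "square": "chessboard"}


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs."""


@dataclasses.dataclass(frozen=True)
class CellLabelMap:
    """Labelled cell masks (0 = background, cells numbered 1..n)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise SegmentationError("label map must be 2-D")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def areas(self) -> pd.Series:
        """Pixel area per cell, indexed by cell id."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)
        return pd.Series(counts[1:], index=self.cell_ids, name="area")

    def bounding_boxes(self) -> pd.DataFrame:
        slices = ndi.find_objects(self.labels)
        rows = []
        for cid, sl in zip(self.cell_ids, slices):
            if sl is None:
                continue
            rows.append((cid, sl[0].start, sl[0].stop, sl[1].start, sl[1].stop))
        return pd.DataFrame(
            rows, columns=["cell_id", "row_start", "row_stop", "col_start", "col_stop"]
        ).set_index("cell_id")

    def centroids(self) -> pd.DataFrame:
        coms = ndi.center_of_mass(
            self.labels > 0, self.labels, self.cell_ids.tolist()
        )
        return pd.DataFrame(coms, columns=["row", "col"], index=self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table (area, centroid, bounding box) for CSV export."""
        out = pd.concat([self.areas(), self.centroids(), self.bounding_boxes()], axis=1)
        out.index.name = "cell_id"
        return out


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]


def segment_cells(
    wall_channel: np.ndarray,
    min_area: int = 200,
    max_area: int = 5000,
    *,
    smooth_sigma: float = 1.0,
    threshold: str | float = "triangle",
    closing_radius: int = 1,
    split_touching: bool = True,
    split_min_distance: int = 10,
    shrink_px: int = 1,
    border_margin: int = 4,
) -> CellLabelMap:
    """Segment cells from the wall-stain channel.

    Recipe: Gaussian smoothing, global threshold, morphological closing and
    hole filling, optional distance-transform watershed to split touching
    objects, size filtering, and exclusion of cells whose outward rings would
    leave the image (``border_margin`` pixels).

    Parameters
    ----------
    threshold:
        ``"triangle"`` (default; robust when background dominates the
        histogram and the wall shell fades gradually), ``"otsu"``, or an
        absolute intensity value.
    """
    image = np.asarray(wall_channel, dtype=float)
    if image.ndim != 2:
        raise SegmentationError(f"expected a 2-D single-channel image, got ndim={image.ndim}")
    if not min_area < max_area:
        raise SegmentationError("min_area must be < max_area")

    smoothed = gaussian(image, sigma=smooth_sigma, preserve_range=True) if smooth_sigma > 0 else image
    if isinstance(threshold, str):
        if smoothed.max() == smoothed.min():  # blank frame: nothing to segment
            return CellLabelMap(np.zeros(image.shape, dtype=np.int32))
        thresh_fn = {"triangle": threshold_triangle, "otsu": threshold_otsu}[threshold]
        tval = thresh_fn(smoothed)
    else:
        tval = float(threshold)
    mask = smoothed > tval
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    # the thresholded object overshoots the stained border by roughly the
    # optical + smoothing blur; shrink compensates
    if shrink_px > 0:
        mask = ndi.binary_erosion(mask, _STRUCTURES["square"], iterations=shrink_px)

    if split_touching and mask.any():
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            ndi.gaussian_filter(distance, sigma=2.0),
            min_distance=split_min_distance,
            labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask, structure=_STRUCTURES["cross"])

    labels = np.asarray(labels, dtype=np.int32)
    counts = np.bincount(labels.ravel())
    for cid in np.nonzero((counts < min_area) | (counts > max_area))[0]:
        if cid:
            labels[labels == cid] = 0

    # drop cells whose +border_margin outward ring would leave the frame
    if border_margin > 0 and labels.max() > 0:
        edge = np.zeros(labels.shape, dtype=bool)
        m = border_margin
        edge[:m, :] = edge[-m:, :] = edge[:, :m] = edge[:, -m:] = True
        for cid in np.unique(labels[edge]):
            if cid:
                labels[labels == cid] = 0

    return CellLabelMap(_relabel_consecutive(labels))


@dataclasses.dataclass(frozen=True)
class RingDecomposition:
    """Per-pixel (cell, ring-coordinate) assignment.

    ``cell`` is nonzero where a pixel belongs to a cell's inward rings/CORE or
    to its outward shells; ``ring`` holds the signed ring coordinate there
    (:data:`CORE` for the residual interior). Inward rings plus CORE exactly
    tile each mask; outward shells are claimed by at most one cell.
    """

    cell: np.ndarray
    ring: np.ndarray
    n_in: int
    n_out: int

    @property
    def inward_coordinates(self) -> list[int]:
        return list(range(0, -self.n_in, -1))

    @property
    def outward_coordinates(self) -> list[int]:
        return list(range(1, self.n_out + 1))

    def mask_of(self, cell_id: int, ring: int) -> np.ndarray:
        return (self.cell == cell_id) & (self.ring == ring)

    def cell_mask(self, cell_id: int) -> np.ndarray:
        """The full original mask of one cell (inward rings plus CORE)."""
        return (self.cell == cell_id) & ((self.ring <= 0) | (self.ring == CORE))

    def counts(self) -> pd.DataFrame:
        """Long table of pixel counts P_i per (cell_id, ring)."""
        sel = self.cell > 0
        df = pd.DataFrame({"cell_id": self.cell[sel], "ring": self.ring[sel]})
        out = df.value_counts(["cell_id", "ring"]).rename("n_pixels").reset_index()
        return out.sort_values(["cell_id", "ring"], ignore_index=True)


def peel_rings(
    cells: CellLabelMap,
    n_in: int = 10,
    n_out: int = 4,
    *,
    structure: str = "cross",
) -> RingDecomposition:
    """Partition each cell into one-pixel inward/outward rings.

    Ring ``-k`` (k = 0 .. n_in-1) is the set of pixels removed by the
    (k+1)-th one-pixel erosion and not the k-th; CORE is whatever survives
    ``n_in`` erosions. Outward ring ``+k`` is the k-th one-pixel dilation
    shell, with contested background pixels awarded to the nearest cell.

    With a 3x3 cross (4-connected) structuring element the erosion depth of a
    pixel equals its city-block distance to the background minus one, so the
    peel is computed with a chamfer distance transform rather than iterated
    morphology; ``structure="square"`` uses the chessboard metric (8-connected
    peel) instead.
    """
    if n_in < 1:
        raise SegmentationError("n_in must be >= 1")
    if structure not in _CDT_METRIC:
        raise SegmentationError(f"unknown structuring element {structure!r}")
    labels = cells.labels
    fg = labels > 0
    metric = _CDT_METRIC[structure]

    ring = np.zeros(labels.shape, dtype=np.int16)
    cell = np.zeros(labels.shape, dtype=np.int32)

    if fg.any():
        # pad so the frame edge counts as background (erosion semantics)
        depth = ndi.distance_transform_cdt(np.pad(fg, 1), metric=metric)[1:-1, 1:-1] - 1
        inside = np.where(depth < n_in, -depth.astype(np.int16), np.int16(CORE))
        ring[fg] = inside[fg]
        cell[fg] = labels[fg]

        if n_out > 0:
            bg = ~fg
            d_out = ndi.distance_transform_cdt(bg, metric=metric)
            shell = bg & (d_out >= 1) & (d_out <= n_out)
            if shell.any():
                # nearest-cell tie-break for contested outward pixels
                _, (ir, ic) = ndi.distance_transform_edt(bg, return_indices=True)
                owner = labels[ir, ic]
                ring[shell] = d_out[shell].astype(np.int16)
                cell[shell] = owner[shell]

    return RingDecomposition(cell=cell, ring=ring, n_in=n_in, n_out=n_out)
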