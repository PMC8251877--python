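"""Watershed single-cell segmentation and per-cell quantification.

Cells are found on the nuclear plane: Gaussian smoothing, Otsu (or fixed)
foreground threshold, Euclidean distance transform, seeds at h-maxima
suppressed local maxima, then watershed on an elevation map that combines
the negated distance transform with an optional membrane-gradient term
(the membrane marker shapes boundaries between touching cells).  The whole
procedure is deterministic — there is no random number generator anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import reconstruction
from skimage.segmentation import relabel_sequential, watershed

from .stack_io import make_cell_table
from .preprocess import Mosaic

__all__ = ["SegmentationParams", "segment_cells", "quantify_cells", "gate_population"]


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 1.0
    threshold: str | float = "otsu"
    min_seed_distance: int = 5
    membrane_weight: float = 0.3
    h_maxima: float = 1.0
    min_area: int = 20
    max_area: int = 10_000

    def validate(self) -> None:
        if self.min_seed_distance < 1:
            raise ValueError("min seed distance must be >= 1")
        if self.min_area >= self.max_area:
            raise ValueError("min area must be below max area")
        if not (0.0 <= self.membrane_weight <= 1.0):
            raise ValueError("membrane weight must be in [0, 1]")


def segment_cells(
    nuclear: np.ndarray,
    membrane: np.ndarray | None = None,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Label individual cells on a registered nuclear plane.

    Returns an integer label image (0 = background, labels dense 1..N).
    An image with no foreground yields zero cells with a warning.
    """
    params = params or SegmentationParams()
    params.validate()
    if membrane is not None and membrane.shape != nuclear.shape:
        raise ValueError("membrane plane shape differs from nuclear plane")

    smoothed = ndi.gaussian_filter(nuclear.astype(float), params.smoothing_sigma)
    if params.threshold == "otsu":
        if np.ptp(smoothed) == 0:
            warnings.warn("constant nuclear image; no cells found")
            return np.zeros(nuclear.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold)
    foreground = smoothed > thr
    if not foreground.any():
        warnings.warn("no foreground after threshold; no cells found")
        return np.zeros(nuclear.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(foreground)
    # h-maxima suppression flattens noise plateaus so each nucleus keeps one peak
    if params.h_maxima > 0:
        suppressed = reconstruction(distance - params.h_maxima, distance, method="dilation")
    else:
        suppressed = distance
    coords = peak_local_max(
        suppressed,
        min_distance=params.min_seed_distance,
        labels=foreground,
        exclude_border=False,
    )
    if len(coords) == 0:
        warnings.warn("no seeds found; no cells segmented")
        return np.zeros(nuclear.shape, dtype=np.int32)
    # deterministic seed ids: raster order (lowest y, then x)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    markers = np.zeros(nuclear.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)

    elevation = -suppressed
    if membrane is not None and params.membrane_weight > 0:
        grad = sobel(membrane.astype(float))
        peak = grad.max()
        if peak > 0:
            elevation = elevation + params.membrane_weight * float(distance.max()) * (grad / peak)

    labels = watershed(elevation, markers=markers, mask=foreground, connectivity=1)

    sizes = np.bincount(labels.ravel())
    bad = np.flatnonzero((sizes < params.min_area) | (sizes > params.max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def quantify_cells(
    labels: np.ndarray,
    mosaic: Mosaic,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Cell table from a label image: centroid, area, mean marker intensity.

    Per-cell intensity is the mean (not sum) over the cell's pixels, so it
    is comparable across cell sizes and exposures.  The nuclear plane is
    included alongside the markers.
    """
    if labels.shape != mosaic.data.shape[1:]:
        raise ValueError("label image and mosaic shapes differ")
    if pixel_size_um is None:
        pixel_size_um = (mosaic.channel_map.pixel_size_um
                         if mosaic.channel_map is not None else 1.0)
    n = int(labels.max())
    if n == 0:
        return make_cell_table(
            np.array([], int), np.array([]), np.array([]), np.array([], int),
            {m: np.array([]) for m in mosaic.plane_names}, pixel_size_um,
        )
    idx = np.arange(1, n + 1)
    area = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, idx).astype(int)
    cy, cx = np.array(ndi.center_of_mass(np.ones_like(labels, float), labels, idx)).T
    intensities = {
        name: ndi.mean(mosaic.data[p], labels, idx)
        for p, name in enumerate(mosaic.plane_names)
    }
    return make_cell_table(idx, cy, cx, area, intensities, pixel_size_um)


def gate_population(
    table: pd.DataFrame,
    marker: str,
    threshold: float | None = None,
    interval: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Select cells by marker intensity: above a threshold or inside an interval.

    The returned subset keeps all columns (including x/y) for spatial plots.
    """
    if marker not in table.columns:
        raise KeyError(f"unknown marker {marker!r}")
    if (threshold is None) == (interval is None):
        raise ValueError("provide exactly one of threshold or interval")
    if threshold is not None:
        return table[table[marker] > threshold].copy()
    lo, hi = interval
    return table[(table[marker] >= lo) & (table[marker] < hi)].copy()
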