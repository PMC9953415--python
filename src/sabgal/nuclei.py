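"""DAPI nuclei segmentation and counting.

Cell number in a field of view is estimated from the DAPI fluorescence
image: bright nuclei on a dark background.  The count normalizes the
SA-β-gal integrated density to an ID-per-cell value.  Note the tool counts
*nuclei*; in multinucleated cultures the caller should apply a
cells-per-nucleus correction factor (see ``sabgal.batch``).

Pipeline (in order): optional ROI restriction → binarization (Otsu by
default, or a fixed 0–255 cutoff) → hole filling → minimum-area filter →
optional distance-transform watershed splitting of touching nuclei →
4-connected labeling, with labels renumbered 1..count in raster-scan order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = ["NucleiParams", "NucleiResult", "segment_nuclei", "count_in_roi"]

#: (row_min, row_max, col_min, col_max), half-open.
Roi = tuple[int, int, int, int]


@dataclass(frozen=True)
class NucleiParams:
    """Segmentation parameters.

    intensity_threshold : "otsu" or a fixed value in [0, 255]; foreground is
        strictly above the threshold.
    min_area_px : minimum object area in pixels.  The default of 50 rejects
        debris at a 20x-objective imaging scale while keeping nuclei; scale
        it with magnification.
    split_touching : split merged objects by distance-transform watershed
        with peak markers separated by at least ``2 * sqrt(min_area/pi)``
        (twice the radius of the smallest admissible nucleus).
    roi : optional (row_min, row_max, col_min, col_max) half-open bounds;
        segmentation (including the Otsu histogram) is restricted to it.
    exclude_border : drop nuclei whose bounding box touches the image edge.
        Off by default.
    """

    intensity_threshold: str | float = "otsu"
    min_area_px: int = 50
    split_touching: bool = False
    roi: Roi | None = None
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if isinstance(self.intensity_threshold, str):
            if self.intensity_threshold != "otsu":
                raise ValueError(
                    f"unknown threshold method {self.intensity_threshold!r}"
                )
        elif not 0 <= float(self.intensity_threshold) <= 255:
            raise ValueError("fixed intensity threshold must be in [0, 255]")


@dataclass
class NucleiResult:
    """Label map (0 = background, labels 1..count), count, per-nucleus
    areas (px) and centroids (row, col)."""

    label_map: np.ndarray
    count: int
    areas: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _empty_result(shape: tuple[int, int]) -> NucleiResult:
    return NucleiResult(
        label_map=np.zeros(shape, dtype=np.int32),
        count=0,
        areas=np.empty(0, dtype=int),
        centroids=np.empty((0, 2)),
    )


def _remove_small(fg: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 4-connected foreground objects with area < min_area."""
    lab = cc_label(fg, connectivity=1)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return sizes[lab] >= min_area


def _relabel_raster_order(lab: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n by order of first appearance in a raster scan."""
    flat = lab.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return lab.astype(np.int32)
    _, first_idx = np.unique(nz, return_index=True)
    order = nz[np.sort(first_idx)]  # old labels in raster order
    remap = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return remap[lab]


def _split_component(comp: np.ndarray, min_distance: int) -> np.ndarray:
    """Watershed-split one connected component; returns its label image.

    Peaks of the Euclidean distance transform, separated by at least
    ``min_distance``, seed the watershed.  A component with a single peak
    is returned unsplit.  Peaks are searched within the component only so
    that neighbouring nuclei cannot suppress each other's markers.
    """
    dist = ndi.distance_transform_edt(comp)
    coords = peak_local_max(
        dist, min_distance=min_distance, exclude_border=False, labels=comp
    )
    if len(coords) < 2:
        return comp.astype(np.int32)
    markers = np.zeros(comp.shape, dtype=np.int32)
    # markers numbered in raster-scan order of the peak coordinates
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    for k, idx in enumerate(order, start=1):
        markers[tuple(coords[idx])] = k
    return watershed(-dist, markers, mask=comp).astype(np.int32)


def segment_nuclei(dapi: np.ndarray, params: NucleiParams | None = None) -> NucleiResult:
    """Segment and count DAPI-stained nuclei in a grayscale image.

    Returns a :class:`NucleiResult` whose label map covers the full image
    (zeros outside the ROI when one is given) with consecutive labels in
    raster-scan order.  A flat image under Otsu yields count 0 rather than
    an error.
    """
    if params is None:
        params = NucleiParams()
    img = np.asarray(dapi, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")

    if params.roi is not None:
        r0, r1, c0, c1 = params.roi
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValueError(f"roi {params.roi} outside image bounds {img.shape}")
        work = img[r0:r1, c0:c1]
    else:
        r0 = c0 = 0
        work = img

    if params.intensity_threshold == "otsu":
        if np.all(work == work.ravel()[0]):
            return _empty_result(img.shape)
        thr = threshold_otsu(work)
    else:
        thr = float(params.intensity_threshold)
    fg = work > thr
    fg = ndi.binary_fill_holes(fg)
    fg = _remove_small(fg, params.min_area_px)
    if not fg.any():
        return _empty_result(img.shape)

    comp_lab = cc_label(fg, connectivity=1)
    if params.split_touching:
        min_dist = max(1, math.ceil(2.0 * math.sqrt(params.min_area_px / math.pi)))
        out = np.zeros(fg.shape, dtype=np.int32)
        offset = 0
        for ci in range(1, int(comp_lab.max()) + 1):
            comp = comp_lab == ci
            sub = _split_component(comp, min_dist)
            n_sub = int(sub.max())
            out[comp] = sub[comp] + offset
            offset += n_sub
        lab = out
        # watershed fragments below the area floor are discarded
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < params.min_area_px)
        lab[np.isin(lab, small[small > 0])] = 0
    else:
        lab = comp_lab.astype(np.int32)

    if params.exclude_border:
        edge_labels = np.unique(
            np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        )
        lab[np.isin(lab, edge_labels[edge_labels > 0])] = 0

    lab = _relabel_raster_order(lab)
    full = np.zeros(img.shape, dtype=np.int32)
    full[r0 : r0 + lab.shape[0], c0 : c0 + lab.shape[1]] = lab

    props = regionprops(full)
    areas = np.array([p.area for p in props], dtype=int)
    centroids = (
        np.array([p.centroid for p in props]) if props else np.empty((0, 2))
    )
    return NucleiResult(
        label_map=full, count=len(props), areas=areas, centroids=centroids
    )


def count_in_roi(result: NucleiResult, roi: Roi) -> int:
    """Count nuclei whose centroid lies inside a half-open ROI.

    The lower bounds are inclusive, the upper exclusive: a centroid with
    ``row == row_min`` counts, one with ``row == row_max`` does not.
    """
    r0, r1, c0, c1 = roi
    shape = result.label_map.shape
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"roi {roi} outside image bounds {shape}")
    if result.count == 0:
        return 0
    rows, cols = result.centroids[:, 0], result.centroids[:, 1]
    inside = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
    return int(inside.sum())
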