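"""Frame preparation and cell/nucleus segmentation.

Pipeline: background correction -> global Otsu threshold -> morphological
cleanup -> distance-transform watershed for touching cells.  Each cell is
then cropped into a fixed-side, zero-padded square, and partitioned into
nucleus (higher-attenuation Otsu class: 255 nm targets nucleic acids, so
nuclei attenuate more) and cytoplasm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

DEFAULT_MIN_AREA = 30  # px; objects below this are removed
DEFAULT_CROP_SIDE = 128  # px; fits activated cells at the ~300 nm resolution scale


@dataclass
class CellCrop:
    """Square, zero-padded image of one segmented cell."""

    image: np.ndarray
    cell_id: int
    frame_id: int = 0

    @property
    def mask(self) -> np.ndarray:
        return self.image > 0

    @property
    def side(self) -> int:
        return self.image.shape[0]


def background_correct(frame: np.ndarray) -> np.ndarray:
    """Map a raw frame to background-corrected attenuation in [0, 1].

    The background mode (histogram peak) is shifted to ~0 and the result
    rescaled by its maximum, a monotone transform invariant to a constant
    intensity offset.  A constant frame returns all zeros with a warning.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if np.any(frame < 0):
        raise ValueError("frame must be nonnegative")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        warnings.warn("constant frame: background correction is degenerate")
        return np.zeros_like(frame)
    hist, edges = np.histogram(frame, bins=256, range=(lo, hi))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    corrected = np.clip(frame - mode, 0.0, None)
    peak = corrected.max()
    if peak == 0:
        warnings.warn("frame entirely at/below background mode")
        return corrected
    return corrected / peak


def segment_cells(frame: np.ndarray, min_area: int = DEFAULT_MIN_AREA,
                  split_touching: bool = True) -> np.ndarray:
    """Label cells in a background-corrected frame.

    Otsu threshold, binary opening (disk radius 2), hole filling, small
    object removal, then a distance-transform watershed to split touching
    cells.  Labels are positive contiguous integers in raster order of
    centroids; an empty frame yields an all-zero mask.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.max() == frame.min():
        return np.zeros(frame.shape, dtype=np.int32)
    # hysteresis around the global Otsu cut: dim (e.g. dead-cell) cytoplasm
    # sits below plain Otsu but stays connected to its bright nucleus
    high = filters.threshold_otsu(frame)
    binary = filters.apply_hysteresis_threshold(frame, 0.3 * high, high)
    binary = morphology.opening(binary, morphology.disk(2))
    binary = ndimage.binary_fill_holes(binary)
    binary = _remove_small(binary, min_area)
    if not binary.any():
        return np.zeros(frame.shape, dtype=np.int32)

    if split_touching:
        distance = ndimage.gaussian_filter(ndimage.distance_transform_edt(binary), 2.0)
        # h-maxima markers: shallow secondary lobes of one irregular cell
        # merge, while the deep saddle between touching cells still splits
        maxima = morphology.h_maxima(distance, 2.0)
        markers, _ = ndimage.label(ndimage.binary_dilation(maxima, iterations=2))
        labels = segmentation.watershed(-distance, markers, mask=binary)
        labels = _remove_small(labels, min_area)
    else:
        labels, _ = ndimage.label(binary)

    return _relabel_raster(labels)


def _remove_small(image: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components / labels with fewer than ``min_area`` px."""
    if image.dtype == bool:
        lab, n = ndimage.label(image)
    else:
        lab, n = image, int(image.max())
    if n == 0:
        return image
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    keep = sizes >= min_area
    keep[0] = False
    if image.dtype == bool:
        return keep[lab]
    return np.where(keep[lab], lab, 0)


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..n in raster (row-major) order of centroids."""
    out = np.zeros_like(labels, dtype=np.int32)
    props = measure.regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    for new, p in enumerate(order, start=1):
        out[labels == p.label] = new
    return out


def crop_and_pad(frame: np.ndarray, mask: np.ndarray, cell_id: int,
                 side: int = DEFAULT_CROP_SIDE, frame_id: int = 0) -> CellCrop:
    """Extract one cell into a centered, zero-padded ``side x side`` crop.

    Pixels outside the cell mask are exactly zero, so the crop conserves
    the masked pixel sum and the mask area.
    """
    sel = np.asarray(mask) == cell_id
    if not sel.any():
        raise ValueError(f"cell id {cell_id} not present in mask")
    rows, cols = np.nonzero(sel)
    h = rows.max() - rows.min() + 1
    w = cols.max() - cols.min() + 1
    if h > side or w > side:
        raise ValueError(
            f"cell {cell_id} ({h}x{w}) exceeds crop side {side}; use a larger side"
        )
    patch = np.where(sel, frame, 0.0)[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
    out = np.zeros((side, side), dtype=np.float64)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    out[r0:r0 + h, c0:c0 + w] = patch
    return CellCrop(out, cell_id=int(cell_id), frame_id=frame_id)


class NucleusSegmentation(NamedTuple):
    nucleus: np.ndarray
    cytoplasm: np.ndarray
    degenerate: bool


def segment_nucleus(crop: CellCrop | np.ndarray,
                    opening_radius: int = 1) -> NucleusSegmentation:
    """Partition a cell crop into nucleus and cytoplasm masks.

    The nucleus is the higher-attenuation Otsu class within the cell,
    smoothed by morphological opening/closing with the largest connected
    component retained and holes filled; the cytoplasm is the remainder, so
    the two masks partition the cell mask exactly.  A cell with (nearly)
    uniform intensity has no defined nucleus: an empty nucleus mask is
    returned with ``degenerate=True``.
    """
    image = crop.image if isinstance(crop, CellCrop) else np.asarray(crop, dtype=float)
    cell = image > 0
    vals = image[cell]
    if vals.size == 0 or np.ptp(vals) < 1e-6:
        empty = np.zeros_like(cell)
        return NucleusSegmentation(empty, cell.copy(), True)
    thresh = filters.threshold_otsu(vals)
    nucleus = cell & (image > thresh)
    selem = morphology.disk(opening_radius)
    nucleus = morphology.opening(nucleus, selem)
    nucleus = morphology.closing(nucleus, selem)
    nucleus &= cell
    if nucleus.any():
        lab, n = ndimage.label(nucleus)
        if n > 1:
            sizes = ndimage.sum_labels(nucleus, lab, index=np.arange(1, n + 1))
            nucleus = lab == (1 + int(np.argmax(sizes)))
        nucleus = ndimage.binary_fill_holes(nucleus) & cell
    if not nucleus.any():
        return NucleusSegmentation(np.zeros_like(cell), cell.copy(), True)
    return NucleusSegmentation(nucleus, cell & ~nucleus, False)


def match_labels(pred: np.ndarray, truth: np.ndarray) -> dict[int, tuple[int, float]]:
    """Greedy best-IoU matching of predicted labels to ground-truth labels.

    Returns ``{truth_label: (pred_label, iou)}`` for each ground-truth cell.
    """
    out = {}
    for t in np.unique(truth):
        if t == 0:
            continue
        tsel = truth == t
        cand = np.unique(pred[tsel])
        cand = cand[cand > 0]
        best, best_iou = 0, 0.0
        for c in cand:
            psel = pred == c
            iou = np.logical_and(tsel, psel).sum() / np.logical_or(tsel, psel).sum()
            if iou > best_iou:
                best, best_iou = int(c), float(iou)
        out[int(t)] = (best, best_iou)
    return out
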