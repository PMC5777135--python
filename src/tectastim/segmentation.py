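"""Watershed segmentation of somata from the average projection.

Bright somata are turned into basins by inverting the intensity image;
markers are the extended minima of the inverted image at depth ``tolerance``
(the h-minima transform, matching the tolerance semantics of
morphological-segmentation tools), and a marker-controlled watershed assigns
every pixel to the basin of its nearest marker.  Oversegmentation is
tolerated: erroneously split cells produce near-identical traces and are
merged downstream by the duplicate-correlation filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from skimage.measure import label as _cc_label
from skimage.morphology import h_minima
from skimage.segmentation import watershed


@dataclass
class LabelMask:
    """Integer ROI labels (0 = background), contiguous in {1..n_rois}."""

    labels: np.ndarray
    n_rois: int
    provenance: str = "computed"
    offset: tuple[int, int] = (0, 0)          # (row, col) of pixel (0,0) in the
                                              # original image after cropping
    label_map: Optional[dict] = None          # old -> new ids after crop/relabel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.n_rois or (
            len(present) and (present[0] != 1 or present[-1] != self.n_rois)
        ):
            raise ValueError("labels must form a contiguous set {1..n_rois}")

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(1, self.n_rois + 1)

    def centroids(self) -> np.ndarray:
        """(n_rois, 2) ROI centroids in original-image coordinates."""
        out = np.zeros((self.n_rois, 2))
        flat = self.labels.ravel()
        counts = np.bincount(flat, minlength=self.n_rois + 1)[1:]
        rows, cols = np.indices(self.labels.shape)
        out[:, 0] = np.bincount(flat, weights=rows.ravel(), minlength=self.n_rois + 1)[1:] / counts
        out[:, 1] = np.bincount(flat, weights=cols.ravel(), minlength=self.n_rois + 1)[1:] / counts
        return out + np.asarray(self.offset)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, dict]:
    """Relabel to contiguous {1..n}, preserving ascending label order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(present, start=1):
        lut[old] = new
    return lut[labels], {int(old): int(new) for new, old in enumerate(present, start=1)}


def morphological_segment(
    image: np.ndarray,
    tolerance: float = 18.0,
    min_area_px: int = 4,
) -> LabelMask:
    """Segment bright somata on a 2-D image via marker-controlled watershed.

    ``tolerance`` (gray levels) is the minimum depth an inverted-intensity
    basin must have to seed its own region; regions smaller than
    ``min_area_px`` pixels are dropped.  A constant image yields 0 ROIs.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("morphological_segment expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    inverted = image.max() - image
    minima = h_minima(inverted, tolerance)
    markers = _cc_label(minima, connectivity=1)
    if markers.max() == 0:
        return LabelMask(labels=np.zeros(image.shape, dtype=np.int32), n_rois=0)
    labels = watershed(inverted, markers=markers, connectivity=1).astype(np.int32)

    if min_area_px > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        if small.size:
            labels[np.isin(labels, small)] = 0
    labels, _ = _relabel(labels)
    return LabelMask(labels=labels, n_rois=int(labels.max()))


def imported_mask(labels: np.ndarray) -> LabelMask:
    """Wrap an externally supplied integer label image (relabeled contiguous)."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("imported mask must be a 2-D integer image")
    relabeled, lmap = _relabel(labels.astype(np.int32))
    return LabelMask(labels=relabeled, n_rois=int(relabeled.max()),
                     provenance="imported", label_map=lmap)


def crop_to_region(
    obj: Union[np.ndarray, LabelMask],
    rectangle: tuple[int, int, int, int],
) -> Union[tuple[np.ndarray, tuple[int, int]], LabelMask]:
    """Crop an image or label mask to ``(r0, c0, r1, c1)`` (half-open bounds).

    For plain arrays, returns ``(cropped, (r0, c0))`` so coordinates can be
    mapped back.  For a :class:`LabelMask`, returns a new mask with labels
    renumbered contiguously and ``label_map`` recording old -> new ids.
    """
    r0, c0, r1, c1 = (int(v) for v in rectangle)
    arr = obj.labels if isinstance(obj, LabelMask) else np.asarray(obj)
    h, w = arr.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"empty or out-of-bounds rectangle {rectangle} for shape {(h, w)}")
    cropped = arr[r0:r1, c0:c1]
    if isinstance(obj, LabelMask):
        relabeled, lmap = _relabel(cropped)
        return LabelMask(
            labels=relabeled,
            n_rois=int(relabeled.max()),
            provenance=obj.provenance,
            offset=(obj.offset[0] + r0, obj.offset[1] + c0),
            label_map=lmap,
        )
    return cropped, (r0, c0)
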