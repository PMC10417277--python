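"""Nuclei segmentation and perinuclear ROI construction.

Nuclei are found on the Hoechst channel with a standard, auditable chain:
Gaussian smoothing -> global threshold (Otsu or fixed) -> hole filling ->
optional distance-transform watershed split of touching objects -> area
filter -> optional removal of border-touching objects.  Each nucleus is
then expanded into a perinuclear region of interest (ROI) by nearest-seed
label expansion, so contested pixels between adjacent cells go to the
closer nucleus and ROIs always partition their union.  The cell-free
complement of the dilated ROIs supplies the background-estimation mask.

Coordinates are 0-based, row-major, pixel-centre; areas are in pixels².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import regionprops_table

from .errors import ConfigError, DataError, InsufficientBackgroundError

LABEL_TABLE_COLUMNS = ("label", "centroid_y", "centroid_x", "area")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the nucleus finder.

    ``smoothing_sigma`` is the Gaussian pre-smoothing width (px);
    ``min_nucleus_area``/``max_nucleus_area`` bound accepted object areas
    (px²); ``watershed_min_distance`` is the minimum separation of
    watershed seed peaks (px) when splitting touching nuclei;
    ``roi_expansion_radius`` is how far each nucleus is grown into its
    perinuclear ROI (px).
    """

    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_nucleus_area: int = 30
    max_nucleus_area: int = 1000
    split_touching: bool = True
    watershed_min_distance: int = 5
    border_exclusion: bool = False
    roi_expansion_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.min_nucleus_area >= self.max_nucleus_area:
            raise ConfigError("min_nucleus_area must be < max_nucleus_area")
        if self.roi_expansion_radius < 0:
            raise ConfigError("roi_expansion_radius must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed_threshold required when threshold_method='fixed'")


@dataclass
class LabelMask:
    """Integer label image (0 = background, k > 0 = object k) with a
    per-label table of centroids and areas; labels are contiguous 1..N."""

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.table)

    def binary(self) -> np.ndarray:
        return self.labels > 0


def _label_table(labels: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(columns=list(LABEL_TABLE_COLUMNS))
    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    df = pd.DataFrame(props).rename(
        columns={"centroid-0": "centroid_y", "centroid-1": "centroid_x"}
    )
    return df[list(LABEL_TABLE_COLUMNS)].sort_values("label").reset_index(drop=True)


def find_nuclei(hoechst: np.ndarray, params: SegmentationParams | None = None) -> LabelMask:
    """Segment nuclei from a single-channel Hoechst image."""
    params = params or SegmentationParams()
    img = np.asarray(hoechst)
    if img.ndim != 2:
        raise DataError(f"expected a 2-D single-channel image, got ndim={img.ndim}")
    if np.issubdtype(img.dtype, np.integer):
        sat = np.iinfo(img.dtype).max
        if img.min() == sat:
            raise DataError("image is fully saturated; cannot segment")

    smoothed = filters.gaussian(
        img.astype(np.float64), sigma=params.smoothing_sigma, preserve_range=True
    )
    if params.threshold_method == "otsu":
        if smoothed.min() == smoothed.max():
            return LabelMask(np.zeros_like(img, dtype=np.int32), _label_table(np.zeros(1, np.int32)))
        thr = filters.threshold_otsu(smoothed)
    else:
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    binary = ndi.binary_fill_holes(smoothed > thr)

    if params.split_touching and binary.any():
        distance = ndi.distance_transform_edt(binary)
        # light smoothing breaks plateaus so each nucleus yields one peak
        distance_s = filters.gaussian(distance, sigma=1.0, preserve_range=True)
        coords = peak_local_max(
            distance_s,
            min_distance=params.watershed_min_distance,
            labels=binary,
            exclude_border=False,
        )
        markers = np.zeros_like(img, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)

    # area filter
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        bad = (areas < params.min_nucleus_area) | (areas > params.max_nucleus_area)
        bad[0] = False
        labels[bad[labels]] = 0
    if params.border_exclusion:
        labels = segmentation.clear_border(labels)
    labels, _, _ = segmentation.relabel_sequential(labels)
    labels = labels.astype(np.int32)
    return LabelMask(labels, _label_table(labels))


def expand_rois(
    nuclei: LabelMask, radius: float, exclude_nucleus: bool = False
) -> LabelMask:
    """Grow each nucleus into its perinuclear ROI.

    Each label is dilated by ``radius`` with contested pixels assigned to
    the nearest nucleus, so ROIs stay disjoint and jointly cover the union
    of the individual dilations.  By default the ROI includes the nucleus
    interior (reporter signal is assumed homogeneous over the cell); pass
    ``exclude_nucleus=True`` for an annular ROI.
    """
    if radius < 0:
        raise ConfigError("radius must be >= 0")
    labels = segmentation.expand_labels(nuclei.labels, distance=radius)
    if exclude_nucleus:
        labels = np.where(nuclei.labels > 0, 0, labels)
    labels = labels.astype(np.int32)
    return LabelMask(labels, _label_table(labels))


def cell_free_mask(
    rois: LabelMask, margin: float = 4.0, min_fraction: float = 0.01
) -> tuple[np.ndarray, float]:
    """Binary mask of pixels usable for background estimation.

    The mask is the complement of all ROIs dilated by ``margin`` pixels.
    Returns ``(mask, area_fraction)``; raises
    :class:`InsufficientBackgroundError` when less than ``min_fraction``
    of the frame remains cell-free (near-confluent field).
    """
    occupied = rois.binary()
    if margin > 0:
        occupied = morphology.dilation(occupied, morphology.disk(int(round(margin))))
    mask = ~occupied
    fraction = float(mask.mean())
    if fraction < min_fraction:
        raise InsufficientBackgroundError(
            f"cell-free area is {fraction:.2%} of the field "
            f"(< {min_fraction:.0%}); background not estimable"
        )
    return mask, fraction


def write_label_mask(mask: LabelMask, tiff_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write a label image as 16-bit TIFF and its table as CSV."""
    tifffile.imwrite(Path(tiff_path), mask.labels.astype(np.uint16))
    if csv_path is not None:
        mask.table.to_csv(Path(csv_path), index=False)


def match_centroids(
    truth_yx: np.ndarray, detected_yx: np.ndarray, max_dist: float = 5.0
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected centroids to truth.

    Returns ``(true_positives, false_positives, false_negatives)`` under a
    matching radius of ``max_dist`` pixels; used to score segmentation
    against generator ground truth.
    """
    truth_yx = np.asarray(truth_yx, dtype=float).reshape(-1, 2)
    detected_yx = np.asarray(detected_yx, dtype=float).reshape(-1, 2)
    if len(truth_yx) == 0 or len(detected_yx) == 0:
        return 0, len(detected_yx), len(truth_yx)
    d = np.linalg.norm(truth_yx[:, None, :] - detected_yx[None, :, :], axis=2)
    pairs = sorted(
        ((d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1]) if d[i, j] <= max_dist)
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        tp += 1
    return tp, len(detected_yx) - tp, len(truth_yx) - tp


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Detection F1 from matched counts; 0 when nothing matches."""
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
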