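"""Detection and measurement of chromogen-positive nerve profiles.

DAB-stained (brown) structures absorb strongly in the blue channel and have
a high red-minus-blue contrast, while the haematoxylin counterstain is
blue-dominant (R - B < 0).  Detection therefore proceeds inside the
tissue-and-ROI processing masks as: candidate pixels from a blue-channel
threshold, slight expansion of the candidate regions, a second threshold on
R - B, then morphological clean-up, a neighbourhood merge rule, and size
filtering before counting.

Connectivity conventions, used consistently: 8-connectivity for objects
(nerve profiles are thin and irregular), 4-connectivity for background
topology.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import closing, dilation, opening, disk

from .io import ROI_LABELS, ROIAnnotation

logger = logging.getLogger(__name__)

EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class NerveObject:
    """One segmented NF-positive profile at full resolution."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]
    area: int
    roi: int = 0  # 1-4 once assigned, 0 before assignment / outside all ROIs
    mean_rb: float = float("nan")  # mean red-minus-blue over the pixel set


@dataclasses.dataclass
class ROIMeasurement:
    roi: int
    count: int
    object_area_px2: int
    other_tissue_area_px2: int
    mean_object_area_px2: float


def restrict_to_rois(tissue_full: np.ndarray, annotation: ROIAnnotation) -> dict[int, np.ndarray]:
    """Per-ROI processing masks: tissue intersected with each ROI.

    Pixels outside every hand-drawn ROI never enter detection.  Raises if
    tissue and annotation do not overlap at all (slide/annotation mismatch).
    """
    tissue = np.asarray(tissue_full, bool)
    if tissue.shape != annotation.shape:
        raise ValueError(f"tissue mask shape {tissue.shape} != annotation shape {annotation.shape}")
    masks = {label: tissue & (annotation.labels == label) for label in ROI_LABELS}
    if not any(m.any() for m in masks.values()):
        raise ValueError("tissue mask does not intersect any ROI; annotation/slide mismatch?")
    return masks


def auto_blue_threshold(
    blue_values: np.ndarray, min_class_separation: float = 50.0
) -> float:
    """Otsu threshold on the blue channel, with a stain-presence guard.

    Otsu always splits its input, even a pure-noise unimodal histogram; on a
    slide with no chromogen it would flag about half the counterstained
    tissue.  The guard requires the two Otsu classes to differ in mean by at
    least ``min_class_separation`` grey levels (default 50, about half the
    blue-channel gap between DAB and haematoxylin); otherwise no stain is
    considered present and the threshold is 0 (empty candidate set).
    """
    vals = np.asarray(blue_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("cannot compute a threshold on an empty pixel set")
    if np.all(vals == vals.flat[0]):
        return 0.0
    thr = float(threshold_otsu(vals))
    low, high = vals[vals < thr], vals[vals >= thr]
    if low.size == 0 or high.size == 0 or (high.mean() - low.mean()) < min_class_separation:
        return 0.0
    return thr


def detect_candidates(
    pixels: np.ndarray,
    processing_mask: np.ndarray,
    blue_threshold: float | str = "auto",
    min_class_separation: float = 50.0,
) -> np.ndarray:
    """Threshold the blue colour layer to find possible stained nerves.

    Candidate pixels are processing-mask pixels whose blue value is strictly
    below the threshold.  ``"auto"`` computes the guarded Otsu threshold on
    the blue values inside the mask.
    """
    mask = np.asarray(processing_mask, bool)
    if not mask.any():
        raise ValueError("empty processing mask")
    blue = pixels[:, :, 2]
    if blue_threshold == "auto":
        blue_threshold = auto_blue_threshold(blue[mask], min_class_separation)
    return mask & (blue < float(blue_threshold))


def refine_candidates(
    pixels: np.ndarray,
    candidate_mask: np.ndarray,
    tissue_full: np.ndarray,
    expand_radius: int = 2,
    rb_diff_threshold: float = 30.0,
) -> np.ndarray:
    """Expand candidate regions slightly and re-threshold on red minus blue.

    Counterstained pixels (blue-dominant, R - B < 0) can never survive a
    positive threshold; chromogen pixels (brown, R >> B) do.  The result is
    clipped to the tissue mask.
    """
    cand = np.asarray(candidate_mask, bool)
    expanded = dilation(cand, disk(expand_radius)) if expand_radius > 0 else cand
    rb = pixels[:, :, 0].astype(np.int16) - pixels[:, :, 2].astype(np.int16)
    return expanded & (rb > rb_diff_threshold) & np.asarray(tissue_full, bool)


def _merge_groups(labels: np.ndarray, n: int, merge_gap: float) -> np.ndarray:
    """Union-find merge of labelled components whose minimal pairwise pixel
    distance is <= merge_gap.  Returns the group id per original label."""
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if merge_gap > 0 and n > 1:
        coords = np.argwhere(labels > 0)
        lab = labels[coords[:, 0], coords[:, 1]]
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(merge_gap, output_type="ndarray"):
            a, b = find(lab[i]), find(lab[j])
            if a != b:
                parent[max(a, b)] = min(a, b)
    return np.array([find(k) for k in range(n + 1)])


def optimize_objects(
    refined_mask: np.ndarray,
    pixels: np.ndarray | None = None,
    tissue_full: np.ndarray | None = None,
    min_size: int = 4,
    max_size: int = 5000,
    close_radius: int = 1,
    open_radius: int = 1,
    merge_gap: float = 3.0,
) -> list[NerveObject]:
    """Morphology, neighbourhood merging and size filtering of the refined
    mask into discrete objects.

    Closing (disc ``close_radius``) bridges within-profile gaps, opening
    (disc ``open_radius``) drops pixel-scale debris; 8-connected components
    whose minimal pairwise pixel distance (Euclidean, pixel centres) is
    <= ``merge_gap`` are merged into one object; merged objects outside
    [min_size, max_size] px^2 are discarded.
    """
    mask = np.asarray(refined_mask, bool)
    if close_radius > 0:
        mask = closing(mask, disk(close_radius))
    if open_radius > 0:
        mask = opening(mask, disk(open_radius))
    if tissue_full is not None:
        mask = mask & np.asarray(tissue_full, bool)
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n == 0:
        return []
    group_of = _merge_groups(labels, n, merge_gap)
    grouped = group_of[labels]
    objects: list[NerveObject] = []
    rb = None
    if pixels is not None:
        rb = pixels[:, :, 0].astype(np.int16) - pixels[:, :, 2].astype(np.int16)
    for gid in np.unique(grouped):
        if gid == 0:
            continue
        coords = np.argwhere(grouped == gid)
        area = len(coords)
        if area < min_size or area > max_size:
            continue
        centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        mean_rb = float(rb[coords[:, 0], coords[:, 1]].mean()) if rb is not None else float("nan")
        objects.append(NerveObject(pixels=coords, centroid=centroid, area=area, mean_rb=mean_rb))
    objects.sort(key=lambda o: (o.centroid[0], o.centroid[1]))
    return objects


def assign_and_measure(
    objects: list[NerveObject],
    annotation: ROIAnnotation,
    tissue_full: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
) -> list[ROIMeasurement]:
    """Assign each object to the ROI containing its centroid and measure
    per-ROI count, total object area and other-tissue area.

    Objects whose centroid falls outside every ROI are dropped (logged).
    Exactly four measurements are returned, zero-filled for empty ROIs.
    Other tissue = tissue inside the ROI minus object pixels minus excluded
    near-white pixels.
    """
    tissue = np.asarray(tissue_full, bool)
    h, w = annotation.shape
    object_pixel_mask = np.zeros((h, w), bool)
    dropped = 0
    for obj in objects:
        r = min(max(int(round(obj.centroid[0])), 0), h - 1)
        c = min(max(int(round(obj.centroid[1])), 0), w - 1)
        obj.roi = int(annotation.labels[r, c])
        if obj.roi == 0:
            dropped += 1
        else:
            object_pixel_mask[obj.pixels[:, 0], obj.pixels[:, 1]] = True
    if dropped:
        logger.info("dropped %d objects with centroid outside all ROIs", dropped)
    excl = np.zeros((h, w), bool) if exclusion_mask is None else np.asarray(exclusion_mask, bool)
    measurements = []
    for label in ROI_LABELS:
        members = [o for o in objects if o.roi == label]
        roi_tissue = tissue & (annotation.labels == label)
        # Area accounting is per-ROI: only the member pixels inside this ROI
        # count, so object area + other-tissue area never exceeds ROI tissue.
        obj_area = int(np.sum(roi_tissue & object_pixel_mask))
        other = int(np.sum(roi_tissue & ~object_pixel_mask & ~excl))
        measurements.append(
            ROIMeasurement(
                roi=label,
                count=len(members),
                object_area_px2=obj_area,
                other_tissue_area_px2=other,
                mean_object_area_px2=float(obj_area / len(members)) if members else 0.0,
            )
        )
    return measurements
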