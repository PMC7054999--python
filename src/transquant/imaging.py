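"""Single-cell puromycin quantification and lane densitometry.

Puromycin incorporated into nascent polypeptides during a short pulse is
detected by immunofluorescence, so the mean anti-puromycin intensity of a
cell reports its protein-synthesis rate.  Cells are segmented in two steps:
nuclei from the Hoechst channel (global threshold, connected components, size
filter) and cell bodies by growing each nucleus seed into the eIF3B-positive
cytoplasmic mask, each foreground pixel going to its nearest seed.  Per-ROI
mean puromycin intensities are averaged per condition and expressed relative
to the control-condition mean.

For Western blots, the puromycin signal integrated along an entire lane is
normalized to the integrated Ponceau (total protein) stain of the same lane
and expressed relative to a control lane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential

__all__ = [
    "segment_nuclei",
    "grow_cells",
    "roi_means",
    "measure_and_normalize",
    "lane_densitometry",
    "LaneDensitometry",
]


def segment_nuclei(hoechst: np.ndarray, min_area: int = 20,
                   threshold: Literal["otsu"] | float = "otsu") -> np.ndarray:
    """Label nuclei in the Hoechst channel.

    Global threshold (Otsu or a fixed value), 8-connected components, and a
    minimum-area filter.  Labels are renumbered in raster order of their first
    pixel so the labeling is deterministic.  An empty foreground yields an
    all-zero label image, not an error.  Touching nuclei merge into one
    component; this is a documented limitation of global thresholding.
    """
    img = np.asarray(hoechst, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if threshold == "otsu":
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    labels = cc_label(mask, connectivity=2)
    # size filter
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_area)
    keep = keep[keep != 0]
    filtered = np.where(np.isin(labels, keep), labels, 0)
    # raster-order relabeling: cc_label already scans in raster order, but
    # renumber after filtering to keep labels consecutive
    relabeled, _, _ = relabel_sequential(filtered)
    return relabeled.astype(np.int32)


def grow_cells(nuclei: np.ndarray, eif3b: np.ndarray,
               threshold: Literal["otsu"] | float = "otsu",
               exclude_border: bool = True) -> np.ndarray:
    """Grow cell ROIs from nucleus seeds inside the eIF3B foreground.

    Every eIF3B-foreground pixel is assigned to the nucleus with the nearest
    nucleus pixel (Euclidean distance transform); nucleus pixels keep their
    own label even outside the cytoplasmic mask, so each ROI contains exactly
    one nucleus and ROIs are pairwise disjoint.  Cells touching the image
    border are dropped by default.
    """
    nuclei = np.asarray(nuclei)
    img = np.asarray(eif3b, dtype=float)
    if nuclei.shape != img.shape:
        raise ValueError("nuclei and eIF3B images must share a shape")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32)
    if threshold == "otsu":
        thr = threshold_otsu(img) if img.max() > img.min() else np.inf
    else:
        thr = float(threshold)
    foreground = img > thr
    # nearest nucleus pixel for every image pixel
    _, (inds_r, inds_c) = ndimage.distance_transform_edt(
        nuclei == 0, return_indices=True)
    nearest = nuclei[inds_r, inds_c]
    rois = np.where(foreground | (nuclei > 0), nearest, 0).astype(np.int32)
    if exclude_border:
        border_labels = np.unique(np.concatenate(
            [rois[0, :], rois[-1, :], rois[:, 0], rois[:, -1]]))
        rois[np.isin(rois, border_labels[border_labels != 0])] = 0
    return rois


def roi_means(rois: np.ndarray, intensity: np.ndarray) -> pd.Series:
    """Mean intensity per ROI label (index = label id)."""
    labels = np.unique(rois)
    labels = labels[labels != 0]
    if labels.size == 0:
        return pd.Series(dtype=float)
    means = ndimage.mean(np.asarray(intensity, dtype=float), labels=rois,
                         index=labels)
    return pd.Series(means, index=labels, name="mean_intensity")


@dataclass(frozen=True)
class IntensityResult:
    """Per-ROI and per-condition puromycin intensities relative to control."""

    per_roi: pd.DataFrame  # condition, roi_label, mean_intensity, normalized
    condition_means: pd.Series
    normalized_means: pd.Series
    control: str


def measure_and_normalize(rois_by_condition: Mapping[str, Sequence[np.ndarray]],
                          puromycin_by_condition: Mapping[str, Sequence[np.ndarray]],
                          control: str) -> IntensityResult:
    """Per-ROI mean puromycin intensities normalized to the control mean.

    ``rois_by_condition`` and ``puromycin_by_condition`` map condition name to
    parallel lists of label images and puromycin channels (one pair per field
    of view).  Per-ROI normalized values are retained so population dispersion
    can be reported alongside the condition means.
    """
    if control not in rois_by_condition:
        raise ValueError(f"control condition {control!r} missing")
    records = []
    for cond, roi_imgs in rois_by_condition.items():
        puro_imgs = puromycin_by_condition[cond]
        if len(roi_imgs) != len(puro_imgs):
            raise ValueError(f"condition {cond!r}: unequal image counts")
        for fov, (rois, puro) in enumerate(zip(roi_imgs, puro_imgs)):
            for lab, m in roi_means(rois, puro).items():
                records.append((cond, fov, int(lab), float(m)))
    per_roi = pd.DataFrame(records, columns=["condition", "fov", "roi_label",
                                             "mean_intensity"])
    control_rois = per_roi[per_roi["condition"] == control]
    if control_rois.empty:
        raise ValueError("control condition has no ROIs; cannot normalize")
    cond_means = per_roi.groupby("condition")["mean_intensity"].mean()
    control_mean = float(cond_means[control])
    per_roi["normalized"] = per_roi["mean_intensity"] / control_mean
    return IntensityResult(per_roi, cond_means, cond_means / control_mean, control)


@dataclass(frozen=True)
class LaneDensitometry:
    signal_integral: float
    loading_integral: float
    normalized: float
    relative_to_control: float | None = None


def lane_densitometry(signal: Sequence[float], loading: Sequence[float],
                      control: LaneDensitometry | None = None) -> LaneDensitometry:
    """Integrate a lane profile and normalize to its loading (Ponceau) profile.

    Trapezoid integrals over the full lane; the normalized value is
    signal/loading, optionally expressed relative to a control lane's
    normalized value.
    """
    s = np.asarray(signal, dtype=float)
    l = np.asarray(loading, dtype=float)
    if s.shape != l.shape:
        raise ValueError("signal and loading profiles must have equal length")
    si = float(np.trapezoid(s))
    li = float(np.trapezoid(l))
    if li <= 0:
        raise ValueError("loading integral must be positive")
    norm = si / li
    rel = norm / control.normalized if control is not None else None
    return LaneDensitometry(si, li, norm, rel)
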