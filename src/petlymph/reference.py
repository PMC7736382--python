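"""Reference (ground-truth style) segmentation by SUV thresholding in template ROIs.

Disease is delineated the way the training labels were produced clinically:
inside each loosely drawn template ROI, the union of two thresholds —
SUV > 2.5 (absolute) and SUV >= 40% of the ROI's SUV_max (relative) — defines
the lesion boundary.  The absolute rule rescues small, low-uptake lesions
that the relative rule would miss next to a hot lesion in the same ROI.
One-voxel islands produced by thresholding are removed afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_model import CONNECTIVITY_26, Modality, Volume

__all__ = ["threshold_union", "remove_islands", "build_reference", "SUV_ABSOLUTE", "SUV_RELATIVE"]

#: Absolute SUV threshold (strict inequality), g/ml.
SUV_ABSOLUTE = 2.5
#: Relative threshold as a fraction of the per-ROI SUV_max (non-strict).
SUV_RELATIVE = 0.40


def threshold_union(
    pet: Volume,
    roi_mask: np.ndarray,
    suv_absolute: float = SUV_ABSOLUTE,
    suv_relative: float = SUV_RELATIVE,
) -> np.ndarray:
    """Union of the absolute and relative SUV thresholds inside one ROI.

    The relative cut uses SUV_max over the ROI and a non-strict inequality,
    so the maximum voxel itself is always selected; the absolute cut is
    strict (SUV > 2.5).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if pet.shape != roi_mask.shape:
        raise ValueError("PET and ROI grids differ")
    if not roi_mask.any():
        raise ValueError("empty template ROI")
    suv = pet.data
    roi_max = float(suv[roi_mask].max())
    selected = roi_mask & ((suv > suv_absolute) | (suv >= suv_relative * roi_max))
    return selected


def remove_islands(mask: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_size`` voxels.

    The default removes exactly the single-voxel islands that SUV
    thresholding tends to produce.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep)


def build_reference(pet: Volume, rois: Volume, min_island_size: int = 2) -> Volume:
    """Threshold-union every template ROI and merge into one binary mask.

    SUV_max for the relative rule is computed per ROI id.  Island removal is
    applied once after merging all ROI outputs.
    """
    if rois.modality is not Modality.LABEL:
        raise ValueError("template ROIs must be a LABEL volume")
    if pet.shape != rois.shape:
        raise ValueError("PET and ROI grids differ")
    ids = np.unique(rois.data)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("template ROI volume contains no regions")
    merged = np.zeros(pet.shape, dtype=bool)
    for roi_id in ids:
        merged |= threshold_union(pet, rois.data == roi_id)
    merged = remove_islands(merged, min_size=min_island_size)
    return Volume(
        data=merged.astype(np.int32),
        spacing=pet.spacing,
        origin=pet.origin,
        modality=Modality.LABEL,
    )
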