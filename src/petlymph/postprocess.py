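"""Ensemble post-processing of CNN probability maps.

Three independently initialized CNNs each propose a contour set.  Each set
is refined by re-applying the clinical thresholding scheme (union of
SUV > 2.5 and SUV >= 40% of the contour's SUV_max) inside every
26-connected contour; the voxelwise intersection of the three refined sets
is the ensemble output; finally, contours dominated by bone (CT HU > 150)
are excluded.  Requiring agreement of all three members is what suppresses
the isolated false positives (benign hot structures) that single networks
produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import CONNECTIVITY_26, Modality, Volume
from .reference import SUV_ABSOLUTE, SUV_RELATIVE

__all__ = [
    "EnsembleOutput",
    "refine_with_thresholds",
    "intersect_ensemble",
    "exclude_bone",
    "postprocess_ensemble",
    "BONE_HU",
]

#: CT threshold above which a voxel is treated as bone.
BONE_HU = 150.0


@dataclass
class EnsembleOutput:
    """Final mask plus the refined per-member masks and exclusion report."""

    member_masks: list  # refined binary masks, one per ensemble member
    final_mask: np.ndarray
    excluded_components: list = field(default_factory=list)  # (component id, reason)


def refine_with_thresholds(
    cnn_mask: np.ndarray,
    pet: Volume,
    suv_absolute: float = SUV_ABSOLUTE,
    suv_relative: float = SUV_RELATIVE,
) -> np.ndarray:
    """Re-threshold each connected CNN contour with the clinical scheme.

    Within each 26-connected component, keeps voxels with SUV > 2.5 or
    SUV >= 40% of the component's own SUV_max (so at least the component's
    hottest voxel always survives).
    """
    cnn_mask = np.asarray(cnn_mask, dtype=bool)
    if pet.shape != cnn_mask.shape:
        raise ValueError("mask and PET grids differ")
    if not cnn_mask.any():
        return cnn_mask.copy()
    labels, n = ndimage.label(cnn_mask, structure=CONNECTIVITY_26)
    suv = pet.data
    comp_max = ndimage.labeled_comprehension(
        suv, labels, np.arange(1, n + 1), np.max, float, 0.0
    )
    # per-voxel relative cut: 40% of the SUV_max of the voxel's component
    cuts = np.zeros(n + 1, dtype=np.float64)
    cuts[1:] = suv_relative * comp_max
    refined = cnn_mask & ((suv > suv_absolute) | (suv >= cuts[labels]))
    return refined


def intersect_ensemble(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise AND over the member masks."""
    if not masks:
        raise ValueError("no member masks")
    out = np.asarray(masks[0], dtype=bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("member mask grids differ")
        out &= m
    return out


def exclude_bone(
    mask: np.ndarray,
    ct: Volume,
    hu_cut: float = BONE_HU,
    bone_fraction: float = 0.5,
) -> tuple[np.ndarray, list]:
    """Remove contours dominated by bone.

    A 26-connected component is dropped when the fraction of its voxels
    with HU > ``hu_cut`` exceeds ``bone_fraction``.  ``bone_fraction=0``
    reproduces the any-voxel-of-bone reading.  Returns the filtered mask
    and a list of (component id, reason) exclusions.
    """
    mask = np.asarray(mask, dtype=bool)
    if ct.shape != mask.shape:
        raise ValueError("mask and CT grids differ")
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return mask.copy(), []
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    bone_counts = ndimage.sum_labels((ct.data > hu_cut).astype(np.float64), labels, index=idx)
    fractions = bone_counts / sizes
    drop = fractions > bone_fraction
    excluded = [
        (int(i), f"bone fraction {fractions[i - 1]:.2f} > {bone_fraction}")
        for i in idx[drop]
    ]
    keep_ids = idx[~drop]
    return np.isin(labels, keep_ids), excluded


def postprocess_ensemble(
    prob_maps: list[Volume],
    pet: Volume,
    ct: Volume,
    cut_point: float = 0.5,
    bone_fraction: float = 0.5,
    hu_cut: float = BONE_HU,
) -> EnsembleOutput:
    """Binarize, refine, intersect and bone-filter an ensemble's outputs.

    The pipeline order is fixed: per-member binarization at ``cut_point``
    and threshold refinement first, then the intersection across members,
    then bone exclusion on the final components.
    """
    if not prob_maps:
        raise ValueError("no probability maps")
    for p in prob_maps:
        if p.modality is not Modality.PROBABILITY:
            raise ValueError("expected PROBABILITY volumes")
        if p.shape != pet.shape or p.shape != ct.shape:
            raise ValueError("probability/PET/CT grids differ")
    if not 0.0 <= cut_point <= 1.0:
        raise ValueError("cut_point must lie in [0, 1]")
    members = [
        refine_with_thresholds(p.data >= cut_point, pet) for p in prob_maps
    ]
    final = intersect_ensemble(members)
    final, excluded = exclude_bone(final, ct, hu_cut=hu_cut, bone_fraction=bone_fraction)
    return EnsembleOutput(member_masks=members, final_mask=final, excluded_components=excluded)
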