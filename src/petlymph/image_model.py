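"""Volume data model, NIfTI I/O, SUV conversion, resampling and normalization.

All volumes are 3D scalar grids on axis-aligned world frames: the world
position of voxel index ``(i, j, k)`` is ``origin + index * spacing`` (mm).
Oblique or non-diagonal NIfTI affines are rejected rather than silently
reoriented.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "Volume",
    "ScanMeta",
    "CaseRecord",
    "read_volume",
    "write_volume",
    "compute_suv",
    "resample_isotropic",
    "body_mask",
    "normalize",
    "F18_HALF_LIFE_MIN",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: 3x3x3 structuring element giving 26-connectivity, used package-wide.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class Modality(str, Enum):
    PET_SUV = "PET_SUV"
    CT_HU = "CT_HU"
    PROBABILITY = "PROBABILITY"
    LABEL = "LABEL"


@dataclass
class Volume:
    """A 3D scalar grid with spacing/origin metadata.

    Parameters
    ----------
    data
        3D array. LABEL volumes must hold non-negative integers,
        PROBABILITY volumes values in [0, 1]; all values must be finite.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel (0, 0, 0).
    modality
        One of :class:`Modality`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.PET_SUV

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.modality = Modality(self.modality)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.modality is Modality.LABEL:
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.array_equal(self.data, np.round(self.data)):
                    raise ValueError("LABEL volume contains non-integer values")
                self.data = self.data.astype(np.int32)
            if self.data.min(initial=0) < 0:
                raise ValueError("LABEL volume contains negative values")
        elif self.modality is Modality.PROBABILITY:
            if self.data.min(initial=0.0) < 0.0 or self.data.max(initial=0.0) > 1.0:
                raise ValueError("PROBABILITY volume has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, modality: Optional[Modality] = None) -> "Volume":
        """New volume on the same grid with different voxel values."""
        return replace(self, data=data, modality=modality or self.modality)


@dataclass
class ScanMeta:
    """Injection metadata needed for body-weight SUV conversion."""

    injected_dose_bq: float
    body_weight_kg: float
    injection_to_scan_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.injection_to_scan_min < 0:
            raise ValueError("injection-to-scan time must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMeta":
        """Read the JSON sidecar {dose_MBq, weight_kg, post_injection_min}."""
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            injected_dose_bq=float(d["dose_MBq"]) * 1e6,
            body_weight_kg=float(d["weight_kg"]),
            injection_to_scan_min=float(d.get("post_injection_min", 0.0)),
        )


@dataclass
class CaseRecord:
    """One patient/phantom case: co-registered PET (SUV) and CT (HU)."""

    case_id: str
    pet: Volume
    ct: Volume
    reference_mask: Optional[Volume] = None
    template_rois: Optional[Volume] = None

    def __post_init__(self) -> None:
        if not self.pet.same_grid(self.ct):
            raise ValueError(f"case {self.case_id}: PET and CT grids differ")


# ---------------------------------------------------------------------------
# I/O


def _affine_to_grid(affine: np.ndarray) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4:
        raise ValueError("oblique/non-diagonal NIfTI affine is not supported")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError("NIfTI affine with non-positive axis scales is not supported")
    return tuple(float(d) for d in diag), tuple(float(o) for o in affine[:3, 3])


def _grid_to_affine(spacing, origin) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def read_volume(path: str | Path, modality: Modality | str) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Spacing and origin are taken from the (diagonal) affine; the array is
    validated against the requested modality's invariants.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    spacing, origin = _affine_to_grid(img.affine)
    modality = Modality(modality)
    if modality is Modality.LABEL:
        data = np.asarray(data)
        if not np.array_equal(data, np.round(data)):
            raise ValueError(f"{path}: LABEL volume contains non-integer values")
        data = data.astype(np.int32)
    else:
        data = np.asarray(data, dtype=np.float32)
    return Volume(data=data, spacing=spacing, origin=origin, modality=modality)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as NIfTI-1; lossless for label volumes."""
    if volume.modality is Modality.LABEL:
        data = volume.data.astype(np.int16 if volume.data.max(initial=0) < 2**15 else np.int32)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, _grid_to_affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# SUV conversion


def compute_suv(activity: Volume, meta: ScanMeta) -> Volume:
    """Body-weight SUV from an activity-concentration volume (Bq/ml).

    The injected dose is decay-corrected to scan time, so

        SUV = C / (dose * 2**(-t/T_half) / (weight_g))

    with C in Bq/ml and weight in grams.  A patient of uniform density
    with all activity retained would read SUV = 1 everywhere.
    """
    if np.any(activity.data < 0):
        raise ValueError("activity concentrations must be non-negative")
    dose_at_scan = meta.injected_dose_bq * math.pow(
        2.0, -meta.injection_to_scan_min / meta.half_life_min
    )
    suv = activity.data.astype(np.float64) * (meta.body_weight_kg * 1000.0) / dose_at_scan
    return Volume(
        data=suv.astype(np.float32),
        spacing=activity.spacing,
        origin=activity.origin,
        modality=Modality.PET_SUV,
    )


# ---------------------------------------------------------------------------
# Resampling


def resample_isotropic(volume: Volume, target_spacing: float, mode: str = "linear") -> Volume:
    """Resample to a cubic voxel grid (``target_spacing`` mm per axis).

    The output grid keeps the world origin; output size along each axis is
    ``ceil(extent / target)`` so the physical extent is preserved to within
    one voxel.  Values outside the input field of view are edge-extended.
    LABEL volumes must use nearest-neighbour interpolation and remain
    integer-valued.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if volume.modality is Modality.LABEL and mode == "linear":
        raise ValueError("LABEL volumes must be resampled with nearest-neighbour mode")

    t = float(target_spacing)
    out_shape = tuple(
        int(math.ceil(n * s / t)) for n, s in zip(volume.shape, volume.spacing)
    )
    # Output voxel i sits at world origin + i*t -> input index i*t/s per axis.
    coords = np.meshgrid(
        *[np.arange(n_out) * t / s for n_out, s in zip(out_shape, volume.spacing)],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        volume.data.astype(np.float32 if mode == "linear" else volume.data.dtype),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",
    ).reshape(out_shape)
    if volume.modality is Modality.LABEL:
        out = np.round(out).astype(np.int32)
    return Volume(data=out, spacing=(t, t, t), origin=volume.origin, modality=volume.modality)


# ---------------------------------------------------------------------------
# Body mask and normalization


def body_mask(ct: Volume) -> Volume:
    """Binary mask of the patient from CT.

    Thresholds at HU > -500 (excludes air, keeps lung), keeps the largest
    26-connected component, and fills internal holes.
    """
    if ct.modality is not Modality.CT_HU:
        raise ValueError("body_mask expects a CT volume in HU")
    thresh = ct.data > -500
    if not thresh.any():
        raise ValueError("CT contains no voxels above -500 HU; unusable scan")
    labels, n = ndimage.label(thresh, structure=CONNECTIVITY_26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        comp = labels == largest
    else:
        comp = thresh
    filled = ndimage.binary_fill_holes(comp)
    return Volume(
        data=filled.astype(np.int32), spacing=ct.spacing, origin=ct.origin, modality=Modality.LABEL
    )


def normalize(volume: Volume, mask: Volume) -> Volume:
    """Z-score the whole grid using mean/variance computed inside ``mask``.

    Population statistics are used, so re-applying the transform is the
    identity up to float error.
    """
    if mask.modality is not Modality.LABEL:
        raise ValueError("mask must be a LABEL volume")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    sel = mask.data > 0
    if not sel.any():
        raise ValueError("empty normalization mask")
    vals = volume.data[sel].astype(np.float64)
    mu = vals.mean()
    sigma = vals.std()  # population std
    if sigma == 0:
        raise ValueError("zero variance inside mask; cannot normalize")
    out = ((volume.data.astype(np.float64) - mu) / sigma).astype(np.float32)
    return Volume(
        data=out, spacing=volume.spacing, origin=volume.origin, modality=volume.modality
    )
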