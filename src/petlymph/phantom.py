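"""Synthetic PET/CT phantoms with multi-lesion FDG-avid disease.

Each phantom is a soft-tissue body ellipsoid in air on a 2 mm isotropic
grid, carrying:

* ellipsoidal lesions with uniform uptake (SUV 3-15) on a low uniform
  background (SUV 0.5-1.5), never planted inside bone or benign structures;
* small benign hot structures (salivary-gland / tonsil / ureter analogues,
  SUV 2.5-8) placed away from disease, which act as false-positive bait;
* bone (HU 400 by default) as a spine-like cylinder;
* Gaussian point-spread blur (FWHM 6 mm by default) followed by additive
  Gaussian noise in SUV units on PET, and mild noise on CT.

Template ROIs are dilated bounding boxes around each lesion cluster,
mimicking loose physician-placed regions.  Everything is deterministic
given the seed.  The planted geometry (pre-blur masks, volumes, uptake) is
returned as ground truth so downstream metrics have exact oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .features import FeatureSet, extract_features
from .image_model import CaseRecord, Modality, Volume, write_volume
from .reference import build_reference

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "generate_cohort"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomConfig:
    """Generation parameters; defaults emulate the target disease setting."""

    grid_size: int = 64
    spacing_mm: float = 2.0
    n_lesions: tuple[int, int] = (2, 5)
    lesion_radius_mm: tuple[float, float] = (4.0, 12.0)
    lesion_suv: tuple[float, float] = (3.0, 15.0)
    background_suv: tuple[float, float] = (0.5, 1.5)
    n_benign_hot: tuple[int, int] = (1, 3)
    benign_radius_mm: tuple[float, float] = (3.0, 5.0)
    benign_suv: tuple[float, float] = (2.5, 8.0)
    bone_structures: int = 1
    bone_hu: float = 400.0
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    psf_fwhm_mm: float = 6.0
    noise_sigma_suv: float = 0.2
    ct_noise_hu: float = 5.0
    roi_margin_voxels: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)


@dataclass
class PhantomTruth:
    """Planted geometry and the exact features it implies."""

    lesion_masks: list
    merged_mask: np.ndarray
    benign_mask: np.ndarray
    bone_mask: np.ndarray
    lesions: list  # dicts: suv, semi_axes_mm, center_mm, volume_cm3, n_voxels
    background_suv: float
    features: FeatureSet
    pre_blur_pet: Volume

    def to_json_dict(self) -> dict:
        return {
            "lesions": self.lesions,
            "background_suv": self.background_suv,
            "features": self.features.to_dict(),
        }


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid in voxel units."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _sample_range(rng, lo_hi) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def _sample_count(rng, lo_hi) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def generate_phantom(
    config: PhantomConfig, seed: Optional[int] = None
) -> tuple[CaseRecord, PhantomTruth]:
    """Build one phantom case (PET, CT, template ROIs, reference mask).

    The reference mask is derived from the *observed* (blurred, noisy) PET
    through the same thresholding protocol used for real labels, while the
    returned truth records the planted (pre-blur) geometry.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.grid_size
    shape = (n, n, n)
    sp = config.spacing_mm
    spacing = (sp, sp, sp)
    center = np.array([(n - 1) / 2.0] * 3)

    # --- anatomy -----------------------------------------------------------
    body_semi = np.array([0.40 * n, 0.40 * n, 0.47 * n])
    body = _ellipsoid(shape, center, body_semi)

    bone = np.zeros(shape, dtype=bool)
    for b in range(config.bone_structures):
        # spine-like cylinder: offset along x, spanning most of z
        off = np.array([0.22 * n * (1 if b % 2 == 0 else -1), 0.0, 0.0])
        r_vox = 3.5 / sp * 2.0  # ~7 mm radius
        gx, gy = np.ogrid[0:n, 0:n]
        disc = ((gx - (center[0] + off[0])) ** 2 + (gy - (center[1] + off[1])) ** 2) <= r_vox**2
        cyl = np.repeat(disc[:, :, None], n, axis=2)
        zlo, zhi = int(0.15 * n), int(0.85 * n)
        cyl[:, :, :zlo] = False
        cyl[:, :, zhi:] = False
        bone |= cyl & body

    # --- lesions -----------------------------------------------------------
    n_lesions = _sample_count(rng, config.n_lesions)
    forbidden = ndimage.binary_dilation(bone, iterations=2)
    lesion_masks: list[np.ndarray] = []
    lesion_info: list[dict] = []
    merged = np.zeros(shape, dtype=bool)
    vox_cm3 = sp**3 / 1000.0
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(300):
            semi_mm = np.array([_sample_range(rng, config.lesion_radius_mm) for _ in range(3)])
            semi_vox = semi_mm / sp
            c = center + (rng.uniform(-1, 1, size=3) * (body_semi - semi_vox - 2))
            mask = _ellipsoid(shape, c, semi_vox)
            if not mask.any():
                continue
            inside = mask & body
            if inside.sum() != mask.sum():
                continue
            if (mask & forbidden).any() or (ndimage.binary_dilation(mask, iterations=2) & merged).any():
                continue
            suv = _sample_range(rng, config.lesion_suv)
            lesion_masks.append(mask)
            lesion_info.append(
                {
                    "suv": suv,
                    "semi_axes_mm": semi_mm.tolist(),
                    "center_mm": (c * sp).tolist(),
                    "n_voxels": int(mask.sum()),
                    "volume_cm3": float(mask.sum()) * vox_cm3,
                }
            )
            merged |= mask
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a lesion after 300 attempts")

    # --- template ROIs: dilated bounding boxes, merged when overlapping ----
    m = config.roi_margin_voxels
    boxes = []
    for mask in lesion_masks:
        idx = np.argwhere(mask)
        lo = np.maximum(idx.min(axis=0) - m, 0)
        hi = np.minimum(idx.max(axis=0) + m + 1, n)
        boxes.append((lo, hi))
    # union-find over overlapping boxes -> lesion clusters share one ROI id
    parent = list(range(len(boxes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            (lo_i, hi_i), (lo_j, hi_j) = boxes[i], boxes[j]
            if np.all(lo_i < hi_j) and np.all(lo_j < hi_i):
                parent[find(i)] = find(j)
    rois = np.zeros(shape, dtype=np.int32)
    roi_ids = {}
    for i, (lo, hi) in enumerate(boxes):
        root = find(i)
        roi_id = roi_ids.setdefault(root, len(roi_ids) + 1)
        rois[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = roi_id
    roi_region = rois > 0

    # --- benign hot structures: outside every template ROI -----------------
    n_benign = _sample_count(rng, config.n_benign_hot)
    benign = np.zeros(shape, dtype=bool)
    benign_block = ndimage.binary_dilation(roi_region, iterations=2) | forbidden
    for _ in range(n_benign):
        for _attempt in range(300):
            semi_vox = np.array(
                [_sample_range(rng, config.benign_radius_mm) for _ in range(3)]
            ) / sp
            c = center + (rng.uniform(-1, 1, size=3) * (body_semi - semi_vox - 2))
            mask = _ellipsoid(shape, c, semi_vox)
            if not mask.any() or (mask & ~body).any():
                continue
            if (mask & benign_block).any() or (mask & benign).any():
                continue
            benign |= mask
            break
        # silently skip a benign structure that cannot be placed

    # --- PET ---------------------------------------------------------------
    background = _sample_range(rng, config.background_suv)
    pet_clean = np.zeros(shape, dtype=np.float64)
    pet_clean[body] = background
    if benign.any():
        pet_clean[benign] = rng.uniform(*config.benign_suv, size=int(benign.sum()))
    for mask, info in zip(lesion_masks, lesion_info):
        pet_clean[mask] = info["suv"]
    pre_blur = Volume(
        data=pet_clean.astype(np.float32), spacing=spacing, modality=Modality.PET_SUV
    )
    pet_data = pet_clean.copy()
    if config.psf_fwhm_mm > 0:
        sigma_vox = config.psf_fwhm_mm * _FWHM_TO_SIGMA / sp
        pet_data = ndimage.gaussian_filter(pet_data, sigma=sigma_vox)
    if config.noise_sigma_suv > 0:
        pet_data = pet_data + rng.normal(0.0, config.noise_sigma_suv, size=shape)
    pet_data = np.clip(pet_data, 0.0, None)
    pet = Volume(data=pet_data.astype(np.float32), spacing=spacing, modality=Modality.PET_SUV)

    # --- CT ----------------------------------------------------------------
    ct_data = np.full(shape, config.air_hu, dtype=np.float64)
    ct_data[body] = config.soft_tissue_hu
    ct_data[bone] = config.bone_hu
    if config.ct_noise_hu > 0:
        ct_data = ct_data + rng.normal(0.0, config.ct_noise_hu, size=shape)
    ct = Volume(data=ct_data.astype(np.float32), spacing=spacing, modality=Modality.CT_HU)

    roi_volume = Volume(data=rois, spacing=spacing, modality=Modality.LABEL)
    reference = build_reference(pet, roi_volume)

    truth = PhantomTruth(
        lesion_masks=lesion_masks,
        merged_mask=merged,
        benign_mask=benign,
        bone_mask=bone,
        lesions=lesion_info,
        background_suv=background,
        features=extract_features(pre_blur, merged),
        pre_blur_pet=pre_blur,
    )
    case = CaseRecord(
        case_id=f"phantom_{config.seed if seed is None else seed:08d}",
        pet=pet,
        ct=ct,
        reference_mask=reference,
        template_rois=roi_volume,
    )
    return case, truth


def case_seeds(master_seed: int, n: int) -> list[int]:
    """Stable per-case seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_cohort(
    n: int,
    config: PhantomConfig,
    seed: int,
    out_dir: Optional[str | Path] = None,
) -> list[tuple[CaseRecord, PhantomTruth]]:
    """Generate ``n`` phantoms with per-case seeds derived from ``seed``.

    With ``out_dir`` set, writes the on-disk cohort layout
    ``case_XXXX/{pet,ct,reference,rois}.nii.gz`` plus ``truth.json``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out = []
    for i, s in enumerate(case_seeds(seed, n)):
        case, truth = generate_phantom(config, seed=s)
        case.case_id = f"case_{i:04d}"
        out.append((case, truth))
        if out_dir is not None:
            d = Path(out_dir) / case.case_id
            d.mkdir(parents=True, exist_ok=True)
            write_volume(case.pet, d / "pet.nii.gz")
            write_volume(case.ct, d / "ct.nii.gz")
            write_volume(case.reference_mask, d / "reference.nii.gz")
            write_volume(case.template_rois, d / "rois.nii.gz")
            with open(d / "truth.json", "w") as fh:
                json.dump({"seed": s, **truth.to_json_dict()}, fh, indent=1)
    return out
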