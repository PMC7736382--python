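"""Desk-scale reproduction experiments on synthetic phantoms.

The full clinical workflow (ensembles of large networks, 5-fold
cross-validation over 100 patients, GPU training) does not fit a single
CPU; this module runs the same pipeline end-to-end at a reduced scale — a
small multi-resolution network, a 64^3 phantom cohort, a single
train/validation/test split — so that segmentation and feature-agreement
behaviour can be measured quickly and reproducibly.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .evaluation import pearson_r, rpd, score_segmentation
from .features import extract_features
from .network import NetworkConfig, predict_probability, prepare_case, train
from .phantom import PhantomConfig, generate_cohort
from .postprocess import postprocess_ensemble

__all__ = ["tiny_ensemble_config", "scaled_learning_experiment"]


def tiny_ensemble_config(seed: int = 0, **overrides) -> NetworkConfig:
    """A two-pathway network small enough to train on one CPU in ~1 min."""
    defaults = dict(
        n_pathways=2,
        downsample_factors=(1, 3),
        conv_features=(8, 8, 12, 12, 12, 12, 16, 16),
        fc_features=32,
        patch_size=25,
        epochs=8,
        batches_per_epoch=8,
        batch_size=8,
        learning_rate=1e-3,
        seed=seed,
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


def scaled_learning_experiment(
    seed: int,
    n_train: int = 20,
    n_test: int = 5,
    n_members: int = 3,
    n_val: int = 2,
    phantom_config: Optional[PhantomConfig] = None,
    network_config: Optional[NetworkConfig] = None,
    cut_point: float = 0.5,
) -> dict:
    """Train a small ensemble on noisy phantoms and score held-out cases.

    ``n_train`` phantoms are used for training (the last ``n_val`` of them
    as a validation split for model selection), ``n_test`` for held-out
    evaluation.  All randomness (phantom cohort, member initialization,
    patch sampling) derives from ``seed``.  Returns per-case scores,
    false-positive volumes for the ensemble and each member, and
    feature-agreement summaries between automated and reference masks.
    """
    phantom_config = phantom_config or PhantomConfig()
    base_net = network_config or tiny_ensemble_config()
    ss = np.random.SeedSequence([int(seed), 11])
    cohort_seed, member_root = (int(s) % 2**31 for s in ss.generate_state(2))
    cohort = generate_cohort(n_train + n_test, phantom_config, seed=cohort_seed)
    prepared = [prepare_case(c) for c, _ in cohort]
    prep_train = prepared[: n_train - n_val]
    prep_val = prepared[n_train - n_val : n_train]
    prep_test = prepared[n_train:]

    member_seeds = [
        int(s) % 2**31 for s in np.random.SeedSequence(member_root).generate_state(n_members)
    ]
    models = []
    histories = []
    for s in member_seeds:
        model, hist = train(
            prep_train, dataclasses.replace(base_net, seed=s), val_cases=prep_val
        )
        models.append(model)
        histories.append(hist)

    voxel_cm3 = float(np.prod(phantom_config.spacing_mm**3)) / 1000.0
    per_case = []
    auto_feats, ref_feats = [], []
    for pc in prep_test:
        case = pc.case
        pet_n = case.pet.with_data(pc.net_input[..., 0])
        ct_n = case.ct.with_data(pc.net_input[..., 1])
        probs = [predict_probability(m, pet_n, ct_n, body=pc.body) for m in models]
        out = postprocess_ensemble(probs, case.pet, case.ct, cut_point=cut_point)
        ref = case.reference_mask.data.astype(bool)
        sc = score_segmentation(out.final_mask, ref)
        member_fp = [score_segmentation(mm, ref).fp for mm in out.member_masks]
        per_case.append(
            {
                "case_id": case.case_id,
                "dsc": sc.dsc,
                "sensitivity": sc.sensitivity,
                "ppv": sc.ppv,
                "fp_cm3": sc.fp * voxel_cm3,
                "member_fp_cm3": [f * voxel_cm3 for f in member_fp],
            }
        )
        auto_feats.append(extract_features(case.pet, out.final_mask))
        ref_feats.append(extract_features(case.pet, ref))

    def _col(feats, attr):
        return np.array(
            [np.nan if getattr(f, attr) is None else getattr(f, attr) for f in feats]
        )

    summary = {
        "median_dsc": float(np.median([r["dsc"] for r in per_case])),
        "median_sensitivity": float(np.median([r["sensitivity"] for r in per_case])),
        "median_ppv": float(np.median([r["ppv"] for r in per_case])),
        "fp_median_ensemble_cm3": float(np.median([r["fp_cm3"] for r in per_case])),
        "fp_median_members_cm3": float(
            np.median([f for r in per_case for f in r["member_fp_cm3"]])
        ),
    }
    a_suv, r_suv = _col(auto_feats, "suv_max"), _col(ref_feats, "suv_max")
    summary["suvmax_exact_fraction"] = float(
        np.mean(np.isclose(a_suv, r_suv, rtol=1e-6, atol=0.0))
    )
    for attr, key in (("mtv_cm3", "mtv"), ("tlg", "tlg")):
        a, r = _col(auto_feats, attr), _col(ref_feats, attr)
        summary[f"{key}_rpd_median_pct"] = float(
            np.median([rpd(x, y) for x, y in zip(a, r) if y != 0])
        )
        if len(a) >= 3 and np.std(a) > 0 and np.std(r) > 0:
            summary[f"{key}_pearson_r"] = pearson_r(a, r)

    return {
        "seed": seed,
        "n_train": n_train,
        "n_test": n_test,
        "member_seeds": member_seeds,
        "final_train_losses": [h["train_loss"][-1] for h in histories],
        "per_case": per_case,
        "summary": summary,
    }
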