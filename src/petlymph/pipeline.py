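"""End-to-end workflow: cross-validated ensemble training and evaluation.

Cases are randomly partitioned into near-equal folds.  For each fold, the
held-out cases are predicted by an ensemble of networks trained (from
different random initializations) on the remaining cases, which are
themselves split into training and validation sets at a 7:1 ratio; the
validation set drives model selection (best validation loss).  Held-out
probability maps are post-processed into the final ensemble mask, the
five PET metrics are extracted from both automated and reference masks,
and the cohort report aggregates segmentation scores, feature agreement
and subgroup statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import score_segmentation, subgroup_analysis, summarize_agreement
from .features import extract_features
from .image_model import CaseRecord, Modality, Volume, read_volume, write_volume
from .network import NetworkConfig, binarize, predict_probability, prepare_case, train
from .postprocess import postprocess_ensemble

__all__ = ["RunConfig", "split_folds", "load_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    network: NetworkConfig = field(default_factory=NetworkConfig)
    cut_point: float = 0.5
    ensemble_size: int = 3
    n_folds: int = 5
    seed: int = 0
    bone_fraction: float = 0.5
    train_val_ratio: float = 7.0
    write_masks: bool = True

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "network" in d:
            d["network"] = NetworkConfig.from_dict(d["network"])
        return cls(**d)


def split_folds(case_ids: list, n_folds: int, seed: int) -> list[list]:
    """Random partition into ``n_folds`` folds with sizes differing by <= 1."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(case_ids):
        raise ValueError("more folds than cases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    folds: list[list] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(case_ids[idx])
    return folds


def load_cohort(cohort_dir: str | Path) -> list[CaseRecord]:
    """Read the on-disk cohort layout written by :func:`phantom.generate_cohort`."""
    cohort_dir = Path(cohort_dir)
    cases = []
    for d in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        pet = read_volume(d / "pet.nii.gz", Modality.PET_SUV)
        ct = read_volume(d / "ct.nii.gz", Modality.CT_HU)
        ref = rois = None
        if (d / "reference.nii.gz").exists():
            ref = read_volume(d / "reference.nii.gz", Modality.LABEL)
        if (d / "rois.nii.gz").exists():
            rois = read_volume(d / "rois.nii.gz", Modality.LABEL)
        cases.append(
            CaseRecord(case_id=d.name, pet=pet, ct=ct, reference_mask=ref, template_rois=rois)
        )
    if not cases:
        raise FileNotFoundError(f"no case directories found under {cohort_dir}")
    return cases


def _member_seeds(master_seed: int, fold: int, n_members: int) -> list[int]:
    ss = np.random.SeedSequence([master_seed, fold])
    return [int(s) % (2**31) for s in ss.generate_state(n_members)]


def _feature_row(case_id: str, source: str, fs) -> dict:
    return {
        "case_id": case_id,
        "suv_max": fs.suv_max,
        "mtv_cm3": fs.mtv_cm3,
        "tlg": fs.tlg,
        "sa_cm2": fs.sa_cm2,
        "sa_mtv_cm1": fs.sa_mtv_cm1,
        "dmax_cm": fs.dmax_cm,
        "n_lesions": fs.n_lesions,
        "source": source,
    }


def run_pipeline(config: RunConfig, cases: Optional[list[CaseRecord]] = None) -> dict:
    """Run the full cross-validated workflow and write the report.

    Returns the report dictionary; also writes ``report.json`` and
    ``features.csv`` (and, with ``write_masks``, per-case mask volumes)
    under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cases is None:
        cases = load_cohort(config.cohort_dir)
    for c in cases:
        if c.reference_mask is None:
            raise ValueError(f"case {c.case_id} has no reference mask")
    by_id = {c.case_id: c for c in cases}
    prepared = {c.case_id: prepare_case(c) for c in cases}
    folds = split_folds(sorted(by_id), config.n_folds, config.seed)

    per_case_rows = []
    feature_rows = []
    run_log = {"folds": [], "config": {
        "cut_point": config.cut_point,
        "ensemble_size": config.ensemble_size,
        "n_folds": config.n_folds,
        "seed": config.seed,
        "bone_fraction": config.bone_fraction,
        "network": config.network.to_dict(),
    }}

    for fold_i, test_ids in enumerate(folds):
        rest = [cid for cid in sorted(by_id) if cid not in test_ids]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77, fold_i]))
        rest = list(rng.permutation(rest))
        n_val = max(1, int(round(len(rest) / (config.train_val_ratio + 1.0))))
        val_ids, train_ids = rest[:n_val], rest[n_val:]
        if not train_ids:
            train_ids, val_ids = rest, []

        seeds = _member_seeds(config.seed, fold_i, config.ensemble_size)
        models = []
        histories = []
        for s in seeds:
            cfg = dataclasses.replace(config.network, seed=s)
            model, hist = train(
                [prepared[c] for c in train_ids],
                cfg,
                val_cases=[prepared[c] for c in val_ids] or None,
            )
            models.append(model)
            histories.append(hist)
        run_log["folds"].append(
            {
                "fold": fold_i,
                "test": list(test_ids),
                "train": train_ids,
                "val": val_ids,
                "member_seeds": seeds,
                "final_train_loss": [h["train_loss"][-1] for h in histories],
            }
        )

        for cid in test_ids:
            pc = prepared[cid]
            case = by_id[cid]
            pet_n = case.pet.with_data(pc.net_input[..., 0])
            ct_n = case.ct.with_data(pc.net_input[..., 1], modality=Modality.CT_HU)
            probs = [
                predict_probability(m, pet_n, ct_n, body=pc.body) for m in models
            ]
            out = postprocess_ensemble(
                probs,
                case.pet,
                case.ct,
                cut_point=config.cut_point,
                bone_fraction=config.bone_fraction,
            )
            ref = case.reference_mask.data.astype(bool)
            sc = score_segmentation(out.final_mask, ref)
            per_case_rows.append(
                {
                    "case_id": cid,
                    "fold": fold_i,
                    "dsc": sc.dsc,
                    "sensitivity": sc.sensitivity,
                    "ppv": sc.ppv,
                    "tp": sc.tp,
                    "fp": sc.fp,
                    "fn": sc.fn,
                }
            )
            feature_rows.append(_feature_row(cid, "automated", extract_features(case.pet, out.final_mask)))
            feature_rows.append(_feature_row(cid, "reference", extract_features(case.pet, ref)))
            if config.write_masks:
                d = out_dir / "masks" / cid
                d.mkdir(parents=True, exist_ok=True)
                write_volume(
                    Volume(out.final_mask.astype(np.int32), case.pet.spacing, case.pet.origin, Modality.LABEL),
                    d / "final.nii.gz",
                )
                for i, (p, mm) in enumerate(zip(probs, out.member_masks)):
                    write_volume(p, d / f"prob_{i}.nii.gz")
                    write_volume(
                        Volume(mm.astype(np.int32), case.pet.spacing, case.pet.origin, Modality.LABEL),
                        d / f"member_{i}.nii.gz",
                    )

    features = pd.DataFrame(feature_rows)
    scores = pd.DataFrame(per_case_rows)
    auto = features[features.source == "automated"].set_index("case_id")
    ref = features[features.source == "reference"].set_index("case_id")
    agreement = {}
    for feat in ["suv_max", "mtv_cm3", "tlg", "sa_mtv_cm1", "dmax_cm"]:
        agreement[feat] = dataclasses.asdict(
            summarize_agreement(
                auto[feat].astype(float),
                ref[feat].astype(float),
                feature=feat,
                exact_match=(feat == "suv_max"),
            )
        )

    subgroups = {}
    sub_table = scores.set_index("case_id").join(
        ref[["mtv_cm3", "sa_mtv_cm1", "dmax_cm"]]
    )
    sub_table["mtv_rpd"] = 100.0 * (auto["mtv_cm3"] - ref["mtv_cm3"]) / ref["mtv_cm3"]
    for feat in ["mtv_cm3", "sa_mtv_cm1", "dmax_cm"]:
        try:
            res = subgroup_analysis(sub_table, dichotomize_by=feat)
            subgroups[feat] = dataclasses.asdict(res)
        except (ValueError, KeyError):
            subgroups[feat] = None

    report = {
        "n_cases": len(cases),
        "single_cnn_mode": config.ensemble_size == 1,
        "per_case": per_case_rows,
        "score_summary": {
            k: {
                "median": float(scores[k].median()),
                "iqr": [float(scores[k].quantile(0.25)), float(scores[k].quantile(0.75))],
            }
            for k in ["dsc", "sensitivity", "ppv"]
        },
        "agreement": agreement,
        "subgroups": subgroups,
        "run_log": run_log,
    }
    features.to_csv(out_dir / "features.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
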