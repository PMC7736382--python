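"""Segmentation scoring and feature-agreement statistics.

Per-case segmentation quality is summarized by voxelwise sensitivity,
positive predictive value (PPV) and Dice similarity coefficient (DSC).
Agreement between automatically and reference-extracted features is
summarized by Pearson's r and by the median/IQR of relative percent
differences (RPD); SUV_max additionally by the count of exact matches.
Subgroup analysis dichotomizes the cohort at the median of a feature and
compares DSC and |RPD of MTV| between groups with two-sided Wilcoxon
rank-sum tests (exact distribution for small tie-free samples, normal
approximation with tie correction otherwise).

Quantiles throughout use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegmentationScore",
    "AgreementSummary",
    "SubgroupResult",
    "score_segmentation",
    "pearson_r",
    "rpd",
    "summarize_agreement",
    "subgroup_analysis",
    "threshold_sweep",
    "wilcoxon_rank_sum",
]


@dataclass
class SegmentationScore:
    tp: int
    fp: int
    fn: int
    dsc: Optional[float]
    sensitivity: Optional[float]
    ppv: Optional[float]
    defined: bool = True


@dataclass
class AgreementSummary:
    feature: str
    pearson_r: Optional[float]
    rpd_median: Optional[float]
    rpd_iqr: Optional[tuple]
    n: int
    n_exact_matches: Optional[int] = None


@dataclass
class SubgroupResult:
    dichotomizing_feature: str
    cut_value: float
    group_low: dict
    group_high: dict
    wilcoxon_p: dict = field(default_factory=dict)


def score_segmentation(pred: np.ndarray, ref: np.ndarray) -> SegmentationScore:
    """Voxelwise TP/FP/FN and derived DSC, sensitivity and PPV."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference grids differ")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    if tp + fp + fn == 0:
        return SegmentationScore(0, 0, 0, None, None, None, defined=False)
    dsc = 2.0 * tp / (2.0 * tp + fp + fn)
    sens = tp / (tp + fn) if tp + fn else None
    ppv = tp / (tp + fp) if tp + fp else None
    return SegmentationScore(tp, fp, fn, dsc, sens, ppv)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Sample Pearson product-moment correlation; None if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def rpd(auto: float, ref: float) -> Optional[float]:
    """Relative percent difference 100*(auto - ref)/ref; None when ref = 0."""
    if ref == 0:
        return None
    return 100.0 * (auto - ref) / ref


def _iqr(values: np.ndarray) -> tuple:
    lo, hi = np.percentile(values, [25, 75])  # linear interpolation
    return (float(lo), float(hi))


def summarize_agreement(
    auto: Sequence[float],
    ref: Sequence[float],
    feature: str = "",
    exact_match: bool = False,
    exact_rtol: float = 1e-6,
) -> AgreementSummary:
    """Pearson r plus median/IQR of RPD for one feature column.

    Pairs where either value is missing (NaN) are dropped; RPD is computed
    over pairs with a nonzero reference.  With ``exact_match`` the count of
    pairs equal to within ``exact_rtol`` relative tolerance is reported
    (used for SUV_max, where agreement means identical voxel selection).
    """
    auto = np.asarray(auto, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if auto.shape != ref.shape:
        raise ValueError("length mismatch between auto and reference columns")
    ok = np.isfinite(auto) & np.isfinite(ref)
    a, r = auto[ok], ref[ok]
    rvalue = pearson_r(a, r) if a.size >= 3 else None
    rpds = np.array(
        [rpd(ai, ri) for ai, ri in zip(a, r) if ri != 0], dtype=float
    )
    n_exact = None
    if exact_match:
        n_exact = int(np.sum(np.isclose(a, r, rtol=exact_rtol, atol=0.0)))
    return AgreementSummary(
        feature=feature,
        pearson_r=rvalue,
        rpd_median=float(np.median(rpds)) if rpds.size else None,
        rpd_iqr=_iqr(rpds) if rpds.size else None,
        n=int(a.size),
        n_exact_matches=n_exact,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both samples have n <= 25 and
    there are no ties, otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def subgroup_analysis(table: pd.DataFrame, dichotomize_by: str) -> SubgroupResult:
    """Median split of the cohort with rank-sum tests on DSC and |MTV RPD|.

    ``table`` needs columns ``dichotomize_by``, ``dsc`` and ``mtv_rpd``
    (reference-based values for dichotomization).  Cases at the median go
    to the low group.
    """
    values = table[dichotomize_by].to_numpy(dtype=float)
    cut = float(np.median(values))
    low = table[values <= cut]
    high = table[values > cut]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("degenerate subgroup (need >= 2 cases per group)")

    def _summary(grp: pd.DataFrame) -> dict:
        return {
            "n": int(len(grp)),
            "dsc_median": float(grp["dsc"].median()),
            "dsc_iqr": _iqr(grp["dsc"].to_numpy(dtype=float)),
            "abs_mtv_rpd_median": float(grp["mtv_rpd"].abs().median()),
        }

    pvals = {
        "dsc": wilcoxon_rank_sum(low["dsc"], high["dsc"]),
        "abs_mtv_rpd": wilcoxon_rank_sum(low["mtv_rpd"].abs(), high["mtv_rpd"].abs()),
    }
    return SubgroupResult(
        dichotomizing_feature=dichotomize_by,
        cut_value=cut,
        group_low=_summary(low),
        group_high=_summary(high),
        wilcoxon_p=pvals,
    )


def threshold_sweep(
    prob_maps_per_case: list,
    pets: list,
    cts: list,
    refs: list,
    cut_points: Sequence[float],
    bone_fraction: float = 0.5,
) -> pd.DataFrame:
    """Full post-processing and scoring at each probability cut point.

    Returns a tidy frame with one row per (case, cut) carrying the scores,
    plus cohort median and IQR columns merged per cut for plotting
    performance-versus-threshold curves.
    """
    from .postprocess import postprocess_ensemble

    rows = []
    for cut in cut_points:
        for i, (probs, pet, ct, ref) in enumerate(
            zip(prob_maps_per_case, pets, cts, refs)
        ):
            out = postprocess_ensemble(
                probs, pet, ct, cut_point=float(cut), bone_fraction=bone_fraction
            )
            sc = score_segmentation(out.final_mask, np.asarray(ref.data, dtype=bool))
            rows.append(
                {
                    "case_index": i,
                    "cut_point": float(cut),
                    "dsc": sc.dsc,
                    "sensitivity": sc.sensitivity,
                    "ppv": sc.ppv,
                    "pred_voxels": int(np.count_nonzero(out.final_mask)),
                }
            )
    df = pd.DataFrame(rows)
    med = (
        df.groupby("cut_point")[["dsc", "sensitivity", "ppv"]]
        .median()
        .rename(columns=lambda c: f"{c}_median")
    )
    q1 = (
        df.groupby("cut_point")[["dsc", "sensitivity", "ppv"]]
        .quantile(0.25)
        .rename(columns=lambda c: f"{c}_q1")
    )
    q3 = (
        df.groupby("cut_point")[["dsc", "sensitivity", "ppv"]]
        .quantile(0.75)
        .rename(columns=lambda c: f"{c}_q3")
    )
    return df.merge(med.join(q1).join(q3), on="cut_point", how="left")
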