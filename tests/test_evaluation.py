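import numpy as np
import pandas as pd
import pytest

from petlymph import (
    Modality,
    Volume,
    pearson_r,
    rpd,
    score_segmentation,
    subgroup_analysis,
    summarize_agreement,
    threshold_sweep,
    wilcoxon_rank_sum,
)


from oracles import exact_rank_sum_p


class TestScores:
    def test_perfect_prediction(self):
        m = np.random.default_rng(0).random((6, 6, 6)) > 0.5
        sc = score_segmentation(m, m)
        assert sc.dsc == sc.sensitivity == sc.ppv == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        sc = score_segmentation(a, b)
        assert sc.dsc == 0.0 and sc.sensitivity == 0.0 and sc.ppv == 0.0

    def test_formula_evaluation(self):
        # |pred|=100, |ref|=80, tp=60 -> sens .75, ppv .60, dsc 2*60/180
        pred = np.zeros((200,), bool)
        ref = np.zeros((200,), bool)
        pred[:100] = True
        ref[40:120] = True  # overlap 60
        sc = score_segmentation(pred.reshape(8, 5, 5), ref.reshape(8, 5, 5))
        assert sc.sensitivity == pytest.approx(0.75)
        assert sc.ppv == pytest.approx(0.60)
        assert sc.dsc == pytest.approx(2 * 60 / 180)

    def test_both_empty_flagged_undefined(self):
        sc = score_segmentation(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))
        assert not sc.defined and sc.dsc is None

    def test_identities_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pred = rng.random((8, 8, 8)) > rng.random()
            ref = rng.random((8, 8, 8)) > rng.random()
            sc = score_segmentation(pred, ref)
            if not sc.defined:
                continue
            assert sc.dsc == pytest.approx(
                2 * sc.tp / (pred.sum() + ref.sum()), abs=1e-12
            )
            if sc.tp + sc.fn:
                assert sc.sensitivity == pytest.approx(sc.tp / (sc.tp + sc.fn))
            if sc.tp + sc.fp:
                assert sc.ppv == pytest.approx(sc.tp / (sc.tp + sc.fp))


class TestPearsonRPD:
    def test_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_formula_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        assert pearson_r([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_rpd_examples(self):
        assert rpd(95.8, 100.0) == pytest.approx(-4.2)
        assert rpd(7.0, 7.0) == 0.0
        assert rpd(4.0, 2.0) == pytest.approx(100.0)
        assert rpd(1.0, 0.0) is None


class TestAgreement:
    def test_identical_columns(self):
        ref = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        s = summarize_agreement(ref, ref, exact_match=True)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.rpd_median == 0.0
        assert s.n_exact_matches == 5

    def test_one_differing_pair(self):
        ref = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        auto = ref.copy()
        auto[2] *= 1.01
        s = summarize_agreement(auto, ref, exact_match=True)
        assert s.n_exact_matches == 4

    def test_iqr_brackets_median(self):
        rng = np.random.default_rng(5)
        ref = rng.random(30) + 1
        auto = ref * rng.uniform(0.8, 1.2, size=30)
        s = summarize_agreement(auto, ref)
        assert s.rpd_iqr[0] <= s.rpd_median <= s.rpd_iqr[1]


class TestWilcoxon:
    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4), (8, 8)])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_fully_separated_groups_5v5(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 11.0, 12.0, 13.0, 14.0]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(2 / 252, abs=1e-12)


class TestSubgroups:
    @staticmethod
    def _table(values, dscs=None, rpds=None):
        n = len(values)
        return pd.DataFrame(
            {
                "mtv_cm3": values,
                "dsc": dscs if dscs is not None else np.linspace(0.5, 0.9, n),
                "mtv_rpd": rpds if rpds is not None else np.linspace(-10, 10, n),
            }
        )

    def test_separated_dsc_gives_exact_small_p(self):
        values = list(range(10))
        dscs = [0.5] * 5 + [0.9] * 5
        dscs = [d + 0.001 * i for i, d in enumerate(dscs)]  # break ties
        res = subgroup_analysis(self._table(values, dscs=dscs), "mtv_cm3")
        assert res.wilcoxon_p["dsc"] == pytest.approx(2 / 252, abs=1e-9)

    def test_odd_cohort_median_case_goes_low(self):
        res = subgroup_analysis(self._table(list(range(9))), "mtv_cm3")
        assert res.group_low["n"] == 5 and res.group_high["n"] == 4

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            subgroup_analysis(self._table([1.0, 1.0, 1.0, 1.0]), "mtv_cm3")


class TestThresholdSweep:
    def test_monotonicity_and_median_oracle(self):
        rng = np.random.default_rng(11)
        from scipy import ndimage

        pets, cts, refs, prob_sets = [], [], [], []
        for _ in range(4):
            pet = Volume(rng.random((12, 12, 12)).astype(np.float32) * 8, spacing=(2, 2, 2))
            ct = Volume(
                np.full((12, 12, 12), 40.0, np.float32), spacing=(2, 2, 2), modality=Modality.CT_HU
            )
            ref = np.zeros((12, 12, 12), bool)
            ref[3:8, 3:8, 3:8] = True
            smooth = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.5)
            smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min())
            probs = [
                Volume(
                    np.clip(smooth + 0.05 * j, 0, 1).astype(np.float32),
                    spacing=(2, 2, 2),
                    modality=Modality.PROBABILITY,
                )
                for j in range(3)
            ]
            pets.append(pet)
            cts.append(ct)
            refs.append(Volume(ref.astype(np.int32), (2, 2, 2), modality=Modality.LABEL))
            prob_sets.append(probs)
        cuts = np.linspace(0.0, 1.0, 11)
        df = threshold_sweep(prob_sets, pets, cts, refs, cuts)
        for _, grp in df.groupby("case_index"):
            grp = grp.sort_values("cut_point")
            assert (np.diff(grp["pred_voxels"]) <= 0).all()
            sens = grp["sensitivity"].to_numpy(float)
            assert (np.diff(sens) <= 1e-12).all()
        for cut, grp in df.groupby("cut_point"):
            assert grp["dsc_median"].iloc[0] == pytest.approx(
                float(np.median(grp["dsc"])), abs=1e-12
            )
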