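"""IoU, landmark distances, ICC(2,1), Bland-Altman and two-phase assembly."""

import numpy as np
import pytest

from lungdeform import BinaryMask, LandmarkSet, bland_altman, icc, iou
from lungdeform.grid import Geometry
from lungdeform.qc import classify_icc, landmark_distances, two_phase_repeatability


def mask_of(arr):
    arr = np.asarray(arr, dtype=np.uint8)
    return BinaryMask(arr, Geometry(arr.shape, (1.0, 1.0, 1.0)))


class TestIoU:
    def test_identical_nonempty_is_one(self):
        m = mask_of(np.ones((3, 3, 3)))
        assert iou(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4)); b = np.zeros((4, 4, 4))
        a[0], b[2] = 1, 1
        assert iou(mask_of(a), mask_of(b)) == 0.0

    def test_direct_formula(self):
        a = np.zeros((10, 10, 10)); b = np.zeros((10, 10, 10))
        a.ravel()[:100] = 1
        b.ravel()[40:140] = 1  # |A|=|B|=100, overlap 60
        assert iou(mask_of(a), mask_of(b)) == pytest.approx(60 / 140)

    def test_both_empty_is_missing(self):
        e = mask_of(np.zeros((3, 3, 3)))
        assert np.isnan(iou(e, e))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(mask_of(np.ones((3, 3, 3))), mask_of(np.ones((4, 4, 4))))

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(0)
        a = mask_of(rng.uniform(size=(8, 8, 8)) < 0.4)
        b = mask_of(rng.uniform(size=(8, 8, 8)) < 0.4)
        j = iou(a, b)
        aa, bb = a.astype_bool(), b.astype_bool()
        dice = 2 * np.sum(aa & bb) / (aa.sum() + bb.sum())
        assert dice == pytest.approx(2 * j / (1 + j))


class TestLandmarkDistances:
    def lm(self, pts, phase="exp"):
        cats = ["A", "A", "B", "B"]
        sides = ["left", "right"] * 2
        return LandmarkSet(pts, cats, sides, phase)

    def test_identical_sets_give_zero(self):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        da, db = landmark_distances(self.lm(pts, "registered"), self.lm(pts))
        assert (da, db) == (0.0, 0.0)

    def test_three_four_five_offset(self):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        moved = pts + [3.0, 4.0, 0.0]
        da, db = landmark_distances(self.lm(moved, "registered"), self.lm(pts))
        assert da == pytest.approx(5.0) and db == pytest.approx(5.0)

    def test_unmatched_labels_rejected(self):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        ref = LandmarkSet(pts[:2], ["A", "A"], ["left", "right"], "exp")
        with pytest.raises(ValueError, match="unmatched|categories"):
            landmark_distances(self.lm(pts, "registered"), ref)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        x = np.arange(1.0, 9.0)
        value, label = icc(np.c_[x, x])
        assert value == pytest.approx(1.0)
        assert label == "almost perfect"

    def test_matches_mean_squares_hand_computation(self):
        # 6 x 2 fixture, ICC(2,1) recomputed from the ANOVA decomposition
        tab = np.array([[9.0, 2.0], [4.5, 4.0], [6.9, 8.0],
                        [7.8, 8.0], [8.0, 6.5], [6.6, 7.0]])
        n, k = tab.shape
        grand = tab.mean()
        msr = k * ((tab.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((tab.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((tab - tab.mean(1, keepdims=True)
                - tab.mean(0, keepdims=True) + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        value, _ = icc(tab)
        assert value == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        subj = rng.normal(size=12)
        tab = np.c_[subj + rng.normal(0, 0.3, 12), subj + 0.2 + rng.normal(0, 0.3, 12)]
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "scores": tab.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores")
        # ICC(A,1): two-way, absolute agreement, single measures
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        value, _ = icc(tab)
        assert value == pytest.approx(icc2, abs=1e-10)

    def test_near_zero_under_independence(self):
        rng = np.random.default_rng(11)
        value, _ = icc(rng.normal(size=(200, 2)))
        assert abs(value) < 0.15

    def test_invariant_under_common_affine_rescaling(self):
        rng = np.random.default_rng(2)
        tab = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        v1, _ = icc(tab)
        v2, _ = icc(3.7 * tab + 11.0)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            icc(np.ones((2, 2)))
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((8, 2), 3.0))

    def test_classification_thresholds(self):
        assert classify_icc(-0.1) == "null"
        assert classify_icc(0.85) == "very good"
        assert classify_icc(0.96) == "almost perfect"


class TestBlandAltman:
    def test_unit_sd_differences(self):
        pairs = np.array([[0.0, 1.0], [0.0, 0.0], [0.0, -1.0]])
        md, lo, hi = bland_altman(pairs)
        assert md == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96) and hi == pytest.approx(1.96)

    def test_identical_pairs_collapse(self):
        pairs = np.tile([[2.5, 2.5]], (5, 1))
        assert bland_altman(pairs) == (0.0, 0.0, 0.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        pairs = rng.normal(size=(50, 2))
        md, lo, hi = bland_altman(pairs)
        d = pairs[:, 0] - pairs[:, 1]
        assert md == pytest.approx(d.mean(), abs=1e-12)
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_antisymmetry_under_pair_swap(self):
        rng = np.random.default_rng(9)
        pairs = rng.normal(size=(20, 2))
        md, lo, hi = bland_altman(pairs)
        md2, lo2, hi2 = bland_altman(pairs[:, ::-1])
        assert md2 == pytest.approx(-md) and lo2 == pytest.approx(-hi)
        assert hi2 == pytest.approx(-lo)


class TestAgreementProperties:
    """Randomized invariants of the agreement statistics."""

    from hypothesis import given, settings, strategies as st

    pair_tables = st.lists(
        st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
        min_size=5, max_size=40,
    ).map(np.array)

    @given(pairs=pair_tables)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bland_altman_bounds_and_antisymmetry(self, pairs):
        md, lo, hi = bland_altman(pairs)
        assert lo <= md <= hi
        md2, lo2, hi2 = bland_altman(pairs[:, ::-1])
        assert md2 == pytest.approx(-md, abs=1e-9)
        assert (lo2, hi2) == (pytest.approx(-hi, abs=1e-9),
                              pytest.approx(-lo, abs=1e-9))

    @given(pairs=pair_tables,
           a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_icc_affine_invariance_randomized(self, pairs, a, b):
        try:
            v1, _ = icc(pairs)
        except ValueError:
            return  # degenerate table: zero variance
        v2, _ = icc(a * pairs + b)
        assert v2 == pytest.approx(v1, abs=1e-6)


class TestTwoPhase:
    def subject(self, sid, q1, q2=None):
        return {"subject_id": sid, "phase1": q1, "phase2": q2 or dict(q1)}

    def test_identical_phases_perfect_agreement(self):
        rng = np.random.default_rng(3)
        recs = [
            self.subject(f"s{i}", {"iou": 0.8 + 0.02 * i + rng.normal(0, 0.001),
                                   "da_mm": 5.0 + i, "db_mm": 6.0 + i})
            for i in range(6)
        ]
        rep = two_phase_repeatability(recs)
        for m in ("iou", "da_mm", "db_mm"):
            assert rep.icc_by_metric[m]["icc"] == pytest.approx(1.0)
            ba = rep.bland_altman_by_metric[m]
            assert (ba["mean_diff"], ba["loa_low"], ba["loa_high"]) == (0, 0, 0)

    def test_incomplete_subject_excluded(self):
        recs = [
            self.subject(f"s{i}", {"iou": 0.8 + 0.01 * i, "da_mm": 5.0 + i,
                                   "db_mm": 6.0 + i})
            for i in range(6)
        ]
        recs.append({"subject_id": "broken", "phase1": {"iou": 0.9}, "phase2": None})
        rep = two_phase_repeatability(recs)
        assert rep.n_subjects == 6
        assert rep.excluded_subjects == ["broken"]

    def test_single_subject_rejected(self):
        recs = [self.subject("s0", {"iou": 0.9, "da_mm": 4.0, "db_mm": 4.0})]
        with pytest.raises(ValueError):
            two_phase_repeatability(recs)
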