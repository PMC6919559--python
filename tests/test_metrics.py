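"""IoU matching, threshold sweep metrics and the competition score."""

import itertools

import numpy as np
import pytest

from nucleval.errors import ContractError
from nucleval.mask_io import LabelMask
from nucleval.metrics import (
    ConfusionAtThreshold,
    IouMatrix,
    ThresholdSet,
    default_thresholds,
    evaluate_dataset,
    f1_curve,
    image_score,
    iou,
    iou_matrix,
    match_at_threshold,
    precision_recall_f1,
)

from conftest import make_mask, random_blob_mask


def brute_force_max_matching(values: np.ndarray, t: float) -> int:
    """Maximum one-to-one matching cardinality by exhaustive enumeration."""
    nt, npred = values.shape
    edges = values > t
    small, big = (0, 1) if nt <= npred else (1, 0)
    n_small = min(nt, npred)
    n_big = max(nt, npred)
    best = 0
    for assign in itertools.permutations(range(n_big), n_small):
        card = 0
        for i, j in enumerate(assign):
            ok = edges[i, j] if nt <= npred else edges[j, i]
            card += bool(ok)
        best = max(best, card)
    return best


class TestIou:
    def test_identical_nonempty_is_one(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        assert iou(a, a) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert iou(a, b) == 0.0

    def test_nested_8_in_16_is_half(self):
        b = np.zeros((8, 8), bool)
        b[0:4, 0:4] = True  # 16 px
        a = np.zeros((8, 8), bool)
        a[0:2, 0:4] = True  # 8 px inside b
        assert iou(a, b) == 0.5

    def test_both_empty_is_zero(self):
        z = np.zeros((3, 3), bool)
        assert iou(z, z) == 0.0

    def test_symmetry(self, rng):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        assert iou(a, b) == iou(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestIouMatrix:
    def test_identical_masks_have_unit_diagonal(self):
        arr = np.array([[1, 1, 0], [2, 2, 0], [0, 0, 3]])
        m = iou_matrix(make_mask(arr), make_mask(arr))
        assert np.allclose(np.diag(m.values), 1.0)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.all(off < 1.0)

    def test_no_overlap_gives_all_zero(self):
        a = np.zeros((4, 4), int)
        a[0, 0] = 1
        b = np.zeros((4, 4), int)
        b[3, 3] = 1
        m = iou_matrix(make_mask(a), make_mask(b))
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_matches_dense_all_pairs_oracle(self, rng):
        for _ in range(20):
            ta = random_blob_mask(rng, 16, 16, int(rng.integers(0, 6)))
            pb = random_blob_mask(rng, 16, 16, int(rng.integers(0, 6)))
            m = iou_matrix(ta, pb)
            dense = np.zeros((ta.n_objects, pb.n_objects))
            for i in range(ta.n_objects):
                for j in range(pb.n_objects):
                    dense[i, j] = iou(ta.labels == i + 1, pb.labels == j + 1)
            assert np.array_equal(m.values, dense)

    def test_zero_entry_iff_no_shared_pixel(self, rng):
        ta = random_blob_mask(rng, 16, 16, 4)
        pb = random_blob_mask(rng, 16, 16, 4)
        m = iou_matrix(ta, pb)
        for i in range(ta.n_objects):
            for j in range(pb.n_objects):
                shares = np.any((ta.labels == i + 1) & (pb.labels == j + 1))
                assert (m.values[i, j] > 0) == shares


class TestMatching:
    def test_single_identical_pair(self):
        arr = np.zeros((5, 5), int)
        arr[1:4, 1:4] = 1
        m = iou_matrix(make_mask(arr), make_mask(arr))
        r = match_at_threshold(m, 0.5)
        assert r.pairs == [(1, 1, 1.0)] and r.tp == 1 and r.fp == 0 and r.fn == 0

    def test_no_predictions_all_fn(self):
        tgt = make_mask(np.array([[1, 0, 2], [0, 0, 0], [3, 0, 0]]))
        prd = make_mask(np.zeros((3, 3)))
        r = match_at_threshold(iou_matrix(tgt, prd), 0.3)
        assert r.fn == 3 and r.tp == 0 and r.fp == 0

    def test_greedy_prefers_highest_iou_then_resolves_rest(self):
        # ious {(a,x)=0.6, (a,y)=0.55, (b,y)=0.58}: best one-to-one set
        # is {(a,x), (b,y)} by brute force over all matchings
        values = np.array([[0.6, 0.55], [0.0, 0.58]])
        r = match_at_threshold(IouMatrix(values), 0.5)
        assert {(t, p) for t, p, _ in r.pairs} == {(1, 1), (2, 2)}
        assert r.tp == 2

    def test_strict_inequality_at_threshold(self):
        values = np.array([[0.5]])
        assert match_at_threshold(IouMatrix(values), 0.5).tp == 0
        assert match_at_threshold(IouMatrix(values), 0.5, inclusive=True).tp == 1

    def test_conservation_invariants(self, rng):
        for _ in range(20):
            ta = random_blob_mask(rng, 14, 14, int(rng.integers(0, 6)))
            pb = random_blob_mask(rng, 14, 14, int(rng.integers(0, 6)))
            m = iou_matrix(ta, pb)
            for t in (0.1, 0.5, 0.9):
                r = match_at_threshold(m, t)
                assert r.tp + r.fn == ta.n_objects
                assert r.tp + r.fp == pb.n_objects
                matched_t = [p[0] for p in r.pairs]
                matched_p = [p[1] for p in r.pairs]
                assert len(set(matched_t)) == len(matched_t)
                assert len(set(matched_p)) == len(matched_p)

    def test_cardinality_equals_brute_force_on_tiny_instances(self, rng):
        for _ in range(60):
            ta = random_blob_mask(rng, 10, 10, int(rng.integers(0, 5)))
            pb = random_blob_mask(rng, 10, 10, int(rng.integers(0, 5)))
            m = iou_matrix(ta, pb)
            for t in default_thresholds():
                got = match_at_threshold(m, t).tp
                assert got == brute_force_max_matching(m.values, t)

    def test_above_half_no_pred_has_two_candidates(self, rng):
        # pigeonhole: a prediction cannot overlap two disjoint targets
        # with IoU > 0.5 each
        for _ in range(30):
            ta = random_blob_mask(rng, 16, 16, 5)
            pb = random_blob_mask(rng, 16, 16, 5)
            cand = iou_matrix(ta, pb).values > 0.5
            assert np.all(cand.sum(axis=0) <= 1)
            assert np.all(cand.sum(axis=1) <= 1)

    def test_tp_non_increasing_in_threshold(self, rng):
        ta = random_blob_mask(rng, 20, 20, 6)
        pb = random_blob_mask(rng, 20, 20, 6)
        m = iou_matrix(ta, pb)
        tps = [match_at_threshold(m, t).tp for t in default_thresholds()]
        assert all(a >= b for a, b in zip(tps, tps[1:]))


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (2, 0, 0, (1.0, 1.0, 1.0)),
            (1, 1, 1, (0.5, 0.5, 0.5)),
            (0, 0, 0, (1.0, 1.0, 1.0)),  # all-empty image counts as perfect
            (0, 3, 0, (0.0, 0.0, 0.0)),
            (0, 0, 2, (0.0, 0.0, 0.0)),
        ],
    )
    def test_formula_and_conventions(self, tp, fp, fn, expected):
        got = precision_recall_f1(ConfusionAtThreshold(0.5, tp, fp, fn))
        assert got == expected

    def test_tn_is_always_zero(self):
        assert ConfusionAtThreshold(0.5, 1, 2, 3).tn == 0


class TestThresholdSet:
    def test_default_is_18_values_from_integer_grid(self):
        t = default_thresholds()
        assert len(t) == 18
        assert t.values[0] == 0.10 and t.values[-1] == 0.95
        assert t.values == tuple(h / 100 for h in range(10, 100, 5))

    def test_spec_string_parses_to_default(self):
        assert ThresholdSet.from_spec("0.10:0.95:0.05") == default_thresholds()

    def test_non_increasing_rejected(self):
        with pytest.raises(ContractError):
            ThresholdSet((0.5, 0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            ThresholdSet((0.0, 0.5))


class TestImageScore:
    def test_perfect_prediction_scores_one_everywhere(self, rng):
        m = random_blob_mask(rng, 24, 24, 5)
        rep = image_score(m, m)
        assert rep.score == 1.0
        assert np.all(rep.f1 == 1.0)

    def test_single_pair_at_exactly_half_iou_gives_8_18(self):
        # IoU 0.5 passes the strict > rule only for t in {0.10..0.45}:
        # 8 of the 18 thresholds
        tgt_arr = np.zeros((8, 8), int)
        tgt_arr[0:2, 0:4] = 1  # 8 px
        prd_arr = np.zeros((8, 8), int)
        prd_arr[0:4, 0:4] = 1  # 16 px, containing the target
        rep = image_score(make_mask(tgt_arr), make_mask(prd_arr))
        assert rep.score == pytest.approx(8.0 / 18.0, abs=1e-15)

    def test_target_without_prediction_scores_zero(self):
        tgt = make_mask(np.array([[1, 1], [0, 0]]))
        prd = make_mask(np.zeros((2, 2)))
        assert image_score(tgt, prd).score == 0.0

    def test_empty_vs_empty_scores_one(self):
        z = make_mask(np.zeros((4, 4)))
        assert image_score(z, z).score == 1.0

    def test_score_bounded_by_mean_f1(self, rng):
        for _ in range(10):
            ta = random_blob_mask(rng, 20, 20, 5)
            pb = random_blob_mask(rng, 20, 20, 5)
            rep = image_score(ta, pb)
            assert 0.0 <= rep.score <= rep.f1.mean() + 1e-12 <= 1.0 + 1e-12

    def test_f1_non_increasing_in_threshold(self, rng):
        for _ in range(10):
            ta = random_blob_mask(rng, 20, 20, 5)
            pb = random_blob_mask(rng, 20, 20, 5)
            f1 = image_score(ta, pb).f1
            assert all(a >= b - 1e-12 for a, b in zip(f1, f1[1:]))


class TestEvaluateDataset:
    def test_two_perfect_images(self, rng):
        m1 = random_blob_mask(rng, 16, 16, 3)
        m2 = random_blob_mask(rng, 16, 16, 4)
        rep = evaluate_dataset([(m1, m1), (m2, m2)])
        assert rep.mean_score == 1.0 and rep.average_f1 == 1.0
        assert rep.missed_at_07 == 0.0 and rep.extra_at_07 == 0.0
        assert rep.recall_at_07 == 100.0

    def test_mean_score_of_perfect_and_empty_prediction(self, rng):
        m1 = random_blob_mask(rng, 16, 16, 3)
        tgt = make_mask(np.pad(np.ones((3, 3), int), 2))
        none = make_mask(np.zeros_like(tgt.labels))
        rep = evaluate_dataset([(m1, m1), (tgt, none)])
        assert rep.mean_score == pytest.approx(0.5)

    def test_recall_plus_missed_is_100(self, rng):
        pairs = []
        for _ in range(6):
            ta = random_blob_mask(rng, 18, 18, int(rng.integers(1, 6)))
            pb = random_blob_mask(rng, 18, 18, int(rng.integers(0, 6)))
            pairs.append((ta, pb))
        rep = evaluate_dataset(pairs)
        assert rep.recall_at_07 + rep.missed_at_07 == pytest.approx(100.0)

    def test_per_group_breakdown_partitions_images(self, rng):
        pairs = []
        for g in ("small_fluorescent", "purple_tissue"):
            for _ in range(2):
                m = random_blob_mask(rng, 16, 16, 3)
                pairs.append((m, m, g))
        rep = evaluate_dataset(pairs)
        assert set(rep.per_group) == {"small_fluorescent", "purple_tissue"}
        assert all(len(r.image_reports) == 2 for r in rep.per_group.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            evaluate_dataset([])

    def test_pooled_aggregation_mode_runs(self, rng):
        m = random_blob_mask(rng, 16, 16, 4)
        rep = evaluate_dataset([(m, m)], aggregate="pooled")
        assert rep.mean_score == 1.0 and rep.average_f1 == 1.0


class TestF1Curve:
    def test_perfect_predictions_constant_one(self, rng):
        m = random_blob_mask(rng, 16, 16, 4)
        curve = f1_curve([(m, m)])
        assert np.all(curve == 1.0)

    def test_single_object_at_075_steps_down(self):
        # a 3x4 target and a prediction sharing 9 of its 12 pixels:
        # IoU = 9/12 = 0.75 -> F1 is 1 below 0.75 and 0 above
        tgt_arr = np.zeros((6, 6), int)
        tgt_arr[0:3, 0:4] = 1
        prd_arr = np.zeros((6, 6), int)
        prd_arr[0:3, 0:3] = 1
        assert iou(tgt_arr > 0, prd_arr > 0) == 0.75
        curve = f1_curve([(make_mask(tgt_arr), make_mask(prd_arr))])
        expected = [1.0 if t < 0.75 else 0.0 for t in default_thresholds()]
        assert np.allclose(curve, expected)

    def test_monotone_non_increasing_on_random_pairs(self, rng):
        pairs = [
            (random_blob_mask(rng, 16, 16, 4), random_blob_mask(rng, 16, 16, 4))
            for _ in range(20)
        ]
        curve = f1_curve(pairs)
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))
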