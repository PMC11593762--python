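import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from entrofuse import (
    ConfusionCounts,
    auroc,
    confusion_counts,
    dice,
    error_rate,
    jaccard,
    mean_iou,
    metric_vector,
    pixel_accuracy,
    precision_recall_tnr,
    report_table,
    slicewise_confusion_counts,
    write_report,
)
from entrofuse.errors import (
    NonBinaryMaskError,
    ShapeMismatchError,
    UndefinedAUROCError,
    UnknownMetricError,
)
from conftest import as_pred, as_truth
from oracles import oracle_auroc, oracle_counts, oracle_metrics

TOY = ConfusionCounts(tp=3, fp=1, fn=2, tn=6)


def random_pair(rng, max_edge=16, p=None):
    shape = tuple(rng.integers(1, max_edge + 1, 3))
    p = rng.uniform(0.05, 0.95) if p is None else p
    truth = (rng.random(shape) < p).astype(np.uint8)
    pred = (rng.random(shape) < p).astype(np.uint8)
    return pred, truth


class TestConfusionCounts:
    def test_enumerated_toy(self, toy_pair):
        cc = confusion_counts(*toy_pair)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)

    def test_identity_prediction_has_no_errors(self, rng):
        mask = (rng.random((4, 5, 6)) < 0.3).astype(np.uint8)
        cc = confusion_counts(as_pred(mask), as_truth(mask))
        assert cc.fp == cc.fn == 0
        assert cc.tp == mask.sum()

    def test_all_zero_prediction(self, rng):
        truth = (rng.random((3, 4, 4)) < 0.4).astype(np.uint8)
        cc = confusion_counts(as_pred(np.zeros_like(truth)), as_truth(truth))
        k = int(truth.sum())
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (0, 0, k, truth.size - k)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            confusion_counts(as_pred(np.zeros((2, 2, 2))), as_truth(np.zeros((2, 2, 3))))

    def test_non_binary_score_pred_rejected(self):
        pred = as_pred(np.full((2, 2, 2), 0.5), role="score")
        with pytest.raises(NonBinaryMaskError):
            confusion_counts(pred, as_truth(np.ones((2, 2, 2))))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestScalarMetrics:
    def test_jaccard_foreground_toy(self):
        assert jaccard(TOY, "foreground") == 3 / 6

    def test_jaccard_background_toy(self):
        assert jaccard(TOY, "background") == 6 / 9

    def test_dice_toy_and_jaccard_relation(self):
        d = dice(TOY)
        j = jaccard(TOY, "foreground")
        assert d == 6 / 9
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-15)

    def test_precision_recall_tnr_toy(self):
        assert precision_recall_tnr(ConfusionCounts(3, 1, 2, 10)) == (
            0.75,
            0.6,
            10 / 11,
        )

    def test_accuracy_error_complement_toy(self, toy_pair):
        cc = confusion_counts(*toy_pair)
        assert pixel_accuracy(cc) == 0.5
        assert error_rate(cc) == 0.5

    def test_mean_iou_global_toy(self):
        assert mean_iou(TOY, "global") == (3 / 6 + 6 / 9) / 2

    def test_empty_set_convention(self):
        empty = ConfusionCounts(0, 0, 0, 8)
        assert jaccard(empty, "foreground") == 1.0
        assert dice(empty) == 1.0
        assert precision_recall_tnr(empty) == (1.0, 1.0, 1.0)

    def test_disjoint_pred_truth_dice_zero(self):
        assert dice(ConfusionCounts(0, 3, 3, 10)) == 0.0

    def test_single_slice_global_equals_per_slice(self, toy_pair):
        pred, truth = toy_pair
        cc = confusion_counts(pred, truth)
        per = slicewise_confusion_counts(pred, truth)
        assert mean_iou(cc, "global") == mean_iou(per, "per_slice")

    def test_per_slice_skips_undefined_class(self):
        # slice 0 correct-empty (only JI_B defined), slice 1 perfect
        truth = as_truth([[[0, 0]], [[1, 1]]])
        pred = as_pred([[[0, 0]], [[1, 1]]])
        per = slicewise_confusion_counts(pred, truth)
        assert mean_iou(per, "per_slice") == 1.0


class TestAuroc:
    def test_perfect_separation(self):
        truth = as_truth([[[1, 1], [0, 0]]])
        pred = as_pred([[[1.0, 1.0], [0.0, 0.0]]], role="score")
        assert auroc(pred, truth) == 1.0

    def test_constant_scores_all_ties(self):
        truth = as_truth([[[1, 0], [1, 0]]])
        pred = as_pred(np.full((1, 2, 2), 0.3), role="score")
        assert auroc(pred, truth) == 0.5

    def test_four_pair_enumeration(self):
        truth = as_truth([[[1, 1], [0, 0]]])
        pred = as_pred([[[0.9, 0.4], [0.6, 0.1]]], role="score")
        assert auroc(pred, truth) == 0.75

    def test_single_class_truth_undefined(self):
        with pytest.raises(UndefinedAUROCError):
            auroc(as_pred(np.zeros((2, 2, 2)) + 0.5, role="score"), as_truth(np.ones((2, 2, 2))))

    def test_binary_scores_reduce_to_balanced_accuracy(self, rng):
        truth = (rng.random((4, 6, 6)) < 0.4).astype(np.uint8)
        truth[0, 0, 0] = 1
        truth[0, 0, 1] = 0
        predm = (rng.random(truth.shape) < 0.4).astype(np.uint8)
        cc = confusion_counts(as_pred(predm), as_truth(truth))
        _, tpr, tnr = precision_recall_tnr(cc)
        val = auroc(as_pred(predm.astype(float), role="score"), as_truth(truth))
        assert val == pytest.approx((tpr + tnr) / 2, abs=1e-12)

    def test_matches_sklearn_on_random_scores(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(2, 8, 3))
            truth = (rng.random(shape) < 0.5).astype(np.uint8)
            truth.ravel()[0] = 1
            truth.ravel()[1] = 0
            scores = np.round(rng.random(shape), 2)  # induce ties
            ours = auroc(as_pred(scores, role="score"), as_truth(truth))
            ref = roc_auc_score(truth.ravel(), scores.ravel())
            assert ours == pytest.approx(ref, abs=1e-12)


class TestMetricVector:
    def test_consistency_with_standalone_ops(self, rng):
        pred, truth = random_pair(rng, max_edge=8)
        mv = metric_vector(as_pred(pred), as_truth(truth))
        cc = confusion_counts(as_pred(pred), as_truth(truth))
        assert mv.entries["JI_F"] == jaccard(cc, "foreground")
        assert mv.entries["DSC"] == dice(cc)
        assert mv.entries["m_IoU"] == mean_iou(cc, "global")
        assert mv.entries["accuracy"] == pixel_accuracy(cc)
        assert list(mv.entries) == [
            "JI_F", "JI_B", "m_IoU", "DSC", "accuracy", "precision", "recall",
        ]

    def test_identity_prediction_gives_ones(self, rng):
        mask = (rng.random((3, 4, 4)) < 0.5).astype(np.uint8)
        mask[0, 0, 0] = 1
        mv = metric_vector(as_pred(mask), as_truth(mask), ["JI_F"])
        assert mv.entries == {"JI_F": 1.0}

    def test_unknown_metric_rejected(self, toy_pair):
        with pytest.raises(UnknownMetricError):
            metric_vector(*toy_pair, metric_names=["f1x"])


class TestOracleProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pred, truth = random_pair(rng, max_edge=8)
        ours = metric_vector(
            as_pred(pred), as_truth(truth),
            ["JI_F", "JI_B", "m_IoU", "DSC", "accuracy", "precision", "recall", "TPR", "TNR"],
        ).entries
        ref = oracle_metrics(pred, truth)
        for name, val in ours.items():
            assert val == ref[name], name
        cc = confusion_counts(as_pred(pred), as_truth(truth))
        assert pixel_accuracy(cc) + error_rate(cc) == 1.0
        assert error_rate(cc) == ref["error_rate"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auroc_matches_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(1, 9, 3))
        truth = (rng.random(shape) < 0.5).astype(np.uint8)
        flat = truth.ravel()
        if flat.size < 2:
            return
        flat[0], flat[1] = 1, 0
        scores = np.round(rng.random(shape), 1)
        ours = auroc(as_pred(scores, role="score"), as_truth(truth))
        assert ours == pytest.approx(oracle_auroc(scores, truth), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pred, truth = random_pair(rng, max_edge=6)
        perm = rng.permutation(truth.size)
        shape = truth.shape
        before = metric_vector(as_pred(pred), as_truth(truth)).entries
        after = metric_vector(
            as_pred(pred.ravel()[perm].reshape(shape)),
            as_truth(truth.ravel()[perm].reshape(shape)),
        ).entries
        assert before == after

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_class_swap_symmetry_of_mean_iou(self, seed):
        rng = np.random.default_rng(seed)
        pred, truth = random_pair(rng, max_edge=6)
        cc = confusion_counts(as_pred(pred), as_truth(truth))
        sw = confusion_counts(as_pred(1 - pred), as_truth(1 - truth))
        assert jaccard(cc, "foreground") == jaccard(sw, "background")
        assert jaccard(cc, "background") == jaccard(sw, "foreground")
        assert mean_iou(cc, "global") == mean_iou(sw, "global")


class TestReport:
    def test_table_shape_and_roundtrip(self, tmp_path, toy_pair):
        import pandas as pd

        pred, truth = toy_pair
        mv = metric_vector(pred, truth)
        table = report_table([mv])
        assert list(table.index) == ["m"]
        write_report(table, tmp_path / "m.csv", tmp_path / "m.txt")
        back = pd.read_csv(tmp_path / "m.csv", index_col=0)
        assert back.loc["m", "DSC"] == pytest.approx(mv.entries["DSC"], abs=1e-4)
        assert "DSC" in (tmp_path / "m.txt").read_text()
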