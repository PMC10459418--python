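"""Confusion-matrix construction, aggregation, projection and macro metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsidl.confmat import (
    ConfusionMatrix,
    LabelMap,
    MetricsReport,
    aggregate_folds,
    build_cm,
    macro_metrics,
    project,
)

from conftest import random_cm


def brute_force_macro(cm: ConfusionMatrix) -> dict[str, float]:
    """Independent per-class loop implementation of the macro metrics."""
    r = cm.r
    recalls, precisions = [], []
    for i in range(r):
        tp = cm.counts[i][i]
        row = sum(cm.counts[i][j] for j in range(r))
        col = sum(cm.counts[j][i] for j in range(r))
        recalls.append(tp / row if row else 0.0)
        precisions.append(tp / col if col else 0.0)
    macro_r = sum(recalls) / r
    macro_p = sum(precisions) / r
    f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r else 0.0
    total = cm.counts.sum()
    acc = sum(cm.counts[i][i] for i in range(r)) / total
    return {"macro_recall": macro_r, "macro_precision": macro_p, "macro_f1": f1, "accuracy": acc}


class TestBuildCM:
    def test_direct_tally(self):
        cm = build_cm(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]
        assert cm.total == 3

    def test_perfect_predictions_are_diagonal(self):
        cm = build_cm(list("ABCABC"), list("ABCABC"))
        assert np.all(cm.counts == 2 * np.eye(3, dtype=int))

    def test_unknown_label_is_named_in_error(self):
        with pytest.raises(ValueError, match="'C'"):
            build_cm(["A"], ["C"], ["A", "B"])
        with pytest.raises(ValueError, match="length mismatch"):
            build_cm(["A", "B"], ["A"])

    def test_matches_naive_double_loop_tally(self):
        rng = np.random.default_rng(11)
        labels = [f"c{k}" for k in range(6)]
        true = rng.choice(labels, 500)
        pred = rng.choice(labels, 500)
        cm = build_cm(true, pred, labels)
        naive = np.zeros((6, 6), int)
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                naive[i, j] = sum(1 for t, p in zip(true, pred) if t == li and p == lj)
        assert np.array_equal(cm.counts, naive)

    def test_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(5)
        labels = ["a", "b", "c", "d"]
        true = rng.choice(labels, 300)
        pred = rng.choice(labels, 300)
        ours = build_cm(true, pred, labels)
        assert np.array_equal(ours.counts, sk_cm(true, pred, labels=labels))


class TestAggregateFolds:
    def test_sum_of_identical_folds(self):
        cm = ConfusionMatrix(("a", "b"), np.eye(2, dtype=int))
        agg = aggregate_folds([cm] * 5)
        assert agg.counts.tolist() == [[5, 0], [0, 5]]

    def test_row_sums_are_linear(self):
        rng = np.random.default_rng(0)
        folds = []
        for _ in range(5):
            counts = rng.multinomial(10, [0.7, 0.2, 0.1], size=3)
            folds.append(ConfusionMatrix(("a", "b", "c"), counts))
        agg = aggregate_folds(folds)
        assert np.all(agg.support() == 50)
        assert agg.total == sum(f.total for f in folds)

    def test_order_invariance_and_oracle(self):
        rng = np.random.default_rng(2)
        folds = [random_cm(rng, r=4) for _ in range(5)]
        agg = aggregate_folds(folds)
        assert np.array_equal(agg.counts, sum(f.counts for f in folds))
        assert np.array_equal(agg.counts, aggregate_folds(folds[::-1]).counts)

    def test_mismatched_labels_error_lists_difference(self):
        a = ConfusionMatrix(("a", "b"), np.eye(2, dtype=int))
        c = ConfusionMatrix(("a", "c"), np.eye(2, dtype=int))
        with pytest.raises(ValueError, match="'b'"):
            aggregate_folds([a, c])


class TestMacroMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(("a", "b", "c"), 7 * np.eye(3, dtype=int))
        rep = macro_metrics(cm)
        assert rep.macro_recall == rep.macro_precision == rep.macro_f1 == rep.accuracy == 1.0

    def test_hand_worked_two_class_case(self):
        rep = macro_metrics(ConfusionMatrix(("a", "b"), np.array([[8, 2], [1, 9]])))
        assert rep.accuracy == pytest.approx(17 / 20)
        assert rep.macro_recall == pytest.approx((0.8 + 0.9) / 2)
        assert rep.macro_precision == pytest.approx((8 / 9 + 9 / 11) / 2)
        mp, mr = (8 / 9 + 9 / 11) / 2, 0.85
        assert rep.macro_f1 == pytest.approx(2 * mp * mr / (mp + mr))

    def test_never_predicted_class_contributes_zero_precision(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[5, 0], [5, 0]]))
        with pytest.warns(UserWarning, match="never predicted"):
            rep = macro_metrics(cm)
        assert rep.macro_precision == pytest.approx(0.25)

    def test_empty_cm_errors(self):
        with pytest.raises(ValueError, match="empty"):
            macro_metrics(ConfusionMatrix(("a", "b"), np.zeros((2, 2), int)))

    def test_matches_brute_force_on_random_cms(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cm = random_cm(rng)
            rep = macro_metrics(cm)
            want = brute_force_macro(cm)
            assert rep.macro_recall == pytest.approx(want["macro_recall"], abs=1e-12)
            assert rep.macro_precision == pytest.approx(want["macro_precision"], abs=1e-12)
            assert rep.macro_f1 == pytest.approx(want["macro_f1"], abs=1e-12)
            assert rep.accuracy == pytest.approx(want["accuracy"], abs=1e-12)

    def test_recall_precision_match_sklearn(self):
        """Independent library cross-check (per-class averages, zero-division 0)."""
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(9)
        labels = ["a", "b", "c", "d", "e"]
        true = rng.choice(labels, 400)
        pred = rng.choice(labels, 400)
        rep = macro_metrics(build_cm(true, pred, labels))
        assert rep.macro_recall == pytest.approx(
            recall_score(true, pred, average="macro", zero_division=0)
        )
        assert rep.macro_precision == pytest.approx(
            precision_score(true, pred, average="macro", zero_division=0)
        )


class TestProject:
    def test_identity_map_is_identity(self):
        rng = np.random.default_rng(1)
        cm = random_cm(rng, r=4)
        out = project(cm, {l: l for l in cm.labels})
        assert out.labels == cm.labels and np.array_equal(out.counts, cm.counts)

    def test_total_conserved(self):
        rng = np.random.default_rng(3)
        cm = random_cm(rng, r=4)
        coarse = project(cm, {l: "p0" if i < 2 else "p1" for i, l in enumerate(cm.labels)})
        assert coarse.total == cm.total

    def test_within_package_confusion_lands_on_diagonal(self):
        cm = ConfusionMatrix(("A", "B", "C"), np.array([[4, 6, 0], [0, 10, 0], [0, 0, 10]]))
        coarse = project(cm, {"A": "X", "B": "X", "C": "Y"})
        i = coarse.labels.index("X")
        assert coarse.counts[i, i] == 20  # 4 + 6 + 10: A->B confusion absorbed

    def test_matches_cellwise_regrouping_oracle(self):
        rng = np.random.default_rng(8)
        cm = random_cm(rng, r=6)
        label_map = {l: f"p{i % 2}" for i, l in enumerate(cm.labels)}
        coarse = project(cm, label_map)
        want = np.zeros((2, 2), int)
        order = sorted(set(label_map.values()))
        for i, li in enumerate(cm.labels):
            for j, lj in enumerate(cm.labels):
                want[order.index(label_map[li]), order.index(label_map[lj])] += cm.counts[i, j]
        assert np.array_equal(coarse.counts, want)

    def test_coarse_accuracy_never_below_fine(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            cm = random_cm(rng)
            label_map = {l: f"p{rng.integers(0, 3)}" for l in cm.labels}
            fine_acc = macro_metrics(cm).accuracy
            coarse_acc = macro_metrics(project(cm, label_map)).accuracy
            assert coarse_acc >= fine_acc - 1e-12

    def test_unmapped_label_errors(self):
        cm = ConfusionMatrix(("a", "b"), np.eye(2, dtype=int))
        with pytest.raises(KeyError, match="'b'"):
            project(cm, {"a": "x"})


@settings(deadline=None, max_examples=60)
@given(st.integers(0, 2**31 - 1))
def test_tp_fn_fp_identities(seed):
    """sum_i (TP_i + FN_i) = sum_i (TP_i + FP_i) = total, for any CM."""
    cm = random_cm(np.random.default_rng(seed))
    assert (cm.tp() + cm.fn()).sum() == cm.total
    assert (cm.tp() + cm.fp()).sum() == cm.total
    assert np.all(cm.tp() + cm.fn() == cm.support())


def test_tsv_round_trip_is_bit_exact(tmp_path):
    rng = np.random.default_rng(4)
    cm = random_cm(rng, r=5)
    cm.to_tsv(tmp_path / "cm.tsv")
    back = ConfusionMatrix.from_tsv(tmp_path / "cm.tsv")
    assert back.labels == cm.labels
    assert np.array_equal(back.counts, cm.counts)


def test_metrics_report_json_round_trip(tmp_path):
    rep = macro_metrics(ConfusionMatrix(("a", "b"), np.array([[8, 2], [1, 9]])))
    rep.to_json(tmp_path / "rep.json")
    back = MetricsReport.from_json(tmp_path / "rep.json")
    assert back.macro_f1 == rep.macro_f1
    assert back.per_class["a"]["recall"] == rep.per_class["a"]["recall"]


def test_label_map_raises_on_missing_fine_label():
    lm = LabelMap({"a": "x"})
    assert lm["a"] == "x"
    with pytest.raises(KeyError, match="no coarse assignment"):
        lm["zzz"]
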