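"""Evaluation suite against independent oracles and printed worked examples."""

import math

import numpy as np
import pytest

from ddekit.metrics import (
    ConfusionMatrix,
    binary_metrics,
    dataset_summary,
    frequency_table,
    hamming_loss,
    jaccard_and_subset,
    multilabel_report,
    pr_curve,
    roc_curve,
    round_half_up,
)

CLASSES = tuple("ABCDEFGH")


def pairwise_concordance_auc(scores, gold):
    """Oracle: P(score_pos > score_neg) + 0.5 P(tie), by enumeration."""
    pos = [s for s, g in zip(scores, gold) if g == 1]
    neg = [s for s, g in zip(scores, gold) if g == 0]
    total = len(pos) * len(neg)
    acc = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return acc / total


def brute_force_f1_pooling(pred_sets, gold_sets, classes):
    """Oracle: per-class cell counting, then micro/macro/weighted by hand."""
    per = {}
    for c in classes:
        tp = sum(1 for i in gold_sets if c in pred_sets[i] and c in gold_sets[i])
        fp = sum(1 for i in gold_sets if c in pred_sets[i] and c not in gold_sets[i])
        fn = sum(1 for i in gold_sets if c not in pred_sets[i] and c in gold_sets[i])
        per[c] = (tp, fp, fn)
    def f1(tp, fp, fn):
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    TP = sum(v[0] for v in per.values())
    FP = sum(v[1] for v in per.values())
    FN = sum(v[2] for v in per.values())
    micro = f1(TP, FP, FN)
    macro = sum(f1(*v) for v in per.values()) / len(classes)
    supports = {c: per[c][0] + per[c][2] for c in classes}
    tot = sum(supports.values())
    weighted = (
        sum(f1(*per[c]) * supports[c] for c in classes) / tot if tot else 0.0
    )
    return micro, macro, weighted


class TestBinaryMetrics:
    # confusion matrices reconstructed from the published class counts
    # (107 positive / 893 negative) and the printed FPR/FNR
    @pytest.mark.parametrize(
        "cm,f1,acc,fpr,fnr",
        [
            (ConfusionMatrix(tp=100, fp=25, fn=7, tn=868), 0.862, 0.968, 0.028, 0.065),
            (ConfusionMatrix(tp=87, fp=115, fn=20, tn=778), 0.563, 0.865, 0.129, 0.187),
            (ConfusionMatrix(tp=25, fp=50, fn=82, tn=843), 0.275, 0.868, 0.056, 0.766),
        ],
    )
    def test_published_worked_examples(self, cm, f1, acc, fpr, fnr):
        m = binary_metrics(cm)
        assert m.f1 == pytest.approx(f1, abs=5e-4)
        assert m.accuracy == pytest.approx(acc, abs=5e-4)
        assert m.fpr == pytest.approx(fpr, abs=5e-4)
        assert m.fnr == pytest.approx(fnr, abs=5e-4)

    def test_degenerate_positive_class_flagged(self):
        m = binary_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m.accuracy == 1.0 and m.precision == 0.0
        assert "precision" in m.degenerate

    def test_identities_hold(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 40, size=4)
            if tp + fp + fn + tn == 0:
                continue
            m = binary_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            if tp + fn:
                assert m.tpr + m.fnr == pytest.approx(1.0)
            if fp + tn:
                assert m.fpr + m.tnr == pytest.approx(1.0)
            if m.precision + m.recall > 0 and "precision" not in m.degenerate \
                    and "recall" not in m.degenerate:
                harm = 2 * m.precision * m.recall / (m.precision + m.recall)
                assert m.f1 == pytest.approx(harm)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            binary_metrics(ConfusionMatrix(0, 0, 0, 0))


class TestRocCurve:
    def test_perfect_and_tied(self):
        assert roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)
        assert roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_four_pair_example(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs concordant
        auc = roc_curve([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]).auc
        assert auc == pytest.approx(0.75)

    def test_single_class_auc_undefined(self):
        assert roc_curve([0.3, 0.7], [1, 1]).auc is None

    def test_endpoints_and_monotone_x(self):
        c = roc_curve([0.1, 0.9, 0.5, 0.4], [0, 1, 1, 0])
        xs = [p[0] for p in c.points]
        assert c.points[0] == (0.0, 0.0) and c.points[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(xs, xs[1:]))

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            gold = rng.integers(0, 2, size=n)
            if gold.sum() in (0, n):
                gold[0], gold[1] = 0, 1
            # ties made likely by quantizing scores
            scores = np.round(rng.random(n), 1)
            got = roc_curve(scores, gold).auc
            want = pairwise_concordance_auc(scores, gold)
            assert abs(got - want) < 1e-12


class TestPrCurve:
    def test_perfect_scorer(self):
        assert pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_no_positives_undefined(self):
        assert pr_curve([0.5, 0.6], [0, 0]).auc is None

    def test_single_positive_ranked_first(self):
        c = pr_curve([0.9, 0.3, 0.2], [1, 0, 0])
        assert (1.0, 1.0) in c.points

    def test_random_scores_auc_near_prevalence(self):
        rng = np.random.default_rng(7)
        n, prev = 20000, 0.15
        gold = (rng.random(n) < prev).astype(int)
        scores = rng.random(n)
        auc = pr_curve(scores, gold).auc
        assert auc == pytest.approx(prev, abs=0.02)

    def test_recall_ascending_ends_at_one(self):
        c = pr_curve([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0])
        xs = [p[0] for p in c.points]
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert xs[-1] == 1.0


class TestMultilabel:
    def test_hamming_cell_identity(self):
        # 1000 items x 8 classes with exactly 1031 differing cells
        rng = np.random.default_rng(3)
        gold = {f"i{k}": {c for c in CLASSES if rng.random() < 0.3} for k in range(1000)}
        cells = [(f"i{k}", c) for k in range(1000) for c in CLASSES]
        pred = {k: set(v) for k, v in gold.items()}
        for idx in rng.choice(len(cells), size=1031, replace=False):
            cid, c = cells[idx]
            pred[cid] = set(pred[cid]) ^ {c}
        assert hamming_loss(pred, gold, CLASSES) == pytest.approx(1031 / 8000)
        assert round_half_up(100 * hamming_loss(pred, gold, CLASSES), 1) == 12.9

    def test_hamming_trivial_cases(self):
        gold = {"a": {"A"}, "b": {"B", "C"}}
        assert hamming_loss(gold, gold, CLASSES) == 0.0
        complement = {k: set(CLASSES) - v for k, v in gold.items()}
        assert hamming_loss(complement, gold, CLASSES) == 1.0

    def test_hamming_equals_mean_per_class_error(self):
        rng = np.random.default_rng(9)
        gold = {f"i{k}": {c for c in CLASSES if rng.random() < 0.4} for k in range(60)}
        pred = {f"i{k}": {c for c in CLASSES if rng.random() < 0.4} for k in range(60)}
        per_class = []
        for c in CLASSES:
            err = sum(1 for k in gold if (c in pred[k]) != (c in gold[k]))
            per_class.append(err / len(gold))
        assert hamming_loss(pred, gold, CLASSES) == pytest.approx(np.mean(per_class))

    def test_jaccard_and_subset_examples(self):
        jac, sub = jaccard_and_subset({"x": {"A", "B"}}, {"x": {"B", "C"}})
        assert jac == pytest.approx(1 / 3) and sub == 0.0
        gold = {"a": {"A"}, "b": set()}
        assert jaccard_and_subset(gold, gold) == (1.0, 1.0)  # empty/empty counts 1

    def test_subset_never_exceeds_jaccard(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(1, 40))
            gold = {str(k): {c for c in CLASSES if rng.random() < 0.3} for k in range(n)}
            pred = {str(k): {c for c in CLASSES if rng.random() < 0.3} for k in range(n)}
            jac, sub = jaccard_and_subset(pred, gold)
            assert sub <= jac + 1e-12

    def test_averages_match_brute_force_pooling(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            gold = {str(k): {c for c in CLASSES if rng.random() < 0.35} for k in range(n)}
            pred = {str(k): {c for c in CLASSES if rng.random() < 0.35} for k in range(n)}
            rep = multilabel_report(pred, gold, CLASSES)
            micro, macro, weighted = brute_force_f1_pooling(pred, gold, CLASSES)
            assert rep.micro_f1 == pytest.approx(micro)
            assert rep.macro_f1 == pytest.approx(macro)
            assert rep.weighted_f1 == pytest.approx(weighted)

    def test_single_class_collapse(self):
        gold = {"a": {"A"}, "b": set(), "c": {"A"}}
        pred = {"a": {"A"}, "b": {"A"}, "c": set()}
        rep = multilabel_report(pred, gold, ("A",))
        assert rep.micro_f1 == rep.macro_f1 == rep.weighted_f1

    def test_auc_fields_none_without_scores(self):
        gold = {"a": {"A"}, "b": {"B"}}
        rep = multilabel_report(gold, gold, CLASSES)
        assert rep.micro_roc_auc is None and rep.micro_pr_auc is None

    def test_auc_fields_with_scores(self):
        gold = {"a": {"A"}, "b": {"B"}, "c": set()}
        scores = {
            "a": {"A": 0.9, "B": 0.1},
            "b": {"A": 0.2, "B": 0.8},
            "c": {"A": 0.1, "B": 0.2},
        }
        rep = multilabel_report(gold, gold, ("A", "B"), scores)
        assert rep.micro_roc_auc == pytest.approx(1.0)
        assert rep.macro_roc_auc == pytest.approx(1.0)


class TestSummaries:
    def test_prevalence_from_published_counts(self):
        gold = [1] * 107 + [0] * 893
        s = dataset_summary(gold)
        assert s["dde"] == {"count": 107, "percent": 10.7}
        assert s["non_dde"] == {"count": 893, "percent": 89.3}

    def test_zero_positive(self):
        assert dataset_summary([0] * 10)["dde"]["percent"] == 0.0

    def test_frequency_table_percentages(self):
        gold = {f"i{k}": ({"personal_choices"} if k < 670 else {"adverse_reactions"})
                for k in range(1000)}
        t = frequency_table(gold, ("personal_choices", "adverse_reactions"))
        assert t["personal_choices"] == {"count": 670, "percent": 67.0}

    def test_round_half_up(self):
        assert round_half_up(2.5) == 3.0
        assert round_half_up(96.335, 2) == 96.34
        assert round_half_up(0.2667 * 100 / 100, 2) == 0.27
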