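"""Detection strategies: max-aggregation, cutoff semantics, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddekit.detect import (
    CutoffGrid,
    DDEClassifier,
    classify_cs1,
    classify_cs2,
    classify_cs3,
    sweep_cutoffs,
)
from ddekit.io import Comment
from ddekit.metrics import binary_metrics
from ddekit.scorers import (
    ChatBinaryClassifier,
    Hypothesis,
    MockEntailmentScorer,
    ScriptedChatBackend,
)
from ddekit.segment import TokenizerSpec


class FixedScorer:
    """Scores each unit by position in a preset list (cycled by call)."""

    def __init__(self, scores):
        self.scores = list(scores)
        self.i = 0

    def score(self, premise, hypothesis):
        v = self.scores[self.i % len(self.scores)]
        self.i += 1
        return v


COMMENT3 = Comment(id="a", text="First sentence. Second sentence. Third sentence.")


class TestCS1:
    def test_max_over_sentences_and_threshold(self):
        r = classify_cs1(COMMENT3, FixedScorer([0.10, 0.97, 0.30]), cutoff=0.95)
        assert r.unit_scores == (0.10, 0.97, 0.30)
        assert r.model_prediction == 0.97 and r.label == 1

    def test_all_zero_scores_negative(self):
        r = classify_cs1(COMMENT3, FixedScorer([0.0]), cutoff=0.05)
        assert r.label == 0

    def test_tie_at_cutoff_is_negative(self):
        r = classify_cs1(COMMENT3, FixedScorer([0.95]), cutoff=0.95)
        assert r.model_prediction == 0.95 and r.label == 0

    def test_empty_comment_prediction_zero(self):
        r = classify_cs1(Comment(id="e", text=""), FixedScorer([0.9]), cutoff=0.5)
        assert r.unit_scores == () and r.model_prediction == 0.0 and r.label == 0

    def test_or_equivalence_with_per_sentence_labels(self):
        # comment-level label == OR of per-sentence thresholded labels
        rng = np.random.default_rng(5)
        scorer = MockEntailmentScorer({"quit": 0.9}, noise=0.3, seed=9)
        hyp = Hypothesis(text="x", label="dde")
        for k in range(200):
            n_sent = rng.integers(1, 6)
            sents = [
                ("I quit " if rng.random() < 0.3 else "Nothing ") + f"unit {k} {j}."
                for j in range(n_sent)
            ]
            comment = Comment(id=str(k), text=" ".join(sents))
            for cutoff in (0.05, 0.5, 0.89, 0.9):
                r = classify_cs1(comment, scorer, hyp, cutoff=cutoff)
                # brute-force per-sentence classifier: label each unit, then OR
                per_sentence = [int(u > cutoff) for u in r.unit_scores]
                assert r.label == int(any(per_sentence))
                assert len(r.unit_scores) == n_sent

    def test_permutation_invariance_of_prediction(self):
        scorer = MockEntailmentScorer({"quit": 0.9})
        a = Comment(id="a", text="I quit lipitor. The sky is blue.")
        b = Comment(id="b", text="The sky is blue. I quit lipitor.")
        assert (
            classify_cs1(a, scorer).model_prediction
            == classify_cs1(b, scorer).model_prediction
        )


class TestCS2:
    def test_high_chunk_score_exceeds_cutoff(self):
        r = classify_cs2(COMMENT3, FixedScorer([0.994]), cutoff=0.95,
                         spec=TokenizerSpec(max_tokens=500))
        assert r.label == 1

    def test_single_chunk_equals_whole_comment_scoring(self):
        scorer = MockEntailmentScorer({"second": 0.8})
        r = classify_cs2(COMMENT3, scorer, cutoff=0.5,
                         spec=TokenizerSpec(max_tokens=500))
        assert len(r.unit_scores) == 1 and r.unit_scores[0] == 0.8

    def test_tiny_budget_still_total(self):
        r = classify_cs2(COMMENT3, FixedScorer([0.2]), cutoff=0.5,
                         spec=TokenizerSpec(max_tokens=1))
        assert r.label in (0, 1) and len(r.unit_scores) >= 3

    def test_cs1_cs2_score_same_sentence_partition(self, small_corpus, clean_scorer):
        spec = TokenizerSpec(max_tokens=30)
        for comment in small_corpus.comments[:20]:
            r1 = classify_cs1(comment, clean_scorer, cutoff=0.5, spec=spec)
            r2 = classify_cs2(comment, clean_scorer, cutoff=0.5, spec=spec)
            assert len(r2.unit_scores) <= max(1, len(r1.unit_scores))


class TestCS3:
    def test_binary_answers(self):
        chat = ChatBinaryClassifier(ScriptedChatBackend({"I quit": "1"}, default="0"))
        r = classify_cs3(Comment(id="a", text="I quit lipitor"), chat)
        assert r.label == 1 and r.unit_scores == () and r.cutoff is None
        r0 = classify_cs3(Comment(id="b", text="nothing"), chat)
        assert r0.label == 0

    def test_persistent_garbage_recorded_missing(self):
        chat = ChatBinaryClassifier(ScriptedChatBackend(lambda p: "???"))
        r = classify_cs3(Comment(id="a", text="x"), chat)
        assert r.label is None


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        clf = DDEClassifier(strategy="cs2", cutoff=0.9)
        params = clf.get_params()
        assert params["strategy"] == "cs2" and params["cutoff"] == 0.9
        clf.set_params(cutoff=0.3)
        assert clf.cutoff == 0.3

    def test_predict_and_decision_function(self, small_corpus, clean_scorer):
        clf = DDEClassifier(scorer=clean_scorer, cutoff=0.5).fit()
        X = list(small_corpus.comments)
        scores = clf.decision_function(X)
        pred = clf.predict(X)
        assert np.array_equal(pred, (scores > 0.5).astype(int))

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            DDEClassifier(scorer=object(), strategy="cs9").fit()

    def test_cs3_missing_raises_in_predict(self):
        chat = ChatBinaryClassifier(ScriptedChatBackend(lambda p: "???"))
        clf = DDEClassifier(scorer=chat, strategy="cs3").fit()
        with pytest.raises(Exception, match="parseable"):
            clf.predict([Comment(id="a", text="x")])
        assert clf.predict_results([Comment(id="a", text="x")])[0].label is None
        assert clf.n_missing_ == 1


class TestSweep:
    def test_small_example(self):
        preds = {"a": 0.2, "b": 0.8}
        gold = {"a": 0, "b": 1}
        rows = dict(sweep_cutoffs(preds, gold))
        cm = rows[0.5]
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)
        assert rows[0.9].fn == 1

    def test_default_grid_has_19_values(self):
        grid = CutoffGrid()
        assert len(grid.values) == 19
        assert grid.values[0] == 0.05 and grid.values[-1] == 0.95

    def test_id_mismatch_lists_orphans(self):
        with pytest.raises(ValueError, match="orphans"):
            sweep_cutoffs({"a": 0.5}, {"b": 1})

    @given(st.lists(st.tuples(st.floats(0, 1), st.integers(0, 1)),
                    min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_monotone_rates_in_cutoff(self, items):
        preds = {str(i): s for i, (s, _) in enumerate(items)}
        gold = {str(i): g for i, (_, g) in enumerate(items)}
        rows = sweep_cutoffs(preds, gold)
        prev_pos = prev_tpr = prev_fpr = None
        for _, cm in rows:
            pos = cm.tp + cm.fp
            m = binary_metrics(cm)
            if prev_pos is not None:
                assert pos <= prev_pos
                assert m.tpr <= prev_tpr + 1e-12
                assert m.fpr <= prev_fpr + 1e-12
            prev_pos, prev_tpr, prev_fpr = pos, m.tpr, m.fpr

    def test_grid_must_ascend_in_open_interval(self):
        with pytest.raises(ValueError):
            CutoffGrid(values=(0.5, 0.4))
        with pytest.raises(ValueError):
            CutoffGrid(values=(0.0, 0.5))
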