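"""Binary drug-discontinuation-event detection.

Three classification strategies share one max-aggregation scheme:

* CS1 — every sentence is scored individually against the hypothesis; the
  comment's "model prediction" is the maximum sentence score.
* CS2 — consecutive sentences are packed into token-budget chunks
  (see :mod:`ddekit.segment`); the prediction is the maximum chunk score.
* CS3 — the entire comment goes through a chat backend that answers a hard
  1/0; no graded score exists, so no threshold sweep applies.

A comment is labeled DDE when its prediction strictly exceeds the cutoff
(ties classify negative). ``DDEClassifier`` wraps the strategies as a
scikit-learn estimator; the module-level ``classify_cs1/cs2/cs3`` functions
are thin conveniences over it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import Comment
from .metrics import ConfusionMatrix
from .scorers import (
    ChatBinaryClassifier,
    EntailmentScorer,
    Hypothesis,
    DEFAULT_HYPOTHESIS,
    ScorerError,
)
from .segment import TokenizerSpec, group_sentences, split_sentences

__all__ = [
    "DetectionResult",
    "CutoffGrid",
    "DDEClassifier",
    "classify_cs1",
    "classify_cs2",
    "classify_cs3",
    "sweep_cutoffs",
]

STRATEGIES = ("cs1", "cs2", "cs3")


@dataclass(frozen=True)
class DetectionResult:
    """Per-comment detection outcome.

    ``unit_scores`` holds one entailment score per sentence (CS1) or chunk
    (CS2) and is empty for CS3. ``model_prediction`` is their maximum (0.0
    for an empty comment); for CS3 it is the parsed binary answer. ``label``
    is ``None`` when a chat backend never produced a parseable answer — a
    recorded missing prediction, excluded (with a count) from metrics.
    """

    comment_id: str
    strategy: str
    unit_scores: tuple[float, ...]
    model_prediction: float
    cutoff: float | None
    label: int | None


@dataclass(frozen=True)
class CutoffGrid:
    """Ascending thresholds; default 0.05..0.95 in steps of 0.05.

    Values are generated from integer numerators over 100 so comparisons
    are not perturbed by float accumulation.
    """

    values: tuple[float, ...] = tuple(float(Fraction(k, 100)) for k in range(5, 100, 5))

    def __post_init__(self) -> None:
        vals = self.values
        if not vals or any(not 0.0 < v < 1.0 for v in vals):
            raise ValueError("grid values must lie in (0, 1)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid values must be strictly ascending")


def _validate_cutoff(cutoff: float) -> float:
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    return float(cutoff)


def _score_units(
    comment: Comment,
    texts: Sequence[str],
    scorer: EntailmentScorer,
    hypothesis: Hypothesis,
) -> tuple[float, ...]:
    scores = []
    for text in texts:
        try:
            scores.append(float(scorer.score(text, hypothesis)))
        except ScorerError as exc:
            raise ScorerError(
                f"scorer failed on comment {comment.id!r}: {exc}", kind=exc.kind
            ) from exc
    return tuple(scores)


def classify_cs1(
    comment: Comment,
    scorer: EntailmentScorer,
    hypothesis: Hypothesis = DEFAULT_HYPOTHESIS,
    cutoff: float = 0.5,
    spec: TokenizerSpec = TokenizerSpec(),
) -> DetectionResult:
    """Score each sentence individually; label by max > cutoff."""
    cutoff = _validate_cutoff(cutoff)
    sentences = split_sentences(comment.text, spec)
    scores = _score_units(comment, [s.text.strip() for s in sentences], scorer, hypothesis)
    pred = max(scores) if scores else 0.0
    return DetectionResult(
        comment_id=comment.id,
        strategy="cs1",
        unit_scores=scores,
        model_prediction=pred,
        cutoff=cutoff,
        label=int(pred > cutoff),
    )


def classify_cs2(
    comment: Comment,
    scorer: EntailmentScorer,
    hypothesis: Hypothesis = DEFAULT_HYPOTHESIS,
    cutoff: float = 0.5,
    spec: TokenizerSpec = TokenizerSpec(),
) -> DetectionResult:
    """Score token-budget chunks of consecutive sentences; label by max > cutoff."""
    cutoff = _validate_cutoff(cutoff)
    chunks = group_sentences(split_sentences(comment.text, spec), spec)
    scores = _score_units(comment, [c.text for c in chunks], scorer, hypothesis)
    pred = max(scores) if scores else 0.0
    return DetectionResult(
        comment_id=comment.id,
        strategy="cs2",
        unit_scores=scores,
        model_prediction=pred,
        cutoff=cutoff,
        label=int(pred > cutoff),
    )


def classify_cs3(comment: Comment, chat: ChatBinaryClassifier) -> DetectionResult:
    """Whole-comment binary classification through a chat backend."""
    label = chat.classify(comment.text)
    return DetectionResult(
        comment_id=comment.id,
        strategy="cs3",
        unit_scores=(),
        model_prediction=float(label) if label is not None else float("nan"),
        cutoff=None,
        label=label,
    )


class DDEClassifier(BaseEstimator, ClassifierMixin):
    """Zero-shot drug-discontinuation-event detector.

    Parameters
    ----------
    scorer : EntailmentScorer or ChatBinaryClassifier
        Entailment backend for ``cs1``/``cs2``; a chat binary classifier
        for ``cs3``.
    strategy : {"cs1", "cs2", "cs3"}
        Aggregation unit: sentences, token-budget chunks, or whole comment.
    hypothesis : Hypothesis
        Statement whose entailment is scored. Results are sensitive to this
        wording; it is configuration, never hard-coded.
    cutoff : float
        Threshold on the max unit score; strict ``>`` (ties negative).
        Ignored for ``cs3``.
    tokenizer_spec : TokenizerSpec
        Token-counting scheme and budget used for CS2 chunking (and
        sentence token counts generally).

    The estimator is zero-shot: ``fit`` only validates parameters and
    records classes. ``X`` may be a sequence of :class:`~ddekit.io.Comment`
    or raw strings (ids are synthesized positionally for strings).
    """

    def __init__(
        self,
        scorer=None,
        strategy: str = "cs1",
        hypothesis: Hypothesis = DEFAULT_HYPOTHESIS,
        cutoff: float = 0.5,
        tokenizer_spec: TokenizerSpec = TokenizerSpec(),
    ) -> None:
        self.scorer = scorer
        self.strategy = strategy
        self.hypothesis = hypothesis
        self.cutoff = cutoff
        self.tokenizer_spec = tokenizer_spec

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X=None, y=None) -> "DDEClassifier":
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if self.scorer is None:
            raise ValueError("a scorer backend is required")
        if self.strategy == "cs3" and not isinstance(self.scorer, ChatBinaryClassifier):
            raise ValueError("cs3 requires a ChatBinaryClassifier scorer")
        _validate_cutoff(self.cutoff)
        self.classes_ = np.array([0, 1])
        self.n_missing_ = 0
        return self

    @staticmethod
    def _as_comments(X) -> list[Comment]:
        out = []
        for i, x in enumerate(X):
            out.append(x if isinstance(x, Comment) else Comment(id=str(i), text=str(x)))
        return out

    def predict_results(self, X) -> list[DetectionResult]:
        """Full per-comment results (unit scores, prediction, label)."""
        if not hasattr(self, "classes_"):
            self.fit()
        results = []
        for c in self._as_comments(X):
            if self.strategy == "cs1":
                results.append(classify_cs1(c, self.scorer, self.hypothesis,
                                            self.cutoff, self.tokenizer_spec))
            elif self.strategy == "cs2":
                results.append(classify_cs2(c, self.scorer, self.hypothesis,
                                            self.cutoff, self.tokenizer_spec))
            else:
                results.append(classify_cs3(c, self.scorer))
        self.n_missing_ = sum(1 for r in results if r.label is None)
        return results

    def decision_function(self, X) -> np.ndarray:
        """Per-comment model prediction (max unit score; NaN when missing)."""
        return np.array([r.model_prediction for r in self.predict_results(X)])

    def predict(self, X) -> np.ndarray:
        """Binary labels. Missing chat predictions raise; use
        ``predict_results`` to retrieve and report them explicitly."""
        results = self.predict_results(X)
        missing = [r.comment_id for r in results if r.label is None]
        if missing:
            raise ScorerError(
                f"{len(missing)} comment(s) with no parseable chat answer: "
                f"{missing[:5]}", kind="transport",
            )
        return np.array([r.label for r in results])


def sweep_cutoffs(
    predictions: Mapping[str, float],
    gold: Mapping[str, int],
    grid: CutoffGrid = CutoffGrid(),
) -> list[tuple[float, ConfusionMatrix]]:
    """Threshold the per-comment predictions at every grid value.

    Scores are computed once and thresholded many times with the strict
    ``>`` rule. Prediction and gold ids must match exactly; orphans on
    either side are an error.
    """
    pred_ids, gold_ids = set(predictions), set(gold)
    if pred_ids != gold_ids:
        orphans = sorted(pred_ids ^ gold_ids)
        raise ValueError(f"prediction/gold id mismatch, orphans: {orphans[:10]}")
    out = []
    for cutoff in grid.values:
        tp = fp = fn = tn = 0
        for cid, score in predictions.items():
            pred, truth = int(score > cutoff), gold[cid]
            if truth == 1:
                tp, fn = tp + pred, fn + (1 - pred)
            else:
                fp, tn = fp + pred, tn + (1 - pred)
        out.append((cutoff, ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)))
    return out
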