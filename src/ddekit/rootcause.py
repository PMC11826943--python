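"""Multilabel root-cause classification over the closed 8-category taxonomy.

Why a comment's author stopped a medication falls into exactly eight
categories: treatment success, treatment inefficacy, adverse reactions,
accessibility issues, personal choices, alternative medical reasons,
indeterminate, and non-discontinuation. A comment may carry several
(someone can stop one drug over side effects and another over cost), so
this is multilabel: under CS1/CS2 each category has its own hypothesis and
the per-category score is the max over sentences/chunks — union semantics
over sentences follow from the max. Under CS3 a chat backend summarizes
the comment and lists applicable category names, parsed closed-world.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import Comment
from .scorers import (
    ChatBackend,
    EntailmentScorer,
    Hypothesis,
    ScorerError,
    UnparseableResponse,
)
from .segment import TokenizerSpec, group_sentences, split_sentences

__all__ = [
    "ROOT_CAUSE_CATEGORIES",
    "CATEGORY_DISPLAY_NAMES",
    "CategoryHypotheses",
    "RootCauseSet",
    "RootCauseClassifier",
    "ChatRootCauseClassifier",
    "classify_rootcause_cs1",
    "classify_rootcause_cs2",
    "classify_rootcause_cs3",
    "build_rootcause_prompt",
    "parse_rootcause_response",
]

# closed enumeration, fixed order
ROOT_CAUSE_CATEGORIES: tuple[str, ...] = (
    "treatment_success",
    "treatment_inefficacy",
    "adverse_reactions",
    "accessibility_issues",
    "personal_choices",
    "alternative_medical_reasons",
    "indeterminate",
    "non_discontinuation",
)

CATEGORY_DISPLAY_NAMES: dict[str, str] = {
    "treatment_success": "Treatment success",
    "treatment_inefficacy": "Treatment inefficacy",
    "adverse_reactions": "Adverse reactions",
    "accessibility_issues": "Accessibility issues",
    "personal_choices": "Personal choices",
    "alternative_medical_reasons": "Alternative medical reasons",
    "indeterminate": "Indeterminate",
    "non_discontinuation": "Nondiscontinuation",
}

# default hypotheses written from the category definitions; every one is
# configuration and can be overridden per run
DEFAULT_CATEGORY_HYPOTHESES: dict[str, str] = {
    "treatment_success": (
        "This person stopped a medication because the treatment succeeded "
        "or their health improved enough."
    ),
    "treatment_inefficacy": (
        "This person stopped a medication because it was not working or "
        "they lost belief in its effectiveness."
    ),
    "adverse_reactions": (
        "This person stopped a medication because of side effects, an "
        "allergic reaction, or a bad interaction with another drug."
    ),
    "accessibility_issues": (
        "This person stopped a medication because of cost, insurance, "
        "availability, or a prescriber's decision."
    ),
    "personal_choices": (
        "This person stopped a medication by personal decision, cultural "
        "or religious reasons, or general nonadherence without medical advice."
    ),
    "alternative_medical_reasons": (
        "This person stopped a medication for another medical reason not "
        "covered by the other categories."
    ),
    "indeterminate": (
        "This person stopped a medication for an unclear or unspecified reason."
    ),
    "non_discontinuation": (
        "This text does not indicate that anyone stopped a medication."
    ),
}


@dataclass(frozen=True)
class CategoryHypotheses:
    """Per-category hypothesis text and cutoff; all 8 categories present.

    One global cutoff applies unless overridden per category.
    """

    hypotheses: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_HYPOTHESES)
    )
    cutoffs: Mapping[str, float] = field(default_factory=dict)
    default_cutoff: float = 0.5

    def __post_init__(self) -> None:
        missing = set(ROOT_CAUSE_CATEGORIES) - set(self.hypotheses)
        if missing:
            raise ValueError(f"missing hypotheses for: {sorted(missing)}")
        unknown = set(self.hypotheses) - set(ROOT_CAUSE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        for c, v in {**{c: self.default_cutoff for c in ROOT_CAUSE_CATEGORIES},
                     **self.cutoffs}.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"cutoff for {c} must be in [0, 1]")

    def cutoff(self, category: str) -> float:
        return float(self.cutoffs.get(category, self.default_cutoff))

    def hypothesis(self, category: str) -> Hypothesis:
        return Hypothesis(text=self.hypotheses[category], label=category)


@dataclass(frozen=True)
class RootCauseSet:
    """Predicted root-cause subset for one comment.

    For CS1/CS2, ``per_category_scores`` holds every category's max score
    and membership means score strictly above that category's cutoff. For
    CS3 scores are empty and ``categories`` is ``None`` when the chat
    backend never produced a parseable list (a recorded missing
    prediction).
    """

    comment_id: str
    strategy: str
    categories: frozenset[str] | None
    per_category_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.categories is not None:
            unknown = set(self.categories) - set(ROOT_CAUSE_CATEGORIES)
            if unknown:
                raise ValueError(f"categories outside the taxonomy: {sorted(unknown)}")


def _max_scores(
    comment: Comment,
    unit_texts: Sequence[str],
    scorer: EntailmentScorer,
    hyps: CategoryHypotheses,
) -> dict[str, float]:
    scores: dict[str, float] = {}
    for cat in ROOT_CAUSE_CATEGORIES:
        hyp = hyps.hypothesis(cat)
        best = 0.0
        for text in unit_texts:
            try:
                best = max(best, float(scorer.score(text, hyp)))
            except ScorerError as exc:
                raise ScorerError(
                    f"scorer failed on comment {comment.id!r}, category {cat}: {exc}",
                    kind=exc.kind,
                ) from exc
        scores[cat] = best
    return scores


def _threshold(scores: Mapping[str, float], hyps: CategoryHypotheses) -> frozenset[str]:
    return frozenset(c for c, s in scores.items() if s > hyps.cutoff(c))


def classify_rootcause_cs1(
    comment: Comment,
    scorer: EntailmentScorer,
    hyps: CategoryHypotheses = CategoryHypotheses(),
    spec: TokenizerSpec = TokenizerSpec(),
) -> RootCauseSet:
    """Per-sentence scoring; the comment's set is the union over sentences."""
    sentences = [s.text.strip() for s in split_sentences(comment.text, spec)]
    scores = _max_scores(comment, sentences, scorer, hyps)
    return RootCauseSet(
        comment_id=comment.id, strategy="cs1",
        categories=_threshold(scores, hyps), per_category_scores=scores,
    )


def classify_rootcause_cs2(
    comment: Comment,
    scorer: EntailmentScorer,
    hyps: CategoryHypotheses = CategoryHypotheses(),
    spec: TokenizerSpec = TokenizerSpec(),
) -> RootCauseSet:
    """Per-chunk scoring under the token budget; max over chunks per category."""
    chunks = [c.text for c in group_sentences(split_sentences(comment.text, spec), spec)]
    scores = _max_scores(comment, chunks, scorer, hyps)
    return RootCauseSet(
        comment_id=comment.id, strategy="cs2",
        categories=_threshold(scores, hyps), per_category_scores=scores,
    )


def build_rootcause_prompt(comment_text: str) -> str:
    """Summarize-then-list prompt enumerating the category names verbatim."""
    names = "; ".join(CATEGORY_DISPLAY_NAMES[c] for c in ROOT_CAUSE_CATEGORIES)
    return (
        "You will read one comment from a health forum in which a person "
        "may have stopped taking a medication.\n"
        "First, briefly summarize the reasons for discontinuation, if any.\n"
        "Then, on a final line starting with 'Categories:', list every "
        "applicable root-cause category from this closed list, separated "
        f"by commas, using the exact names: {names}.\n"
        "Comment:\n"
        f"{comment_text}\n"
    )


_NAME_TO_CATEGORY = {
    re.sub(r"[^a-z]", "", name.lower()): cat
    for cat, name in CATEGORY_DISPLAY_NAMES.items()
}
# also accept the snake_case identifiers themselves
_NAME_TO_CATEGORY.update(
    {re.sub(r"[^a-z]", "", c): c for c in ROOT_CAUSE_CATEGORIES}
)


def parse_rootcause_response(raw: str) -> frozenset[str]:
    """Map a chat response's category list onto the closed taxonomy.

    Names are matched case- and whitespace-insensitively but must
    otherwise be exact; an unrecognized name makes the whole response
    unparseable (closed-world: no fuzzy assignment).
    """
    text = raw
    m = re.search(r"categories\s*:\s*(.*)", raw, flags=re.IGNORECASE | re.DOTALL)
    if m:
        text = m.group(1)
    parts = [p for p in re.split(r"[,\n;]+", text) if p.strip()]
    if not parts:
        raise UnparseableResponse(raw)
    cats: set[str] = set()
    for part in parts:
        key = re.sub(r"[^a-z]", "", part.lower())
        if key in ("none", ""):
            continue
        if key not in _NAME_TO_CATEGORY:
            raise UnparseableResponse(raw)
        cats.add(_NAME_TO_CATEGORY[key])
    return frozenset(cats)


class ChatRootCauseClassifier:
    """Whole-comment summarize-then-list root-cause labeling via chat."""

    def __init__(self, backend: ChatBackend, *, retries: int = 2) -> None:
        self.backend = backend
        self.retries = retries

    def classify(self, comment_text: str) -> frozenset[str] | None:
        prompt = build_rootcause_prompt(comment_text)
        for _ in range(self.retries + 1):
            try:
                return parse_rootcause_response(self.backend.complete(prompt))
            except UnparseableResponse:
                continue
        return None


def classify_rootcause_cs3(
    comment: Comment, chat: ChatRootCauseClassifier
) -> RootCauseSet:
    """Entire comment through the chat backend; missing when unparseable."""
    cats = chat.classify(comment.text)
    return RootCauseSet(comment_id=comment.id, strategy="cs3", categories=cats)


class RootCauseClassifier(BaseEstimator, ClassifierMixin):
    """Multilabel zero-shot root-cause classifier.

    Parameters
    ----------
    scorer : EntailmentScorer or ChatRootCauseClassifier
        Entailment backend for ``cs1``/``cs2``; a chat classifier for ``cs3``.
    strategy : {"cs1", "cs2", "cs3"}
    hypotheses : CategoryHypotheses
        Per-category hypothesis texts and cutoffs (CS1/CS2 only).
    tokenizer_spec : TokenizerSpec

    ``predict`` returns an (n_items, 8) binary indicator array with columns
    ordered as ``ROOT_CAUSE_CATEGORIES``; ``predict_sets`` returns the raw
    per-comment results including recorded-missing CS3 predictions.
    """

    def __init__(
        self,
        scorer=None,
        strategy: str = "cs1",
        hypotheses: CategoryHypotheses = CategoryHypotheses(),
        tokenizer_spec: TokenizerSpec = TokenizerSpec(),
    ) -> None:
        self.scorer = scorer
        self.strategy = strategy
        self.hypotheses = hypotheses
        self.tokenizer_spec = tokenizer_spec

    def fit(self, X=None, y=None) -> "RootCauseClassifier":
        if self.strategy not in ("cs1", "cs2", "cs3"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.scorer is None:
            raise ValueError("a scorer backend is required")
        if self.strategy == "cs3" and not isinstance(self.scorer, ChatRootCauseClassifier):
            raise ValueError("cs3 requires a ChatRootCauseClassifier scorer")
        self.classes_ = np.array(ROOT_CAUSE_CATEGORIES)
        self.n_missing_ = 0
        return self

    @staticmethod
    def _as_comments(X) -> list[Comment]:
        return [x if isinstance(x, Comment) else Comment(id=str(i), text=str(x))
                for i, x in enumerate(X)]

    def predict_sets(self, X) -> list[RootCauseSet]:
        if not hasattr(self, "classes_"):
            self.fit()
        out = []
        for c in self._as_comments(X):
            if self.strategy == "cs1":
                out.append(classify_rootcause_cs1(c, self.scorer, self.hypotheses,
                                                  self.tokenizer_spec))
            elif self.strategy == "cs2":
                out.append(classify_rootcause_cs2(c, self.scorer, self.hypotheses,
                                                  self.tokenizer_spec))
            else:
                out.append(classify_rootcause_cs3(c, self.scorer))
        self.n_missing_ = sum(1 for r in out if r.categories is None)
        return out

    def decision_function(self, X) -> np.ndarray:
        """(n_items, 8) per-category max scores (CS1/CS2 only)."""
        if self.strategy == "cs3":
            raise ScorerError(
                "cs3 produces hard category sets, not graded scores"
            )
        sets = self.predict_sets(X)
        return np.array(
            [[r.per_category_scores[c] for c in ROOT_CAUSE_CATEGORIES] for r in sets]
        )

    def predict(self, X) -> np.ndarray:
        sets = self.predict_sets(X)
        missing = [r.comment_id for r in sets if r.categories is None]
        if missing:
            raise ScorerError(
                f"{len(missing)} comment(s) with no parseable category list: "
                f"{missing[:5]}", kind="transport",
            )
        return np.array(
            [[int(c in r.categories) for c in ROOT_CAUSE_CATEGORIES] for r in sets]
        )
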