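"""Synthetic forum-corpus generator with a matched mock scorer.

Generates desk-scale corpora that copy the statistical structure of the
labeled forum dataset — multi-sentence comments, ~10.7% discontinuation
prevalence, multilabel root-cause frequencies matching the observed
marginals, and hard negatives like "I am not on any medication" — with
planted gold labels. Discontinuation comments embed cue sentences whose
phrases a :class:`~ddekit.scorers.MockEntailmentScorer` recognizes, so at
zero noise the full pipeline recovers the gold labels exactly, and at
noise eps the comment-level error rates have closed forms against which
the measured rates can be checked. The generator exercises plumbing and
statistics; realism of register is a non-goal.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .io import Comment, GoldBinaryLabel, GoldRootCauseLabel, Lexicon
from .rootcause import ROOT_CAUSE_CATEGORIES
from .scorers import MockEntailmentScorer

__all__ = [
    "SyntheticConfig",
    "SyntheticCorpus",
    "generate",
    "matched_mock_scorer",
    "naive_cue_table",
    "closed_form_detection_error",
    "default_lexicon",
]

MANIFEST_VERSION = 1
CUE_SCORE = 0.9
DETECTION_CUE = "stopped taking"

# observed per-1000 occurrence counts in the labeled root-cause dataset
_TABLE_WEIGHTS = {
    "personal_choices": 0.670,
    "adverse_reactions": 0.627,
    "alternative_medical_reasons": 0.418,
    "treatment_inefficacy": 0.250,
    "accessibility_issues": 0.119,
    "indeterminate": 0.103,
    "non_discontinuation": 0.100,
    "treatment_success": 0.096,
}

_DRUGS = [
    "lipitor", "metformin", "prozac", "zoloft", "lisinopril", "synthroid",
    "amoxicillin", "gabapentin", "omeprazole", "atenolol", "warfarin",
    "sertraline", "ibuprofen", "prednisone", "tramadol", "citalopram",
]

# each category cue phrase is unique, never appears in backgrounds or hard
# negatives, and never contains the detection cue
_CATEGORY_PHRASES = {
    "treatment_success": "because i was finally cured",
    "treatment_inefficacy": "because it simply did not work",
    "adverse_reactions": "because of the awful side effects",
    "accessibility_issues": "because i could not afford the refill",
    "personal_choices": "because i just decided on my own",
    "alternative_medical_reasons": "because of an unrelated medical condition",
    "indeterminate": "for reasons i would rather not say",
    "non_discontinuation": "although nobody here quit any treatment",
}

_ADJECTIVES = ["tired", "dizzy", "anxious", "hopeful", "restless", "fine", "sore", "weak"]
_RELATIVES = ["sister", "brother", "mother", "father", "neighbor", "cousin", "friend"]
_PLACES = ["downtown", "county", "village", "riverside", "hilltop", "community"]
_HARD_NEGATIVES = [
    "I am not on any medication at the moment, number {n}.",
    "Right now I am not taking any medication at all, case {n}.",
    "My doctor confirmed I am not on any medication, visit {n}.",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults copy the labeled dataset's structure: 10.7% discontinuation
    prevalence and per-category inclusion probabilities proportional to
    the observed root-cause marginals. ``seed`` fully determines output.
    """

    n_comments: int = 1000
    dde_prevalence: float = 0.107
    rootcause_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_TABLE_WEIGHTS)
    )
    sentences_per_comment: tuple[int, int] = (2, 6)
    hard_negative_rate: float = 0.1
    noise: float = 0.0
    seed: int = 0
    disagreement_rate: float = 0.089
    confidence_weights: tuple[float, float, float] = (0.9633, 0.034, 0.0027)

    def __post_init__(self) -> None:
        if self.n_comments < 1:
            raise ValueError("n_comments must be positive")
        if not 0.0 <= self.dde_prevalence <= 1.0:
            raise ValueError("dde_prevalence must be in [0, 1]")
        if not 0.0 <= self.hard_negative_rate <= 1.0:
            raise ValueError("hard_negative_rate must be in [0, 1]")
        for c, w in self.rootcause_weights.items():
            if c not in ROOT_CAUSE_CATEGORIES:
                raise ValueError(f"unknown root-cause category {c!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {c} must be in [0, 1]")
        lo, hi = self.sentences_per_comment
        if lo < 1 or hi < lo:
            raise ValueError("sentences_per_comment must be a valid (lo, hi) range")


@dataclass(frozen=True)
class SyntheticCorpus:
    comments: tuple[Comment, ...]
    gold_binary: tuple[GoldBinaryLabel, ...]
    gold_rootcause: tuple[GoldRootCauseLabel, ...]
    manifest: dict

    def corpus_hash(self) -> str:
        payload = json.dumps(
            [[c.id, c.text, c.source] for c in self.comments]
            + [[g.comment_id, list(g.labels), list(g.confidences)] for g in self.gold_binary]
            + [[g.comment_id, sorted(g.categories)] for g in self.gold_rootcause],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def default_lexicon() -> Lexicon:
    """Drug-keyword lexicon covering every drug name the generator emits."""
    return Lexicon(terms=frozenset(_DRUGS))


class _UniqueSentences:
    """Sentence factory that never emits the same text twice in a corpus.

    Uniqueness keeps the mock scorer's per-sentence hash-based noise flips
    independent across sentences, which the closed-form comment-level
    error rates assume.
    """

    def __init__(self, rng: random.Random) -> None:
        self.rng = rng
        self.seen: set[str] = set()

    def _fresh(self, make) -> str:
        for _ in range(1000):
            s = make()
            if s not in self.seen:
                self.seen.add(s)
                return s
        raise RuntimeError("could not generate a unique sentence")

    def detection_cue(self) -> str:
        return self._fresh(lambda: (
            f"I {DETECTION_CUE} {self.rng.choice(_DRUGS)} about "
            f"{self.rng.randrange(1, 10000)} days ago."
        ))

    def category_cue(self, category: str) -> str:
        phrase = _CATEGORY_PHRASES[category]
        return self._fresh(lambda: (
            f"It was {phrase}, as I told my {self.rng.choice(_RELATIVES)} "
            f"on day {self.rng.randrange(1, 10000)}."
        ))

    def background(self) -> str:
        makers = [
            lambda: (f"I have been feeling {self.rng.choice(_ADJECTIVES)} for "
                     f"{self.rng.randrange(1, 10000)} days."),
            lambda: (f"My {self.rng.choice(_RELATIVES)} visited the "
                     f"{self.rng.choice(_PLACES)} clinic on day "
                     f"{self.rng.randrange(1, 10000)}."),
            lambda: (f"I still take {self.rng.choice(_DRUGS)} every morning, "
                     f"week {self.rng.randrange(1, 10000)}."),
            lambda: (f"The {self.rng.choice(_PLACES)} pharmacy was busy on day "
                     f"{self.rng.randrange(1, 10000)}."),
        ]
        return self._fresh(self.rng.choice(makers))

    def hard_negative(self) -> str:
        tpl = self.rng.choice(_HARD_NEGATIVES)
        return self._fresh(lambda: tpl.format(n=self.rng.randrange(1, 10000)))


def _sample_categories(rng: random.Random, weights: Mapping[str, float]) -> frozenset[str]:
    # independent inclusion per category, at least one forced by a
    # weight-proportional draw
    cats = {c for c, w in weights.items() if rng.random() < w}
    if not cats:
        pool = [c for c, w in weights.items() if w > 0] or list(ROOT_CAUSE_CATEGORIES)
        wts = [weights.get(c, 0.0) or 1.0 for c in pool]
        cats = {rng.choices(pool, weights=wts, k=1)[0]}
    return frozenset(cats)


def _annotators(
    rng: random.Random, truth: int, config: SyntheticConfig
) -> tuple[tuple[int, ...], tuple[str, ...]]:
    labels = [truth, truth, truth]
    if rng.random() < config.disagreement_rate:
        labels[rng.randrange(3)] = 1 - truth
    levels = ("very_confident", "somewhat_confident", "not_confident")
    confs = tuple(
        rng.choices(levels, weights=config.confidence_weights, k=1)[0] for _ in range(3)
    )
    return tuple(labels), confs


def generate(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus with exactly ``round(n * prevalence)`` positives.

    Deterministic in the seed: the same config yields byte-identical
    corpora. Every discontinuation comment carries one detection-cue
    sentence plus one cue sentence per sampled root cause; non-DDE
    comments are background sentences, a configurable fraction of them
    containing the negated-medication hard-negative phrasing.
    """
    rng = random.Random(config.seed)
    sentences = _UniqueSentences(rng)
    n = config.n_comments
    n_pos = round(n * config.dde_prevalence)
    pos_positions = set(rng.sample(range(n), n_pos))

    comments: list[Comment] = []
    gold_binary: list[GoldBinaryLabel] = []
    gold_rootcause: list[GoldRootCauseLabel] = []
    structure: list[dict] = []
    lo, hi = config.sentences_per_comment

    for i in range(n):
        cid = f"c{i:06d}"
        is_dde = i in pos_positions
        target_len = rng.randint(lo, hi)
        sents: list[str] = []
        if is_dde:
            cats = _sample_categories(rng, config.rootcause_weights)
            sents.append(sentences.detection_cue())
            for cat in sorted(cats):
                sents.append(sentences.category_cue(cat))
            while len(sents) < target_len:
                sents.append(sentences.background())
            gold_rootcause.append(GoldRootCauseLabel(comment_id=cid, categories=cats))
        else:
            hard = rng.random() < config.hard_negative_rate
            while len(sents) < target_len:
                sents.append(sentences.background())
            if hard:
                sents[rng.randrange(len(sents))] = sentences.hard_negative()
        rng.shuffle(sents)
        text = " ".join(sents)
        n_cue = sum(1 for s in sents if DETECTION_CUE in s.lower())
        comments.append(Comment(id=cid, text=text, source="synthetic"))
        labels, confs = _annotators(rng, int(is_dde), config)
        gold_binary.append(
            GoldBinaryLabel(comment_id=cid, labels=labels, confidences=confs)
        )
        structure.append(
            {"id": cid, "is_dde": int(is_dde), "n_cue": n_cue,
             "n_background": len(sents) - n_cue}
        )

    cue_table: dict[str, dict[str, float]] = {
        "dde": {DETECTION_CUE: CUE_SCORE},
        **{cat: {phrase: CUE_SCORE} for cat, phrase in _CATEGORY_PHRASES.items()},
    }
    cfg = asdict(config)
    cfg["rootcause_weights"] = dict(config.rootcause_weights)
    manifest = {
        "version": MANIFEST_VERSION,
        "config": cfg,
        "seed": config.seed,
        "cue_table": cue_table,
        "cue_score": CUE_SCORE,
        "structure": structure,
    }
    return SyntheticCorpus(
        comments=tuple(comments),
        gold_binary=tuple(gold_binary),
        gold_rootcause=tuple(gold_rootcause),
        manifest=manifest,
    )


def matched_mock_scorer(
    manifest: Mapping, noise: float = 0.0
) -> MockEntailmentScorer:
    """Mock scorer whose cue table matches a generated corpus.

    At ``noise`` 0, any cutoff strictly between the baseline and the cue
    score makes the sentence-level pipeline recover the planted gold
    labels exactly.
    """
    if manifest.get("version") != MANIFEST_VERSION:
        raise ValueError(
            f"manifest version {manifest.get('version')!r} does not match "
            f"generator version {MANIFEST_VERSION}"
        )
    return MockEntailmentScorer(
        manifest["cue_table"], noise=noise, seed=int(manifest["seed"])
    )


def naive_cue_table() -> dict[str, float]:
    """Substring cue table that fires on bare medication mentions.

    Demonstrates the documented failure mode: hard negatives such as
    "I am not on any medication" are scored positive, producing a nonzero
    false positive rate.
    """
    return {"medication": CUE_SCORE, DETECTION_CUE: CUE_SCORE}


def closed_form_detection_error(
    manifest: Mapping, eps: float
) -> dict[str, float]:
    """Expected comment-level FNR/FPR under per-sentence flip noise eps.

    A discontinuation comment with k cue and m background sentences is
    missed only when all k cue sentences flip down and none of the m
    background sentences flips up: probability eps^k (1-eps)^m. A clean
    comment with m sentences is falsely flagged with probability
    1-(1-eps)^m. Returns the means plus binomial-sum standard deviations
    for tolerance checks.
    """
    fn_probs = [
        eps ** r["n_cue"] * (1 - eps) ** r["n_background"]
        for r in manifest["structure"] if r["is_dde"]
    ]
    fp_probs = [
        1 - (1 - eps) ** (r["n_cue"] + r["n_background"])
        for r in manifest["structure"] if not r["is_dde"]
    ]

    def _mean_sd(probs: Sequence[float]) -> tuple[float, float]:
        if not probs:
            return 0.0, 0.0
        mean = sum(probs) / len(probs)
        var = sum(p * (1 - p) for p in probs) / len(probs) ** 2
        return mean, var ** 0.5

    fnr, fnr_sd = _mean_sd(fn_probs)
    fpr, fpr_sd = _mean_sd(fp_probs)
    return {"fnr": fnr, "fnr_sd": fnr_sd, "fpr": fpr, "fpr_sd": fpr_sd,
            "n_pos": len(fn_probs), "n_neg": len(fp_probs)}
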