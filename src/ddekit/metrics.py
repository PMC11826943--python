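"""Evaluation suite: binary confusion metrics, PR/ROC curves with AUC, and
the multilabel battery (micro/macro/weighted F1 and AUCs, hamming loss,
sample-averaged Jaccard, subset accuracy).

Curve points and the averaged F1/ROC-AUC aggregates come from
scikit-learn; AUC integration is trapezoidal throughout. Sample-averaged
Jaccard is computed here directly because an item with empty predicted and
empty gold set counts as a perfect match (Jaccard 1), a convention
scikit-learn does not offer. Rates with a zero denominator are reported as
0 together with a ``degenerate`` flag, never NaN, so serialized reports
stay machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "ConfusionMatrix",
    "BinaryMetrics",
    "Curve",
    "MultilabelReport",
    "binary_metrics",
    "roc_curve",
    "pr_curve",
    "hamming_loss",
    "jaccard_and_subset",
    "multilabel_report",
    "dataset_summary",
    "frequency_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (96.335 -> 96.34)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, pred: Sequence[int], gold: Sequence[int]) -> "ConfusionMatrix":
        if len(pred) != len(gold):
            raise ValueError("pred and gold lengths differ")
        p, g = np.asarray(pred, dtype=int), np.asarray(gold, dtype=int)
        return cls(
            tp=int(np.sum((p == 1) & (g == 1))),
            fp=int(np.sum((p == 1) & (g == 0))),
            fn=int(np.sum((p == 0) & (g == 1))),
            tn=int(np.sum((p == 0) & (g == 0))),
        )


@dataclass(frozen=True)
class BinaryMetrics:
    """Derived rates of one binary confusion matrix.

    ``degenerate`` lists the rate names whose denominator was zero and
    whose value was therefore reported as 0.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    fpr: float
    fnr: float
    tpr: float
    tnr: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | list[str]]:
        d = {k: getattr(self, k) for k in
             ("precision", "recall", "f1", "accuracy", "fpr", "fnr", "tpr", "tnr")}
        d["degenerate"] = list(self.degenerate)
        return d


def _rate(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(cm: ConfusionMatrix) -> BinaryMetrics:
    """precision, recall/TPR, F1, accuracy, FPR, FNR, TNR from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    precision = _rate(cm.tp, cm.tp + cm.fp, "precision", flags)
    recall = _rate(cm.tp, cm.tp + cm.fn, "recall", flags)
    f1 = _rate(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1", flags)
    fpr = _rate(cm.fp, cm.fp + cm.tn, "fpr", flags)
    fnr = _rate(cm.fn, cm.fn + cm.tp, "fnr", flags)
    tnr = _rate(cm.tn, cm.tn + cm.fp, "tnr", flags)
    return BinaryMetrics(
        precision=precision, recall=recall, f1=f1,
        accuracy=(cm.tp + cm.tn) / cm.total,
        fpr=fpr, fnr=fnr, tpr=recall, tnr=tnr,
        degenerate=tuple(dict.fromkeys(flags)),
    )


@dataclass(frozen=True)
class Curve:
    """PR or ROC curve: (x, y) points with trapezoidal area.

    For ROC, x is FPR and y is TPR (endpoints (0,0) and (1,1) included);
    for PR, x is recall and y is precision with the right endpoint at
    recall 1. ``auc`` is ``None`` when undefined (single-class gold).
    """

    kind: str
    points: tuple[tuple[float, float], ...]
    auc: float | None


def roc_curve(scores: Sequence[float], gold: Sequence[int]) -> Curve:
    """ROC curve over all distinct score thresholds, trapezoidal AUC.

    With ties, the trapezoid over the tie-grouped points equals the
    pairwise concordance probability P(s+ > s-) + 0.5 P(tie). A gold
    vector with a single class yields points but an undefined AUC.
    """
    g = np.asarray(gold, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(g) != len(s) or len(g) == 0:
        raise ValueError("scores and gold must be non-empty and aligned")
    if len(np.unique(g)) < 2:
        return Curve(kind="roc", points=((0.0, 0.0), (1.0, 1.0)), auc=None)
    fpr, tpr, _ = skm.roc_curve(g, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return Curve(kind="roc", points=tuple(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def pr_curve(scores: Sequence[float], gold: Sequence[int]) -> Curve:
    """Precision-recall curve with trapezoidal AUC over recall.

    Points are ordered by ascending recall and end at recall 1 (the
    all-positive threshold, precision = prevalence). No positive items
    means precision/recall are undefined: AUC reported as ``None``.
    """
    g = np.asarray(gold, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(g) != len(s) or len(g) == 0:
        raise ValueError("scores and gold must be non-empty and aligned")
    if g.sum() == 0:
        return Curve(kind="pr", points=(), auc=None)
    precision, recall, _ = skm.precision_recall_curve(g, s, drop_intermediate=False)
    # sklearn orders by descending recall; flip to ascending for integration
    recall, precision = recall[::-1], precision[::-1]
    auc = float(np.trapezoid(precision, recall))
    return Curve(kind="pr", points=tuple(zip(recall.tolist(), precision.tolist())), auc=auc)


def _aligned_sets(
    pred: Mapping[str, frozenset[str] | set[str]],
    gold: Mapping[str, frozenset[str] | set[str]],
) -> list[str]:
    if set(pred) != set(gold):
        orphans = sorted(set(pred) ^ set(gold))
        raise ValueError(f"pred/gold id mismatch, orphans: {orphans[:10]}")
    if not pred:
        raise ValueError("no items to evaluate")
    return sorted(pred)


def _indicator(
    ids: Sequence[str],
    sets: Mapping[str, frozenset[str] | set[str]],
    classes: Sequence[str],
) -> np.ndarray:
    idx = {c: j for j, c in enumerate(classes)}
    m = np.zeros((len(ids), len(classes)), dtype=int)
    for i, cid in enumerate(ids):
        for c in sets[cid]:
            if c not in idx:
                raise ValueError(f"unknown category {c!r} for item {cid!r}")
            m[i, idx[c]] = 1
    return m


def hamming_loss(
    pred: Mapping[str, frozenset[str] | set[str]],
    gold: Mapping[str, frozenset[str] | set[str]],
    classes: Sequence[str],
) -> float:
    """Fraction of item-class membership cells predicted incorrectly."""
    ids = _aligned_sets(pred, gold)
    P = _indicator(ids, pred, classes)
    G = _indicator(ids, gold, classes)
    return float(skm.hamming_loss(G, P))


def jaccard_and_subset(
    pred: Mapping[str, frozenset[str] | set[str]],
    gold: Mapping[str, frozenset[str] | set[str]],
) -> tuple[float, float]:
    """(sample-averaged Jaccard, subset accuracy).

    Per-item Jaccard is |pred∩gold| / |pred∪gold| with empty/empty
    defined as 1; subset accuracy is the fraction of exact set matches.
    Subset accuracy never exceeds the averaged Jaccard.
    """
    ids = _aligned_sets(pred, gold)
    jac, exact = 0.0, 0
    for cid in ids:
        p, g = frozenset(pred[cid]), frozenset(gold[cid])
        union = p | g
        jac += 1.0 if not union else len(p & g) / len(union)
        exact += p == g
    n = len(ids)
    return jac / n, exact / n


@dataclass(frozen=True)
class MultilabelReport:
    micro_f1: float
    macro_f1: float
    weighted_f1: float
    micro_roc_auc: float | None
    macro_roc_auc: float | None
    weighted_roc_auc: float | None
    micro_pr_auc: float | None
    macro_pr_auc: float | None
    weighted_pr_auc: float | None
    hamming_loss: float
    jaccard: float
    subset_accuracy: float
    per_class: dict[str, BinaryMetrics] = field(default_factory=dict)
    n_items: int = 0

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "micro_f1", "macro_f1", "weighted_f1",
                "micro_roc_auc", "macro_roc_auc", "weighted_roc_auc",
                "micro_pr_auc", "macro_pr_auc", "weighted_pr_auc",
                "hamming_loss", "jaccard", "subset_accuracy", "n_items",
            )
        }
        d["per_class"] = {c: m.as_dict() for c, m in self.per_class.items()}
        return d


def _averaged_aucs(
    G: np.ndarray, S: np.ndarray, kind: str
) -> tuple[float | None, float | None, float | None]:
    """(micro, macro, weighted) trapezoidal AUCs for ROC or PR.

    Macro/weighted skip classes whose AUC is undefined (single-class gold
    column); all-undefined yields None. Micro pools every item-class cell.
    """
    curve = roc_curve if kind == "roc" else pr_curve
    per_class: list[float | None] = []
    for j in range(G.shape[1]):
        per_class.append(curve(S[:, j], G[:, j]).auc)
    support = G.sum(axis=0).astype(float)
    defined = [(a, w) for a, w in zip(per_class, support) if a is not None]
    macro = float(np.mean([a for a, _ in defined])) if defined else None
    wsum = sum(w for _, w in defined)
    weighted = (
        float(sum(a * w for a, w in defined) / wsum) if defined and wsum > 0 else None
    )
    micro = curve(S.ravel(), G.ravel()).auc
    return micro, macro, weighted


def multilabel_report(
    pred: Mapping[str, frozenset[str] | set[str]],
    gold: Mapping[str, frozenset[str] | set[str]],
    classes: Sequence[str],
    scores: Mapping[str, Mapping[str, float]] | None = None,
) -> MultilabelReport:
    """Full multilabel battery over a closed class list.

    micro pools item-class cells across classes; macro is the unweighted
    mean of per-class values; weighted weighs each class by its gold
    support. AUC fields need per-category ``scores`` (absent for hard
    binary chat predictions) and are ``None`` otherwise.
    """
    ids = _aligned_sets(pred, gold)
    G = _indicator(ids, gold, classes)
    P = _indicator(ids, pred, classes)

    per_class = {
        c: binary_metrics(ConfusionMatrix.from_labels(P[:, j], G[:, j]))
        for j, c in enumerate(classes)
    }

    if len(classes) == 1:
        # a single-column indicator collapses: micro = macro = weighted;
        # sklearn would reinterpret the column as a multiclass vector here
        only = per_class[classes[0]].f1
        micro_f1 = macro_f1 = weighted_f1 = only
    else:
        micro_f1 = float(skm.f1_score(G, P, average="micro", zero_division=0))
        macro_f1 = float(skm.f1_score(G, P, average="macro", zero_division=0))
        weighted_f1 = float(skm.f1_score(G, P, average="weighted", zero_division=0))

    aucs: dict[str, float | None] = {
        "micro_roc_auc": None, "macro_roc_auc": None, "weighted_roc_auc": None,
        "micro_pr_auc": None, "macro_pr_auc": None, "weighted_pr_auc": None,
    }
    if scores is not None:
        S = np.zeros_like(G, dtype=float)
        cidx = {c: j for j, c in enumerate(classes)}
        for i, cid in enumerate(ids):
            row = scores.get(cid)
            if row is None:
                raise ValueError(f"missing scores for item {cid!r}")
            for c, v in row.items():
                S[i, cidx[c]] = float(v)
        (aucs["micro_roc_auc"], aucs["macro_roc_auc"],
         aucs["weighted_roc_auc"]) = _averaged_aucs(G, S, "roc")
        (aucs["micro_pr_auc"], aucs["macro_pr_auc"],
         aucs["weighted_pr_auc"]) = _averaged_aucs(G, S, "pr")

    jac, subset = jaccard_and_subset(pred, gold)
    return MultilabelReport(
        micro_f1=micro_f1, macro_f1=macro_f1, weighted_f1=weighted_f1,
        hamming_loss=hamming_loss(pred, gold, classes),
        jaccard=jac, subset_accuracy=subset,
        per_class=per_class, n_items=len(ids), **aucs,
    )


def dataset_summary(gold: Sequence[int]) -> dict[str, dict[str, float | int]]:
    """Class counts and percentages (1 decimal) for binary gold labels."""
    if len(gold) == 0:
        raise ValueError("dataset_summary requires a non-empty sequence")
    g = np.asarray(gold, dtype=int)
    n = len(g)
    pos = int(g.sum())
    return {
        "dde": {"count": pos, "percent": round_half_up(100.0 * pos / n, 1)},
        "non_dde": {"count": n - pos, "percent": round_half_up(100.0 * (n - pos) / n, 1)},
        "total": {"count": n, "percent": 100.0},
    }


def frequency_table(
    gold_sets: Mapping[str, frozenset[str] | set[str]],
    classes: Sequence[str],
) -> dict[str, dict[str, float | int]]:
    """Per-category occurrence counts and percentages over a labeled corpus."""
    if not gold_sets:
        raise ValueError("frequency_table requires a non-empty mapping")
    n = len(gold_sets)
    out = {}
    for c in classes:
        k = sum(1 for s in gold_sets.values() if c in s)
        out[c] = {"count": k, "percent": round_half_up(100.0 * k / n, 1)}
    return out
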