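"""Corpus, lexicon and gold-label I/O plus annotation aggregation.

Comments are plain records (id, text, optional source) read from JSONL or
CSV. The keyword prefilter retains comments mentioning at least one drug
lexicon term as a whole word; gold labels carry per-annotator binary votes
and confidence levels whose consensus is the majority vote.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Comment",
    "Lexicon",
    "GoldBinaryLabel",
    "GoldRootCauseLabel",
    "CorpusError",
    "read_comments",
    "write_comments",
    "read_lexicon",
    "keyword_filter",
    "majority_vote",
    "confidence_summary",
    "read_gold_binary",
    "read_gold_rootcause",
]

CONFIDENCE_LEVELS = ("very_confident", "somewhat_confident", "not_confident")


class CorpusError(ValueError):
    """Malformed or inconsistent corpus/label input."""


@dataclass(frozen=True)
class Comment:
    """One forum question or answer."""

    id: str
    text: str
    source: str = ""


@dataclass(frozen=True)
class Lexicon:
    """Set of lowercase drug-keyword terms used for prefiltering."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        for t in self.terms:
            if t != t.strip() or t != t.lower():
                raise CorpusError(f"lexicon term not normalised: {t!r}")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GoldBinaryLabel:
    """Per-annotator binary DDE votes with confidence levels and consensus."""

    comment_id: str
    labels: tuple[int, ...]
    confidences: tuple[str, ...]
    consensus: int = field(default=-1)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.confidences):
            raise CorpusError(
                f"{self.comment_id}: {len(self.labels)} labels vs "
                f"{len(self.confidences)} confidences"
            )
        if any(v not in (0, 1) for v in self.labels):
            raise CorpusError(f"{self.comment_id}: labels must be 0/1")
        for c in self.confidences:
            if c not in CONFIDENCE_LEVELS:
                raise CorpusError(f"{self.comment_id}: unknown confidence {c!r}")
        if self.consensus == -1:
            object.__setattr__(self, "consensus", majority_vote(self.labels))
        elif self.consensus != majority_vote(self.labels):
            raise CorpusError(
                f"{self.comment_id}: consensus {self.consensus} is not the majority"
            )


@dataclass(frozen=True)
class GoldRootCauseLabel:
    """Gold multilabel root-cause set for one DDE comment.

    ``categories`` holds names from the closed 8-value taxonomy; validation
    against the enumeration happens in :mod:`ddekit.rootcause`.
    """

    comment_id: str
    categories: frozenset[str]


def _records_from_jsonl(path: Path) -> Iterable[tuple[int, dict]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
            if not isinstance(rec, dict):
                raise CorpusError(f"{path}:{lineno}: expected a JSON object")
            yield lineno, rec


def _records_from_csv(path: Path) -> Iterable[tuple[int, dict]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        for rec in reader:
            lineno = reader.line_num
            if None in rec or any(v is None for v in rec.values()):
                raise CorpusError(f"{path}:{lineno}: ragged CSV row")
            yield lineno, rec


def _iter_records(path: str | Path, format: str | None) -> Iterable[tuple[int, dict]]:
    p = Path(path)
    if not p.exists():
        raise CorpusError(f"no such file: {p}")
    fmt = format or ("csv" if p.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        return _records_from_jsonl(p)
    if fmt == "csv":
        return _records_from_csv(p)
    raise CorpusError(f"unknown format {fmt!r} (expected jsonl or csv)")


def read_comments(path: str | Path, format: str | None = None) -> list[Comment]:
    """Read comments from a JSONL or CSV file, order preserved.

    Each record needs ``id`` and ``text``; ``source`` defaults to empty.
    Duplicate ids and malformed records are hard errors naming the line.
    """
    comments: list[Comment] = []
    seen: set[str] = set()
    for lineno, rec in _iter_records(path, format):
        if "id" not in rec or "text" not in rec:
            missing = [k for k in ("id", "text") if k not in rec]
            raise CorpusError(f"{path}:{lineno}: missing column(s) {missing}")
        cid = str(rec["id"])
        if cid in seen:
            raise CorpusError(f"{path}:{lineno}: duplicate comment id {cid!r}")
        seen.add(cid)
        comments.append(Comment(id=cid, text=str(rec["text"]), source=str(rec.get("source") or "")))
    return comments


def write_comments(comments: Sequence[Comment], path: str | Path) -> None:
    """Write comments as UTF-8 JSONL (one object per line)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(json.dumps({"id": c.id, "text": c.text, "source": c.source}) + "\n")


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a plain-text lexicon: one term per line, ``#`` comments allowed."""
    terms: set[str] = set()
    p = Path(path)
    if not p.exists():
        raise CorpusError(f"no such file: {p}")
    for line in p.read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip().lower()
        if term:
            terms.add(term)
    return Lexicon(terms=frozenset(terms))


def _lexicon_pattern(lexicon: Lexicon) -> re.Pattern[str]:
    # whole-word, case-insensitive; multi-word terms match as contiguous
    # phrases. Boundaries are non-alphanumeric so "lipitoring" never matches
    # "lipitor" while "lipitor," does.
    alts = sorted((re.escape(t) for t in lexicon.terms), key=len, reverse=True)
    return re.compile(
        r"(?<![0-9A-Za-z])(?:" + "|".join(alts) + r")(?![0-9A-Za-z])",
        re.IGNORECASE,
    )


def keyword_filter(comments: Sequence[Comment], lexicon: Lexicon) -> list[Comment]:
    """Retain comments whose text contains at least one lexicon term.

    Matching is case-insensitive and whole-word (delimited by
    non-alphanumerics); order is preserved. An empty lexicon is an error —
    it would retain nothing meaningful.
    """
    if len(lexicon) == 0:
        raise CorpusError("keyword_filter requires a non-empty lexicon")
    pat = _lexicon_pattern(lexicon)
    return [c for c in comments if pat.search(c.text)]


def majority_vote(labels: Sequence[int]) -> int:
    """Majority of an odd number of binary annotator votes.

    An even panel is an error: ties are undefined and were resolved by
    discussion, not by vote, in the source labeling protocol.
    """
    n = len(labels)
    if n == 0 or n % 2 == 0:
        raise CorpusError(f"majority_vote needs an odd number of labels, got {n}")
    if any(v not in (0, 1) for v in labels):
        raise CorpusError("labels must be 0 or 1")
    return int(sum(labels) * 2 > n)


def confidence_summary(
    confidences: Sequence[str],
) -> dict[str, tuple[int, float]]:
    """Count annotator confidence levels; percent rounded to 2 decimals."""
    from .metrics import round_half_up

    if not confidences:
        raise CorpusError("confidence_summary requires a non-empty sequence")
    counts = Counter(confidences)
    unknown = set(counts) - set(CONFIDENCE_LEVELS)
    if unknown:
        raise CorpusError(f"unknown confidence level(s): {sorted(unknown)}")
    total = len(confidences)
    return {
        level: (counts[level], round_half_up(100.0 * counts[level] / total, 2))
        for level in CONFIDENCE_LEVELS
        if counts[level]
    }


def read_gold_binary(path: str | Path, format: str | None = None) -> list[GoldBinaryLabel]:
    """Read gold binary DDE labels.

    Dialect: columns ``comment_id``, ``label_1..label_k``, ``conf_1..conf_k``
    (CSV with header, or JSONL objects with the same keys). The consensus is
    recomputed as the majority vote and checked against any stored value.
    """
    out: list[GoldBinaryLabel] = []
    seen: set[str] = set()
    for lineno, rec in _iter_records(path, format):
        if "comment_id" not in rec:
            raise CorpusError(f"{path}:{lineno}: missing comment_id")
        cid = str(rec["comment_id"])
        if cid in seen:
            raise CorpusError(f"{path}:{lineno}: duplicate comment id {cid!r}")
        seen.add(cid)
        labels, confs = [], []
        k = 1
        while f"label_{k}" in rec:
            labels.append(int(rec[f"label_{k}"]))
            if f"conf_{k}" not in rec:
                raise CorpusError(f"{path}:{lineno}: label_{k} without conf_{k}")
            confs.append(str(rec[f"conf_{k}"]))
            k += 1
        if not labels:
            raise CorpusError(f"{path}:{lineno}: no label_* columns")
        consensus = int(rec["consensus"]) if "consensus" in rec and rec["consensus"] != "" else -1
        try:
            out.append(
                GoldBinaryLabel(
                    comment_id=cid,
                    labels=tuple(labels),
                    confidences=tuple(confs),
                    consensus=consensus,
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_gold_rootcause(path: str | Path, format: str | None = None) -> list[GoldRootCauseLabel]:
    """Read gold root-cause sets: ``comment_id`` plus ``categories``.

    In JSONL ``categories`` is a list; in CSV it is a ``;``-separated string.
    """
    out: list[GoldRootCauseLabel] = []
    seen: set[str] = set()
    for lineno, rec in _iter_records(path, format):
        if "comment_id" not in rec or "categories" not in rec:
            raise CorpusError(f"{path}:{lineno}: need comment_id and categories")
        cid = str(rec["comment_id"])
        if cid in seen:
            raise CorpusError(f"{path}:{lineno}: duplicate comment id {cid!r}")
        seen.add(cid)
        cats = rec["categories"]
        if isinstance(cats, str):
            cats = [c.strip() for c in cats.split(";") if c.strip()]
        out.append(GoldRootCauseLabel(comment_id=cid, categories=frozenset(map(str, cats))))
    return out


def gold_binary_consensus(gold: Iterable[GoldBinaryLabel]) -> dict[str, int]:
    """Map comment id to consensus label."""
    return {g.comment_id: g.consensus for g in gold}
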