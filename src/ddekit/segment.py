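"""Sentence segmentation and token-budget chunking.

Entailment scorers accept a bounded number of tokens, so comments are split
into sentences and consecutive sentences are greedily packed into chunks
that fit the active scorer's budget. Segmentation is deterministic and
rule-based: informal forum text defeats linguistically exact boundary
detection anyway, and the downstream max-aggregation only needs reasonable
units, not perfect ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

__all__ = [
    "SentenceSpan",
    "Chunk",
    "TokenizerSpec",
    "split_sentences",
    "count_tokens",
    "group_sentences",
]

# maximal alphanumeric runs, or a single non-space punctuation mark
_TOKEN_RE = re.compile(r"[0-9A-Za-z]+|[^\s0-9A-Za-z]")

# sentence-final punctuation followed by whitespace; a period followed by a
# lowercase letter does not split (reduces spurious breaks on "e.g. this")
_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*\s+")


@dataclass(frozen=True)
class TokenizerSpec:
    """Token-counting scheme and budget of the target scorer."""

    name: str = "regex"
    max_tokens: int = 256

    def __post_init__(self) -> None:
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence with character offsets into the source comment.

    Spans partition the text: ``start`` of each span equals ``end`` of the
    previous one, so concatenating ``text[start:end]`` slices reconstructs
    the input byte-for-byte (trailing whitespace belongs to the span that
    precedes it).
    """

    text: str
    start: int
    end: int
    token_count: int


@dataclass(frozen=True)
class Chunk:
    """Consecutive sentences packed under a token budget.

    ``overflow_flag`` marks windows cut from a single sentence that alone
    exceeded the budget; only those may carry ``token_count > max_tokens``
    ancestry (each window itself still fits).
    """

    sentence_indices: tuple[int, ...]
    text: str
    token_count: int
    overflow_flag: bool = False


_COUNTERS: dict[str, Callable[[str], int]] = {}


def register_token_counter(name: str, fn: Callable[[str], int]) -> None:
    """Register a counting scheme (e.g. a neural backend's own tokenizer)."""
    _COUNTERS[name] = fn


def count_tokens(text: str, spec: TokenizerSpec = TokenizerSpec()) -> int:
    """Count tokens under the spec's scheme.

    The default ``regex`` scheme counts maximal alphanumeric runs and each
    punctuation mark as one token ("can't" -> can, ', t = 3).
    """
    if spec.name == "regex":
        return len(_TOKEN_RE.findall(text))
    if spec.name in _COUNTERS:
        return _COUNTERS[spec.name](text)
    raise ValueError(f"unknown token-counting scheme {spec.name!r}")


def split_sentences(text: str, spec: TokenizerSpec = TokenizerSpec()) -> list[SentenceSpan]:
    """Split text into sentence spans at ., ! or ? followed by whitespace.

    Text without any such boundary yields a single span; empty text yields
    none. A period directly followed by a lowercase letter is not a
    boundary. Total function — never raises on content.
    """
    if not text:
        return []
    cuts: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        nxt = text[m.end()] if m.end() < len(text) else ""
        if nxt.islower():
            continue
        cuts.append(m.end())
    spans: list[SentenceSpan] = []
    start = 0
    for cut in cuts + [len(text)]:
        if cut <= start:
            continue
        seg = text[start:cut]
        spans.append(
            SentenceSpan(text=seg, start=start, end=cut, token_count=count_tokens(seg, spec))
        )
        start = cut
    return spans


def _window_oversized(
    sent: SentenceSpan, index: int, spec: TokenizerSpec
) -> list[Chunk]:
    """Hard-split one over-budget sentence into token windows, all flagged."""
    if spec.name == "regex":
        token_spans = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(sent.text)]
    else:
        # non-regex schemes: fall back to whitespace pieces for windowing
        token_spans = []
        pos = 0
        for piece in sent.text.split():
            i = sent.text.index(piece, pos)
            token_spans.append((i, i + len(piece)))
            pos = i + len(piece)
    chunks: list[Chunk] = []
    for i in range(0, len(token_spans), spec.max_tokens):
        window = token_spans[i : i + spec.max_tokens]
        text = sent.text[window[0][0] : window[-1][1]]
        chunks.append(
            Chunk(
                sentence_indices=(index,),
                text=text,
                token_count=count_tokens(text, spec),
                overflow_flag=True,
            )
        )
    return chunks


def group_sentences(
    sentences: Sequence[SentenceSpan], spec: TokenizerSpec
) -> list[Chunk]:
    """Greedy left-to-right packing of sentences into budgeted chunks.

    The current chunk is extended while the next sentence keeps the total
    within ``spec.max_tokens``; otherwise a new chunk starts. A single
    sentence over budget is force-windowed at token boundaries with
    ``overflow_flag`` set. Every sentence lands in exactly one chunk (or one
    run of overflow windows); the single-space join adds no tokens under the
    regex scheme.
    """
    chunks: list[Chunk] = []
    cur_idx: list[int] = []
    cur_total = 0

    def flush() -> None:
        nonlocal cur_idx, cur_total
        if cur_idx:
            text = " ".join(sentences[i].text.strip() for i in cur_idx)
            chunks.append(
                Chunk(
                    sentence_indices=tuple(cur_idx),
                    text=text,
                    token_count=cur_total,
                    overflow_flag=False,
                )
            )
            cur_idx, cur_total = [], 0

    for i, sent in enumerate(sentences):
        if sent.token_count > spec.max_tokens:
            flush()
            chunks.extend(_window_oversized(sent, i, spec))
            continue
        if cur_idx and cur_total + sent.token_count > spec.max_tokens:
            flush()
        cur_idx.append(i)
        cur_total += sent.token_count
    flush()
    return chunks
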