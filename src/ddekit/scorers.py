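"""Entailment scorers: the contract every classification strategy consumes.

A scorer maps a (premise, hypothesis) pair to a probability that the
premise entails the hypothesis. Three backends exist:

* ``MockEntailmentScorer`` — deterministic, seeded, cue-phrase driven; the
  default for tests and synthetic experiments. Pure function of
  (premise, hypothesis, seed, noise), stable across processes.
* ``NliScorer`` — a neural zero-shot NLI model, loaded lazily; requires the
  optional ``transformers``/``torch`` stack at call time.
* chat-style backends — produce hard {0,1} answers via prompt construction
  and strict response parsing. Only score-producing backends support
  threshold sweeps and AUC analysis; chat backends are binary by design.
"""

from __future__ import annotations

import hashlib
import json
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol

__all__ = [
    "Hypothesis",
    "ScorerConfig",
    "ScorerError",
    "UnparseableResponse",
    "EntailmentScorer",
    "MockEntailmentScorer",
    "NliScorer",
    "ChatBackend",
    "ScriptedChatBackend",
    "ChatBinaryClassifier",
    "build_binary_prompt",
    "parse_binary_response",
    "make_scorer",
    "ScoreCache",
    "DEFAULT_HYPOTHESIS",
]

DEFAULT_BASELINE = 0.01


@dataclass(frozen=True)
class Hypothesis:
    """A candidate statement whose entailment by a premise is scored."""

    text: str
    label: str = "dde"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("hypothesis text must be non-empty")


DEFAULT_HYPOTHESIS = Hypothesis(text="Person stopped taking medication.", label="dde")


class ScorerError(RuntimeError):
    """Backend misconfiguration or transport failure."""

    def __init__(self, message: str, *, kind: str = "configuration") -> None:
        super().__init__(message)
        self.kind = kind  # "configuration" | "transport"


class UnparseableResponse(ScorerError):
    """A chat response from which no answer token could be extracted."""

    def __init__(self, raw: str) -> None:
        super().__init__(f"unparseable chat response: {raw!r}", kind="transport")
        self.raw = raw


class EntailmentScorer(Protocol):
    def score(self, premise: str, hypothesis: Hypothesis) -> float: ...


@dataclass(frozen=True)
class ScorerConfig:
    """Declarative scorer selection, resolvable via :func:`make_scorer`."""

    backend: str = "mock"  # {mock, nli, chat}
    model_id: str = ""
    max_tokens: int = 256
    seed: int = 0
    noise: float = 0.0
    cue_table: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in ("mock", "nli", "chat"):
            raise ScorerError(f"unknown backend {self.backend!r}")
        if not 0.0 <= self.noise < 1.0:
            raise ScorerError("noise must be in [0, 1)")


def _unit_uniform(*parts: str) -> float:
    """Deterministic uniform in [0,1) from a SHA-256 of the parts."""
    digest = hashlib.sha256("\x1f".join(parts).encode("utf-8")).digest()
    (val,) = struct.unpack(">Q", digest[:8])
    return val / 2**64


def _normalise_cue_table(
    cue_table: Mapping[str, object],
) -> dict[str | None, dict[str, float]]:
    """Accept either a flat {phrase: score} table (applies to every
    hypothesis) or a nested {hypothesis_label: {phrase: score}} table."""
    if not cue_table:
        return {}
    first = next(iter(cue_table.values()))
    if isinstance(first, Mapping):
        return {str(k): {p.lower(): float(s) for p, s in v.items()}  # type: ignore[union-attr]
                for k, v in cue_table.items()}
    return {None: {p.lower(): float(s) for p, s in cue_table.items()}}  # type: ignore[arg-type]


class MockEntailmentScorer:
    """Deterministic cue-phrase scorer for tests and synthetic corpora.

    The score is the maximum table value over cue phrases present as
    (lowercased) substrings of the premise, else ``baseline``. With
    ``noise`` = eps > 0 the cue decision is flipped with probability eps,
    decided by a seeded hash of (premise, hypothesis label) — so repeated
    calls, and calls in other processes, agree exactly.
    """

    def __init__(
        self,
        cue_table: Mapping[str, object],
        *,
        baseline: float = DEFAULT_BASELINE,
        noise: float = 0.0,
        seed: int = 0,
        flip_score: float | None = None,
    ) -> None:
        if not 0.0 <= noise < 1.0:
            raise ScorerError("noise must be in [0, 1)")
        self._tables = _normalise_cue_table(cue_table)
        self.baseline = float(baseline)
        self.noise = float(noise)
        self.seed = int(seed)
        all_scores = [s for tbl in self._tables.values() for s in tbl.values()]
        self.flip_score = float(flip_score) if flip_score is not None else (
            max(all_scores) if all_scores else 0.99
        )

    def _table_for(self, hypothesis: Hypothesis) -> dict[str, float]:
        if None in self._tables:
            return self._tables[None]
        return self._tables.get(hypothesis.label, {})

    def score(self, premise: str, hypothesis: Hypothesis) -> float:
        table = self._table_for(hypothesis)
        low = premise.lower()
        hits = [s for phrase, s in table.items() if phrase in low]
        cue_score = max(hits) if hits else None
        if self.noise > 0.0:
            u = _unit_uniform("mock-noise", premise, hypothesis.label, str(self.seed))
            if u < self.noise:
                cue_score = None if cue_score is not None else self.flip_score
        value = cue_score if cue_score is not None else self.baseline
        return min(max(value, 0.0), 1.0)


class NliScorer:
    """Neural zero-shot NLI backend, loaded lazily on first use.

    Kept out of the default path: the test and synthetic pipelines run
    entirely on the mock. Needs the optional ``transformers`` + ``torch``
    stack installed.
    """

    def __init__(self, model_id: str) -> None:
        if not model_id:
            raise ScorerError("nli backend requires a model_id")
        self.model_id = model_id
        self._pipeline = None

    def _load(self):
        if self._pipeline is None:
            try:
                from transformers import pipeline  # type: ignore[import-not-found]
            except ImportError as exc:
                raise ScorerError(
                    "nli backend needs the optional 'transformers' and 'torch' "
                    "packages installed",
                ) from exc
            self._pipeline = pipeline("zero-shot-classification", model=self.model_id)
        return self._pipeline

    def score(self, premise: str, hypothesis: Hypothesis) -> float:
        pipe = self._load()
        out = pipe(premise, candidate_labels=[hypothesis.text], hypothesis_template="{}")
        return float(out["scores"][0])


# ---------------------------------------------------------------------------
# chat-style backends


class ChatBackend(Protocol):
    def complete(self, prompt: str) -> str: ...


class ScriptedChatBackend:
    """Chat backend driven by a mapping or callable — the mock chat route.

    ``script`` maps a prompt (or the comment text embedded in it, via
    ``by_substring``) to a canned response; a callable receives the full
    prompt. Unmatched prompts return ``default``.
    """

    def __init__(
        self,
        script: Mapping[str, str] | Callable[[str], str],
        *,
        by_substring: bool = True,
        default: str = "",
    ) -> None:
        self._script = script
        self._by_substring = by_substring
        self._default = default
        self.calls = 0

    def complete(self, prompt: str) -> str:
        self.calls += 1
        if callable(self._script):
            return self._script(prompt)
        if self._by_substring:
            for key, resp in self._script.items():
                if key in prompt:
                    return resp
            return self._default
        return self._script.get(prompt, self._default)


def build_binary_prompt(comment_text: str, task: str = "detect") -> str:
    """Build a strictly parseable binary prompt embedding the comment verbatim."""
    if task != "detect":
        raise ValueError(f"unknown binary task {task!r}")
    return (
        "You will read one comment from a health forum. Decide whether it "
        "describes a drug discontinuation event: a specific person stopping "
        "a recurring medication or treatment (medication changes count; "
        "one-time treatments do not).\n"
        "Answer with a single character: 1 if the comment contains a drug "
        "discontinuation event, 0 if it does not. Output nothing else.\n"
        "Comment:\n"
        f"{comment_text}\n"
        "Answer:"
    )


_STANDALONE_BIT = re.compile(r"(?<![0-9A-Za-z])([01])(?![0-9A-Za-z])")


def parse_binary_response(raw: str) -> int:
    """Extract the first standalone 0/1 token; anything else is unparseable."""
    m = _STANDALONE_BIT.search(raw)
    if m is None:
        raise UnparseableResponse(raw)
    return int(m.group(1))


class ChatBinaryClassifier:
    """Whole-comment binary classification through a chat backend.

    Retries unparseable responses up to ``retries`` times, then records a
    missing prediction (returns ``None``) — never a silent default.
    """

    def __init__(self, backend: ChatBackend, *, retries: int = 2) -> None:
        self.backend = backend
        self.retries = retries

    def classify(self, comment_text: str) -> int | None:
        prompt = build_binary_prompt(comment_text)
        for _ in range(self.retries + 1):
            try:
                return parse_binary_response(self.backend.complete(prompt))
            except UnparseableResponse:
                continue
        return None


def make_scorer(config: ScorerConfig) -> EntailmentScorer:
    """Resolve a declarative config into a live scorer instance."""
    if config.backend == "mock":
        return MockEntailmentScorer(
            config.cue_table, noise=config.noise, seed=config.seed
        )
    if config.backend == "nli":
        return NliScorer(config.model_id)
    raise ScorerError(
        "chat backends produce hard binary answers, not entailment scores; "
        "construct a ChatBinaryClassifier instead"
    )


class ScoreCache:
    """JSONL score cache keyed by hash of (premise, hypothesis, model id).

    Makes re-runs with live backends deterministic and cheap; a pass-through
    for anything not yet cached.
    """

    def __init__(self, path: str | Path | None = None) -> None:
        self.path = Path(path) if path is not None else None
        self._mem: dict[str, float] = {}
        if self.path is not None and self.path.exists():
            for line in self.path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    rec = json.loads(line)
                    self._mem[rec["key"]] = float(rec["score"])

    @staticmethod
    def key(premise: str, hypothesis: Hypothesis, model_id: str) -> str:
        return hashlib.sha256(
            "\x1f".join((premise, hypothesis.text, model_id)).encode("utf-8")
        ).hexdigest()

    def score(
        self, scorer: EntailmentScorer, premise: str, hypothesis: Hypothesis,
        model_id: str = "",
    ) -> float:
        k = self.key(premise, hypothesis, model_id)
        if k not in self._mem:
            val = scorer.score(premise, hypothesis)
            self._mem[k] = val
            if self.path is not None:
                with self.path.open("a", encoding="utf-8") as fh:
                    fh.write(json.dumps({"key": k, "score": val}) + "\n")
        return self._mem[k]
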