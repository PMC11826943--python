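# Methods

## Problem and model

The package detects drug discontinuation events (DDEs) in informal
health-forum comments and classifies their root causes. A DDE is a
statement from which a specific person's discontinuation of a recurring
medication or treatment can be inferred; medication changes count,
one-time treatments do not. Detection is cast as zero-shot natural-language
inference: a pretrained entailment model scores how strongly a premise
(a sentence, a chunk of consecutive sentences, or a whole comment)
supports a hypothesis such as "Person stopped taking medication.", and
the comment-level decision aggregates unit scores by their maximum. The
max is the correct aggregator for this task's semantics: a comment
mentions a discontinuation iff at least one of its units does, and
`max(scores) > cutoff` is exactly the OR of per-unit threshold decisions.

Comparison to the cutoff is **strict** (`>`): a prediction exactly equal
to the cutoff classifies negative. The alternative (`>=`) is equally
defensible a priori; strictness was fixed once so that sweeps and tests
share one tie rule. Empty comments get prediction 0.0 and therefore
classify negative at any positive cutoff — the safe default for empty
text.

Root causes form a closed 8-category taxonomy: treatment success,
treatment inefficacy, adverse reactions, accessibility issues, personal
choices, alternative medical reasons, indeterminate, non-discontinuation.
The task is multilabel; under the sentence/chunk strategies each category
has its own hypothesis and cutoff and the per-category score is the max
over units. `indeterminate` and `non_discontinuation` are ordinary scored
classes, not fallbacks: an empty predicted set stays empty rather than
being coerced to `indeterminate`, so reported per-class metrics are not
contaminated by a fallback rule.

The default per-category hypothesis strings are written from the category
definitions and are plain configuration; detection results are known to be
sensitive to hypothesis wording, so nothing is hard-coded.

## Segmentation and chunking

Sentence segmentation is deterministic and rule-based: a boundary is
sentence-final punctuation (., !, ?) followed by whitespace, except when
the next character is lowercase (suppresses splits after abbreviations
like "e.g."). Text without such punctuation is one sentence; spans
partition the input exactly (trailing whitespace belongs to the preceding
span), so concatenating spans reconstructs the comment byte-for-byte.
This approximates an off-the-shelf sentencizer; linguistically exact
boundary detection on typo-ridden forum text is explicitly a non-goal,
and no contract depends on matching any third-party tokenizer.

The default token counter treats each maximal alphanumeric run and each
punctuation character as one token; a neural backend can register its own
counting function behind the same interface. Chunking is greedy
left-to-right: extend the current chunk while the next sentence keeps the
total within `max_tokens`, else start a new chunk. A single sentence over
budget is hard-windowed at token boundaries into flagged overflow chunks,
guaranteeing every text is scoreable. The inter-sentence separator in
chunk text is a single space (which contributes no tokens under the
default scheme, keeping chunk counts equal to the sum of sentence
counts).

## Scorers

All strategies consume one contract: `score(premise, hypothesis) -> [0,1]`.

* **Mock** (default, used by all tests): the score is the max cue-table
  value over cue phrases present as substrings of the lowercased premise,
  else a baseline of 0.01. With flip noise ε the cue decision is inverted
  with probability ε, decided by a SHA-256 hash of (premise, hypothesis
  label, seed) — a pure function, identical across processes, so noisy
  runs are exactly reproducible and flips on distinct sentences are
  independent.
* **Neural NLI**: lazy-loaded zero-shot classification pipeline; optional
  dependency, never touched by the default paths.
* **Chat**: builds a strictly parseable prompt (binary 1/0 for detection;
  summarize-then-list with the eight category names enumerated verbatim
  for root causes) and parses the response. Unparseable output is retried
  twice, then recorded as a *missing* prediction; missing predictions are
  excluded from metrics with an explicit count, never imputed. Chat
  backends return hard decisions only, so threshold sweeps and AUCs are
  defined only for score-producing backends.

## Evaluation

Binary rates follow the standard definitions; zero-denominator rates are
reported as 0 with a `degenerate` flag rather than NaN. ROC and PR curve
points come from scikit-learn (all distinct thresholds retained); AUC is
trapezoidal in both cases, which for ROC equals the pairwise concordance
probability P(s⁺ > s⁻) + ½P(tie) — the test suite verifies agreement to
1e-12 against an enumeration oracle. Multilabel averaging: micro pools
item-class cells, macro is the unweighted per-class mean, weighted weighs
classes by gold support. Sample-averaged Jaccard defines empty∕empty = 1
(an item with no predicted and no gold categories is a perfect match);
subset accuracy is exact-set-match and never exceeds the averaged
Jaccard. Reported percentages round half-up to one decimal (two for
confidence rates and F1).

## Synthetic corpus generator

The generator is first-class code, not a fixture. It emulates the
statistical structure of the labeled evaluation corpus:

* prevalence 10.7% of comments containing a DDE, planted **exactly**
  (`round(n × prevalence)` positives) rather than Bernoulli-sampled, so
  small corpora have deterministic class counts;
* root-cause inclusion probabilities 0.670 (personal choices), 0.627
  (adverse reactions), 0.418 (alternative medical reasons), 0.250
  (treatment inefficacy), 0.119 (accessibility issues), 0.103
  (indeterminate), 0.100 (non-discontinuation), 0.096 (treatment
  success), sampled independently per category with at least one forced —
  the real co-occurrence structure is unknown, so independence is a
  declared approximation, and the forcing biases marginals upward
  slightly (tests allow for it);
* 2–6 sentences per comment; 10% of non-DDE comments carry a
  negated-medication hard negative ("I am not on any medication"), the
  documented failure mode of substring-style cues;
* three annotators whose majority equals the planted label, with one
  dissenting in 8.9% of comments, and confidence levels drawn at rates
  0.9633 / 0.034 / 0.0027 — all mirroring the labeled dataset's reported
  aggregates.

Every DDE comment carries one detection-cue sentence plus one cue
sentence per sampled root cause; sentence texts are guaranteed unique
within a corpus so that hash-based mock flips are independent across
sentences. That independence gives closed forms for the comment-level
error rates under flip noise ε: a DDE comment with k cue and m background
sentences is missed with probability ε^k(1−ε)^m, and a clean comment with
m sentences is falsely flagged with probability 1−(1−ε)^m. The matched
mock scorer is constructed from the corpus manifest; at ε = 0 any cutoff
strictly between the baseline (0.01) and the cue score (0.9) recovers the
planted labels and root-cause sets exactly.

What passing these tests shows — and does not show. The synthetic corpus
exercises the plumbing (segmentation, chunking, aggregation, thresholds,
metrics) and the statistical machinery under controlled noise. Its
template English carries none of the lexical ambiguity, typos, sarcasm or
context-dependence of real forum text, so perfect recovery here says
nothing about any particular entailment model's real-data accuracy; real
performance must be measured with a live scorer on labeled data.

## Numerical choices

Cutoff grid values are generated from integer numerators (5..95 over
100), so grid comparisons are exact. Scores are computed once per comment
and thresholded many times during sweeps. The keyword prefilter matches
lexicon terms case-insensitively as whole words (delimited by
non-alphanumerics; multi-word terms as contiguous phrases) — substring
matching would falsely retain e.g. "aspiring" for "aspirin". Duplicate
comment ids are hard errors everywhere: silent last-wins merging corrupts
prediction/gold joins. Majority voting requires an odd panel; ties on an
even panel are undefined by design (the labeling protocol resolved
root-cause disagreements by discussion, not by vote).

## Problem sizes

The test suite and acceptance script run the synthetic pipeline at
200–2000 comments and the oracle-equivalence checks at n ≤ 200 per
instance (100 instances) and 10,000 random chunking profiles — sizes at
which every check completes in seconds while keeping binomial tolerances
(3σ) tight enough to be meaningful.

## Known limitations

* The sentencizer and token counter are deliberate simplifications; CS2
  chunk boundaries will differ from those produced by any specific neural
  tokenizer (the contract, not the boundary positions, is what the
  package guarantees).
* Chat-derived probabilities are not modeled: the chat route is
  binary-only, so CS3 contributes no AUC.
* The generator does not model root-cause co-occurrence, register, or
  multilinguality, and its hard negatives cover one documented failure
  phrasing, not the space of negations.
* No calibration of scorer probabilities and no ensembling across
  strategies or models.
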