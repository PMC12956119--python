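# Methods

## The similarity measure

A story is an ordered list of sentences; each sentence stands in for one
narrative event. This proxy is reasonable for short stories whose sentences
each carry one main action, and it is what makes the measure fully automatic.

**Per-sentence thresholds.** For story A, θᵢ is the maximum similarity
between sentence i and every other sentence of A. The rationale: θᵢ is the
most similar sentence i can be to a sentence describing a *different*
occurrence, so any cross-story match that fails to beat θᵢ cannot be trusted
to describe the *same* occurrence. We apply the threshold per sentence rather
than as one story-global cutoff, because redundancy is a property of the
individual sentence: a formulaic sentence inside an otherwise varied story
needs a stricter criterion than its neighbours. A story-global variant
(`threshold_mode="global"`, every θᵢ replaced by the story-wide maximum) is
kept for sensitivity analysis.

**Remembered / Forgotten.** Strict inequality decides: an exact tie with θᵢ
is Forgotten. Ties among best matches go to the lowest target index —
deterministic and order-respecting. A target sentence may be the best match
of several source sentences (recall often merges events).

**Sequence.** Best matches are computed with *no* threshold so that every
sentence contributes order information, and Spearman's ρ (average ranks for
ties) compares source positions with matched positions. Degenerate cases are
defined, not dropped: a single-sentence story, or a mapping where every
sentence matches the same target position, contributes ρ = 0 — there is no
order information, and 0 is the neutral value under the multiplicative
combination. Mappings whose matched ranks are exactly monotone are returned
as exactly ±1, bypassing the floating-point Pearson route, so that identity
and reversal are algebraically exact.

**Combination.** The symmetrized content and sequence scores are multiplied
(`combined = content × sequence`), not the per-direction products. The
combined score therefore lives in [−1, 1] and is symmetric in its arguments
by construction.

## Similarity backends

Both backends tokenize identically: lowercase, strip punctuation and digits,
split on whitespace.

* `lexical` — Jaccard index of token sets, in [0, 1]. Deterministic,
  dependency-free, and exactly analyzable; the default for testing and
  simulation.
* `vectors` — cosine of the mean word vector of each sentence, in [−1, 1],
  loaded from any word2vec-format text table. This mirrors the standard
  distributional approach for scoring real transcripts; no claim is made that
  scores match any particular published model, since results depend entirely
  on the vector table supplied.

Out-of-vocabulary-only sentences and empty token sets score 0: bounded,
conservative, and keeps thresholds well-defined.

## Cleaning and segmentation

Meta-commentary phrases ("if I remember correctly", "I recall", "I believe",
"I think", plus user additions) are deleted case-insensitively at word
boundaries; a sentence left with fewer than `min_content_tokens` (default 2)
tokens is dropped whole, which is how task-difficulty remarks disappear once
their key phrase is configured. Cleaning is idempotent. The default of 2
keeps minimal complete clauses ("she won.") while discarding fragments left
over from phrase excision. Spelling correction is deliberately out of scope:
no deterministic algorithm exists, and silent rewriting would be worse than
the occasional missed match.

Segmentation splits on terminal punctuation with an abbreviation list
(titles, single initials, e.g./i.e., …). A rule-based splitter was chosen
over a statistical one so that identical input always yields identical
events; the backend-agnostic design accepts pre-segmented stories, so any
external segmenter can be used upstream.

## Evolution metrics

For a lineage (stimulus = day 0, retellings days 1..T):

* stabilization — combined similarity of each adjacent pair, starting with
  (Initial, Day 1); T values.
* consistency — each earlier story vs. the final retelling; T values.
* modification — the stimulus vs. each retelling; T values.
* cross-reference — each retelling vs. an arbitrary reference story (equal to
  modification when the reference is the lineage's own stimulus).

Group curves report per-condition means with SE = s/√n (SE 0, flagged n = 1,
for singleton cells). Inferential statistics are intentionally limited to a
label-shuffle permutation contrast (two-sided, add-one p-value
(c+1)/(n_perm+1)); per-participant series are exported as tidy CSV for any
dedicated statistics package.

## Dispersion

All stories — every day, every condition, stimuli included — are compared
pairwise and embedded in one shared 2-D space, so that subsets (e.g. each
condition's day-5 retellings) are measured in a common geometry. Distances
are d = 1 − s (s ∈ [−1, 1] ⇒ d ∈ [0, 2]); a normalized option (1 − s)/2 is
available. Classical (Torgerson) MDS is the default: double-centering plus
the top-2 eigenpairs, negative eigenvalues truncated at 0, axis signs fixed
by the largest-magnitude coordinate — fully deterministic, and exact when the
distances are genuinely 2-D Euclidean. An iterative SMACOF embedding
(`method="stress"`, seeded) is available when a stress-optimal layout is
preferred. SDD is the root-mean-square distance to the centroid; the
permutation test shuffles story labels over fixed coordinates (two-sided,
add-one, default n_perm = 10,000).

## The synthetic generator

The generator emulates the *statistical* structure the measures consume, not
realistic prose. Each of N events owns a private vocabulary of purely
alphabetic tokens, pairwise disjoint across events, with disjoint synonym
sets for paraphrase and a separate distractor vocabulary for intrusions.
Consequences under the lexical backend: distinct events have similarity
exactly 0, within-story thresholds are 0, and dropping d of N events yields
content exactly 1 − d/(2N) — a closed form the tests verify for every d.

A retelling applies, in order: per-event forgetting (probability p_forget,
redrawn if everything would be forgotten), n_transpositions adjacent swaps
(each attractor-biased with probability λ: one bubble-sort step toward a
condition-level target order, modeling a shared schema; otherwise a uniform
random adjacent swap), per-token paraphrase (probability p_paraphrase), and
an optional intrusion sentence (probability p_intrude). Retellings chain —
day t distorts day t−1 — matching the observation that people stabilize on
their own previous retelling; a from-stimulus mode exists. Adjacent
transpositions (rather than arbitrary permutations) make reorder magnitude a
single interpretable count. Everything is a pure function of (config, seed),
via spawned numpy SeedSequences, so corpora regenerate byte-identically.

Defaults: N = 25 events × 15 tokens (a few-hundred-word story), p_forget =
0.15, n_transpositions = 2, p_paraphrase = 0.1, p_intrude = 0.05, λ = 0,
5 days with a halving noise schedule (0.5^(day−1) scales p_forget and the
swap count) — a first recall that loses and reorders the most, then
progressive settling.

Three named scenarios freeze the study conditions used by the tests and the
acceptance script:

* `settling_config()` — the defaults above; 50 participants. Expected
  pattern: the (Initial, Day 1) pair is the minimum of the stabilization
  curve, and mean consistency is non-decreasing toward Day 5.
* `convergence_scenario()` — two 25-participant conditions sharing N = 12 × 6
  tokens, p_forget = 0.05, 14 transpositions/day (constant schedule),
  p_paraphrase = 0.05; λ = 1 with the stimulus order as attractor
  (`convergent`) vs. λ = 0 (`drifting`). Heavy reordering with low content
  noise makes event order the dominant axis of variation, so the biased
  condition clusters tightly (lower day-5 SDD). Forgetting and paraphrase
  rates were kept low here because content noise affects both conditions
  equally and only dilutes the order contrast.
* `calibration_config()` — a small 6-event, 3-day configuration used to run
  hundreds of null corpora (both conditions identical) quickly when checking
  that the permutation tests reject at their nominal rate.

What the generator does **not** emulate: semantic paraphrase beyond token
substitution, schema-driven *content* intrusions that resemble real events,
gist-level compression of several events into one sentence, or any
correlation between forgetting and serial position. Passing tests therefore
validate the measurement and inference machinery, not the claim that any
particular human corpus will show these effect sizes.

## Numerical choices and problem sizes

* Strict `>` for Remembered; argmax tie-break to the lowest index; average
  ranks in Spearman; exact ±1 short-circuit for monotone rank mappings.
* Distance matrices must be symmetric to 1e−9; CSV matrices are written with
  `%.17g` and parsed with round-trip float precision, so they round-trip
  bit-exactly.
* Permutation p-values use the add-one estimator and are deterministic given
  a seed; they can never be below 1/(n_perm+1).
* The test suite and acceptance script run the full pipeline at moderate
  scale — 400 null corpora of 2 × 8 participants for calibration, 100 (tests)
  or 40 (script) corpora of 2 × 25 participants for the convergence contrast,
  one 50-participant corpus for the settling pattern — sizes chosen to give
  stable Monte-Carlo estimates while keeping a full run in a few minutes.

## Known limitations

* Sentence = event is an approximation; long multi-clause sentences dilute
  both measures.
* The lexical backend is blind to synonymy in real text; the vector backend's
  scores depend entirely on the supplied table.
* The sequence measure assigns unmatched (forgotten) events their best
  available match anyway, which adds rank noise when two stories share few
  events; this is inherent to the thresholdless design.
* 2-D MDS of many nearly-equidistant stories compresses structure; SDD
  contrasts remain valid (they live in the shared embedding) but absolute SDD
  values should not be compared across corpora or embeddings.
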