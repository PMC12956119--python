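"""The core story-similarity measure.

Two retellings are compared on two axes and the axes are multiplied:

*Content.* Each sentence of story A carries its own admission threshold
θ_i — the highest similarity between that sentence and any *other* sentence
within A. Sentence i counts as *remembered* in story B only when its best
match in B strictly exceeds θ_i; otherwise the match is no closer than A's
own internal redundancy allows, so it likely depicts a different occurrence
and the event counts as *forgotten*. The directional content score is the
remembered fraction; the two directions are averaged.

*Sequence.* Each sentence of A is mapped to its best match in B with no
threshold (a best match always exists), and the Spearman rank correlation
between A's sentence positions and the matched positions measures how well
event order is preserved. Both directions are averaged.

*Combined.* content × sequence, in [-1, 1]: high only when a story keeps
both its events and their order; negative when the order is reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus_io import Story
from .embeddings import SimilarityBackend, pairwise_matrix
from .errors import ContractError

__all__ = [
    "MatchResult",
    "StorySimilarity",
    "within_story_thresholds",
    "match_events",
    "content_similarity",
    "sequence_similarity",
    "story_similarity",
]


@dataclass
class MatchResult:
    """Directional A→B matching: thresholds, best matches, remembered flags."""

    reference_id: str
    target_id: str
    thresholds: np.ndarray  # θ_i per reference sentence
    best_index: np.ndarray  # index into target sentences
    best_sim: np.ndarray
    remembered: np.ndarray  # best_sim_i > θ_i (strict)

    @property
    def n_remembered(self) -> int:
        return int(self.remembered.sum())


@dataclass
class StorySimilarity:
    """Symmetrized content, sequence, and combined scores for a story pair."""

    story_a: str
    story_b: str
    content_ab: float
    content_ba: float
    content: float
    sequence_ab: float
    sequence_ba: float
    sequence: float
    combined: float


def within_story_thresholds(
    sentences: list[str],
    backend: SimilarityBackend,
    threshold_mode: str = "per_sentence",
) -> np.ndarray:
    """Per-sentence admission thresholds θ_i = max_{j≠i} sim(sent_i, sent_j).

    A single-sentence story gets θ = 0 (no internal comparison exists).
    ``threshold_mode='global'`` replaces every θ_i with the story-wide
    maximum over all within-story pairs, for sensitivity analysis.
    """
    if not sentences:
        raise ContractError("within_story_thresholds requires >= 1 sentence")
    n = len(sentences)
    if n == 1:
        return np.zeros(1)
    within = pairwise_matrix(backend, sentences, sentences)
    np.fill_diagonal(within, -np.inf)
    theta = within.max(axis=1)
    if threshold_mode == "global":
        theta = np.full(n, theta.max())
    elif threshold_mode != "per_sentence":
        raise ContractError(f"unknown threshold_mode {threshold_mode!r}")
    return theta


def _require_segmented(story: Story) -> None:
    if not story.sentences:
        raise ContractError(
            f"story {story.story_id!r} has no sentences; segment it before comparing"
        )


def match_events(
    ref: Story,
    target: Story,
    backend: SimilarityBackend,
    threshold_mode: str = "per_sentence",
) -> MatchResult:
    """Match every reference sentence to its best target sentence.

    Ties go to the lowest target index; a target sentence may serve as the
    best match for several reference sentences. ``remembered`` requires the
    best similarity to *strictly* exceed that sentence's threshold — an exact
    tie with the story's internal redundancy is not good enough.
    """
    _require_segmented(ref)
    _require_segmented(target)
    theta = within_story_thresholds(ref.sentences, backend, threshold_mode)
    cross = pairwise_matrix(backend, ref.sentences, target.sentences)
    best_index = cross.argmax(axis=1)  # argmax takes the lowest index on ties
    best_sim = cross[np.arange(len(ref.sentences)), best_index]
    return MatchResult(
        reference_id=ref.story_id,
        target_id=target.story_id,
        thresholds=theta,
        best_index=best_index,
        best_sim=best_sim,
        remembered=best_sim > theta,
    )


def content_similarity(
    a: Story,
    b: Story,
    backend: SimilarityBackend,
    threshold_mode: str = "per_sentence",
) -> tuple[float, float, float]:
    """(content_ab, content_ba, mean): remembered fractions in both directions."""
    ab = match_events(a, b, backend, threshold_mode)
    ba = match_events(b, a, backend, threshold_mode)
    content_ab = ab.n_remembered / len(a.sentences)
    content_ba = ba.n_remembered / len(b.sentences)
    return content_ab, content_ba, (content_ab + content_ba) / 2.0


def _sequence_from_cross(cross: np.ndarray) -> float:
    """Directional sequence score from a precomputed |ref| x |target| matrix."""
    matched = cross.argmax(axis=1) + 1  # 1-based target positions
    n = cross.shape[0]
    if n < 2 or np.all(matched == matched[0]):
        return 0.0  # no order information in a constant mapping
    # perfectly monotone mappings are exactly +/-1; skip the floating-point
    # detour through Pearson, which loses an ulp for some n
    ranks = stats.rankdata(matched)
    ref_ranks = np.arange(1, n + 1, dtype=float)
    if np.array_equal(ranks, ref_ranks):
        return 1.0
    if np.array_equal(ranks, ref_ranks[::-1]):
        return -1.0
    rho = stats.spearmanr(ref_ranks, matched).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _directional_sequence(ref: Story, target: Story, backend: SimilarityBackend) -> float:
    return _sequence_from_cross(pairwise_matrix(backend, ref.sentences, target.sentences))


def _scores_from_cross(
    cross: np.ndarray, theta_a: np.ndarray, theta_b: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """All symmetrized scores from one cross matrix and both threshold vectors.

    Shared by :func:`story_similarity` and the all-pairs path so both produce
    bitwise-identical results.
    """
    content_ab = float((cross.max(axis=1) > theta_a).mean())
    content_ba = float((cross.max(axis=0) > theta_b).mean())
    content = (content_ab + content_ba) / 2.0
    seq_ab = _sequence_from_cross(cross)
    seq_ba = _sequence_from_cross(cross.T)
    sequence = (seq_ab + seq_ba) / 2.0
    return content_ab, content_ba, content, seq_ab, seq_ba, sequence


def sequence_similarity(
    a: Story, b: Story, backend: SimilarityBackend
) -> tuple[float, float, float]:
    """(sequence_ab, sequence_ba, mean): rank correlation of matched order.

    No threshold is applied — every sentence gets its best available match —
    so the score reflects order alone, not retention. Average ranks break
    ties; a single-sentence story or a constant mapping contributes 0.
    """
    _require_segmented(a)
    _require_segmented(b)
    seq_ab = _directional_sequence(a, b, backend)
    seq_ba = _directional_sequence(b, a, backend)
    return seq_ab, seq_ba, (seq_ab + seq_ba) / 2.0


def story_similarity(
    a: Story,
    b: Story,
    backend: SimilarityBackend,
    threshold_mode: str = "per_sentence",
) -> StorySimilarity:
    """Full symmetrized similarity; ``combined = content × sequence`` exactly."""
    _require_segmented(a)
    _require_segmented(b)
    theta_a = within_story_thresholds(a.sentences, backend, threshold_mode)
    theta_b = within_story_thresholds(b.sentences, backend, threshold_mode)
    cross = pairwise_matrix(backend, a.sentences, b.sentences)
    content_ab, content_ba, content, seq_ab, seq_ba, sequence = _scores_from_cross(
        cross, theta_a, theta_b
    )
    return StorySimilarity(
        story_a=a.story_id,
        story_b=b.story_id,
        content_ab=content_ab,
        content_ba=content_ba,
        content=content,
        sequence_ab=seq_ab,
        sequence_ba=seq_ba,
        sequence=sequence,
        combined=content * sequence,
    )
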