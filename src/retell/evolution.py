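"""Evolution metrics over a retelling lineage and group-level contrasts.

Three trajectories summarize how one participant's story changes over days:

* *stabilization* — similarity between each adjacent pair of retellings
  (Initial–Day1, Day1–Day2, ...): when does the story stop changing?
* *consistency* — similarity of every earlier story to the final retelling:
  how early did the story settle into its final form?
* *modification* — similarity of the initial stimulus to each retelling:
  how far has the story drifted from its origin?

All three use the combined story-similarity score. ``cross_reference_series``
generalizes modification to an arbitrary reference story (e.g. the *other*
condition's stimulus), which is how a scrambled-story lineage can be scored
against the coherent original.

Group inference here is deliberately nonparametric: per-participant series
are exported as tidy tables for any statistics package, and a label-shuffle
permutation test provides a between-condition contrast on any one comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import RetellingLineage, Story
from .embeddings import SimilarityBackend
from .errors import ContractError
from .similarity import story_similarity

__all__ = [
    "EvolutionSeries",
    "PermutationResult",
    "day_label",
    "stabilization_series",
    "consistency_series",
    "modification_series",
    "cross_reference_series",
    "series_to_frame",
    "group_curves",
    "condition_permutation_test",
]


def day_label(day: int) -> str:
    return "Initial" if day == 0 else f"Day{day}"


@dataclass
class EvolutionSeries:
    """One metric trajectory for one participant's lineage."""

    participant_id: str
    condition: str
    metric: str  # stabilization | consistency | modification | cross_reference
    labels: list[str]  # e.g. "Initial-Day1"
    values: list[float]  # combined similarity, aligned to labels

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ContractError(
                f"{self.metric} series: {len(self.labels)} labels vs "
                f"{len(self.values)} values"
            )


def _pair_label(day_a: int, day_b: int) -> str:
    return f"{day_label(day_a)}-{day_label(day_b)}"


def _combined(a: Story, b: Story, backend: SimilarityBackend) -> float:
    return story_similarity(a, b, backend).combined


def stabilization_series(
    lineage: RetellingLineage, backend: SimilarityBackend
) -> EvolutionSeries:
    """Combined similarity of each adjacent day pair, in day order."""
    if len(lineage.stories) < 2:
        raise ContractError("stabilization needs >= 2 stories in the lineage")
    labels, values = [], []
    for earlier, later in zip(lineage.stories, lineage.stories[1:]):
        labels.append(_pair_label(earlier.day, later.day))
        values.append(_combined(earlier, later, backend))
    return EvolutionSeries(
        lineage.participant_id, lineage.condition, "stabilization", labels, values
    )


def consistency_series(
    lineage: RetellingLineage, backend: SimilarityBackend
) -> EvolutionSeries:
    """Combined similarity of every earlier story to the final retelling."""
    if len(lineage.stories) < 2:
        raise ContractError("consistency needs >= 2 stories in the lineage")
    final = lineage.stories[-1]
    labels, values = [], []
    for story in lineage.stories[:-1]:
        labels.append(_pair_label(story.day, final.day))
        values.append(_combined(story, final, backend))
    return EvolutionSeries(
        lineage.participant_id, lineage.condition, "consistency", labels, values
    )


def modification_series(
    lineage: RetellingLineage, backend: SimilarityBackend
) -> EvolutionSeries:
    """Combined similarity of the day-0 stimulus to each retelling."""
    if not lineage.stories or lineage.stories[0].day != 0:
        raise ContractError(
            f"modification needs a day-0 story in lineage "
            f"({lineage.participant_id}, {lineage.condition})"
        )
    initial = lineage.stories[0]
    labels, values = [], []
    for story in lineage.stories[1:]:
        labels.append(_pair_label(0, story.day))
        values.append(_combined(initial, story, backend))
    return EvolutionSeries(
        lineage.participant_id, lineage.condition, "modification", labels, values
    )


def cross_reference_series(
    lineage: RetellingLineage,
    reference: Story,
    backend: SimilarityBackend,
) -> EvolutionSeries:
    """Combined similarity of each retelling (days >= 1) to ``reference``.

    With the lineage's own stimulus as reference this reproduces
    :func:`modification_series` exactly.
    """
    if not reference.sentences:
        raise ContractError("cross_reference requires a segmented, non-empty reference")
    labels, values = [], []
    for story in lineage.stories:
        if story.day == 0:
            continue
        labels.append(f"Ref-{day_label(story.day)}")
        values.append(_combined(reference, story, backend))
    return EvolutionSeries(
        lineage.participant_id, lineage.condition, "cross_reference", labels, values
    )


def series_to_frame(series_collection: list[EvolutionSeries]) -> pd.DataFrame:
    """Long-format table: participant_id, condition, metric, label, value."""
    rows = [
        {
            "participant_id": s.participant_id,
            "condition": s.condition,
            "metric": s.metric,
            "label": lab,
            "value": val,
        }
        for s in series_collection
        for lab, val in zip(s.labels, s.values)
    ]
    return pd.DataFrame(rows)


def group_curves(series_collection: list[EvolutionSeries]) -> pd.DataFrame:
    """Per-condition mean and standard error per comparison label.

    SE uses the sample standard deviation (ddof=1); a single-participant cell
    reports SE 0 and is flagged via its ``n`` column. Label order follows the
    order of first appearance across the input series.
    """
    if not series_collection:
        raise ContractError("group_curves requires at least one series")
    frame = series_to_frame(series_collection)
    # comparison labels are ordered per metric, by first appearance
    label_pos: dict[tuple[str, str], int] = {}
    for s in series_collection:
        for lab in s.labels:
            label_pos.setdefault((s.metric, lab), len(label_pos))
    rows = []
    for (cond, metric, label), grp in frame.groupby(
        ["condition", "metric", "label"], sort=False
    ):
        vals = grp["value"].to_numpy()
        n = len(vals)
        rows.append(
            {
                "condition": cond,
                "metric": metric,
                "label": label,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n": n,
            }
        )
    out = pd.DataFrame(rows)
    out["_pos"] = [label_pos[(m, l)] for m, l in zip(out["metric"], out["label"])]
    return (
        out.sort_values(["condition", "metric", "_pos"])
        .drop(columns="_pos")
        .reset_index(drop=True)
    )


@dataclass
class PermutationResult:
    """Two-sided permutation contrast between two conditions at one label."""

    label: str
    conditions: tuple[str, str]
    observed_difference: float  # mean(cond1) - mean(cond2)
    p_value: float
    n_perm: int
    seed: int | None


def condition_permutation_test(
    series_collection: list[EvolutionSeries],
    label: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Shuffle participant condition labels to test a group mean difference.

    The observed statistic is the difference of condition means of the metric
    value at ``label``. Exactly two conditions are required, each with at
    least two participants. Two-sided add-one p-value:
    ``(count(|Δ_perm| >= |Δ_obs|) + 1) / (n_perm + 1)``.
    """
    per_participant: dict[str, list[float]] = defaultdict(list)
    for s in series_collection:
        if label in s.labels:
            per_participant[s.condition].append(s.values[s.labels.index(label)])
    conditions = sorted(per_participant)
    if len(conditions) != 2:
        raise ContractError(
            f"permutation test needs exactly 2 conditions, got {conditions}"
        )
    n1, n2 = (len(per_participant[c]) for c in conditions)
    if n1 < 2 or n2 < 2:
        raise ContractError("each condition needs >= 2 participants")

    values = np.array(per_participant[conditions[0]] + per_participant[conditions[1]])
    observed = values[:n1].mean() - values[n1:].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if abs(perm[:n1].mean() - perm[n1:].mean()) >= abs(observed):
            count += 1
    return PermutationResult(
        label=label,
        conditions=(conditions[0], conditions[1]),
        observed_difference=float(observed),
        p_value=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
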