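"""Synthetic serial-reproduction corpus generator.

Emulates the structure of a repeated-reproduction study — a stimulus story of
N single-action sentences, followed by daily retellings per participant in two
(or more) conditions — with a controllable forward model of recall distortion:

* *forgetting*: each event is dropped with a per-day probability;
* *reordering*: a number of adjacent transpositions, each either random or
  biased one bubble-sort step toward a condition-level *attractor* order
  (modeling convergence on a shared schema);
* *paraphrase*: tokens are replaced by synonyms from disjoint synonym sets;
* *intrusion*: occasionally a sentence of novel distractor content appears.

Every event owns a private, pairwise-disjoint vocabulary of purely alphabetic
tokens, so under the lexical backend distinct events have similarity exactly 0
and the analytic behavior of the similarity measures is known in closed form
(e.g. dropping d of N events yields content 1 - d/(2N) exactly). Retellings
chain by default (day t is produced from day t-1), matching the empirical
picture that retellings stabilize on their own previous versions.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import RetellingLineage, Story
from .errors import ContractError

__all__ = [
    "GeneratorConfig",
    "ConditionSpec",
    "generate_base_story",
    "generate_retelling",
    "generate_corpus",
    "scramble_story",
    "drop_events",
    "noise_multiplier",
    "settling_config",
    "convergence_scenario",
    "calibration_config",
]

# digits 0-9 encoded as letters a-j keeps every token purely alphabetic
_DIGITS = "abcdefghij"


def _enc(value: int) -> str:
    return "".join(_DIGITS[int(ch)] for ch in str(value))


def _dec(text: str) -> int:
    return int("".join(str(_DIGITS.index(ch)) for ch in text))


def _event_token(event: int, slot: int, variant: int) -> str:
    # 'x'/'y' are outside the digit alphabet, so parsing is unambiguous
    return f"ev{_enc(event)}x{_enc(slot)}y{_enc(variant)}"


def _parse_event_token(token: str) -> tuple[int, int, int] | None:
    if not token.startswith("ev"):
        return None
    try:
        body = token[2:]
        ev, rest = body.split("x", 1)
        slot, variant = rest.split("y", 1)
        return _dec(ev), _dec(slot), _dec(variant)
    except (ValueError, IndexError):
        return None


def _distractor_token(uid: int, slot: int) -> str:
    return f"zq{_enc(uid)}x{_enc(slot)}"


@dataclass
class GeneratorConfig:
    """Forward-model settings for one simulated condition.

    ``noise_schedule`` scales ``p_forget`` and ``n_transpositions`` per day:
    ``"halving"`` uses 0.5**(day-1) (noisiest first retelling, then settling),
    ``"constant"`` applies no scaling, and a sequence gives explicit per-day
    multipliers. ``convergence`` is the probability that each transposition
    is an attractor-biased bubble-sort step rather than a random swap.
    """

    n_events: int = 25
    tokens_per_event: int = 15
    p_forget: float = 0.15
    n_transpositions: int = 2
    p_paraphrase: float = 0.1
    p_intrude: float = 0.05
    convergence: float = 0.0
    noise_schedule: str | Sequence[float] = "halving"
    n_days: int = 5
    n_synonyms: int = 2
    chain_mode: str = "chained"  # or "from_stimulus"

    def __post_init__(self) -> None:
        if self.n_events < 2:
            raise ContractError("n_events must be >= 2")
        if self.tokens_per_event < 2:
            raise ContractError("tokens_per_event must be >= 2")
        if not 0.0 <= self.p_forget < 1.0:
            raise ContractError("p_forget must be in [0, 1)")
        if self.n_transpositions < 0:
            raise ContractError("n_transpositions must be >= 0")
        for name in ("p_paraphrase", "p_intrude", "convergence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ContractError(f"{name} must be in [0, 1]")
        if self.n_days < 1:
            raise ContractError("n_days must be >= 1")
        if self.n_synonyms < 0:
            raise ContractError("n_synonyms must be >= 0")
        if self.chain_mode not in ("chained", "from_stimulus"):
            raise ContractError(f"unknown chain_mode {self.chain_mode!r}")


def noise_multiplier(schedule: str | Sequence[float], day: int) -> float:
    """Per-day multiplier applied to (p_forget, n_transpositions)."""
    if day < 1:
        raise ContractError("retelling days start at 1")
    if isinstance(schedule, str):
        if schedule == "halving":
            return 0.5 ** (day - 1)
        if schedule == "constant":
            return 1.0
        raise ContractError(f"unknown noise_schedule {schedule!r}")
    seq = list(schedule)
    if not seq:
        raise ContractError("noise_schedule sequence is empty")
    return float(seq[min(day - 1, len(seq) - 1)])


def generate_base_story(
    config: GeneratorConfig,
    seed: int,
    story_id: str | None = None,
    condition: str = "sim",
) -> Story:
    """Build the stimulus: one sentence per event, disjoint vocabularies.

    Token order within each sentence is shuffled by ``seed``; the token *sets*
    (hence all lexical similarities) do not depend on it. Within-story
    pairwise similarities are exactly 0 under the lexical backend.
    """
    rng = np.random.default_rng(seed)
    sentences = []
    for ev in range(config.n_events):
        tokens = [_event_token(ev, k, 0) for k in range(config.tokens_per_event)]
        order = rng.permutation(len(tokens))
        sentences.append(" ".join(tokens[i] for i in order) + ".")
    text = " ".join(sentences)
    return Story(
        story_id=story_id or f"stim-{condition}",
        participant_id=None,
        condition=condition,
        day=0,
        raw_text=text,
        sentences=sentences,
    )


def drop_events(story: Story, indices: Sequence[int]) -> Story:
    """Delete the sentences at ``indices``; at least one must survive."""
    drop = set(int(i) for i in indices)
    kept = [s for i, s in enumerate(story.sentences) if i not in drop]
    if not story.sentences:
        raise ContractError("cannot drop events from an unsegmented story")
    if not kept:
        raise ContractError("drop_events would remove every sentence")
    return dataclasses.replace(
        story, sentences=kept, raw_text=" ".join(kept), story_id=story.story_id + "-drop"
    )


def scramble_story(story: Story, seed: int) -> Story:
    """Uniformly permute the sentences (identity redrawn when possible)."""
    if not story.sentences:
        raise ContractError("cannot scramble an empty story")
    rng = np.random.default_rng(seed)
    n = len(story.sentences)
    perm = rng.permutation(n)
    while n > 1 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    sentences = [story.sentences[i] for i in perm]
    return dataclasses.replace(
        story,
        sentences=sentences,
        raw_text=" ".join(sentences),
        story_id=story.story_id + "-scrambled",
    )


def _sentence_event(sentence: str) -> int | None:
    for token in sentence.rstrip(".").split():
        parsed = _parse_event_token(token)
        if parsed is not None:
            return parsed[0]
    return None


def _paraphrase_sentence(
    sentence: str, p: float, n_synonyms: int, rng: np.random.Generator
) -> str:
    if p <= 0.0 or n_synonyms == 0:
        return sentence
    out = []
    for token in sentence.rstrip(".").split():
        parsed = _parse_event_token(token)
        if parsed is not None and rng.random() < p:
            ev, slot, variant = parsed
            choices = [v for v in range(n_synonyms + 1) if v != variant]
            token = _event_token(ev, slot, int(rng.choice(choices)))
        out.append(token)
    return " ".join(out) + "."


def _biased_swap(
    sentences: list[str], attractor_rank: dict[int, int], rng: np.random.Generator
) -> None:
    """One bubble-sort step toward the attractor order, in place."""
    candidates = []
    for p in range(len(sentences) - 1):
        ev_a = _sentence_event(sentences[p])
        ev_b = _sentence_event(sentences[p + 1])
        if ev_a in attractor_rank and ev_b in attractor_rank:
            if attractor_rank[ev_a] > attractor_rank[ev_b]:
                candidates.append(p)
    if candidates:
        p = int(rng.choice(candidates))
        sentences[p], sentences[p + 1] = sentences[p + 1], sentences[p]


def generate_retelling(
    source: Story,
    config: GeneratorConfig,
    day: int,
    seed: int,
    attractor: Sequence[int] | None = None,
    story_id: str | None = None,
) -> Story:
    """One day's recall of ``source``: drop, reorder, paraphrase, intrude.

    Distortions apply in that order, with the day's noise multiplier scaling
    the forgetting probability and the transposition count. ``attractor`` is
    the condition-level target event order used by convergence-biased swaps;
    it defaults to the source's own event order.
    """
    if not source.sentences:
        raise ContractError("cannot retell an empty story")
    rng = np.random.default_rng(seed)
    mult = noise_multiplier(config.noise_schedule, day)
    p_forget = config.p_forget * mult
    n_swaps = int(np.floor(config.n_transpositions * mult + 0.5))

    # forgetting — redrawn if everything would be forgotten
    keep = rng.random(len(source.sentences)) >= p_forget
    while not keep.any():
        keep = rng.random(len(source.sentences)) >= p_forget
    sentences = [s for s, k in zip(source.sentences, keep) if k]

    # reordering
    if attractor is None:
        attractor = [e for e in (_sentence_event(s) for s in source.sentences) if e is not None]
    rank = {ev: i for i, ev in enumerate(attractor)}
    for _ in range(n_swaps):
        if len(sentences) < 2:
            break
        if rng.random() < config.convergence:
            _biased_swap(sentences, rank, rng)
        else:
            p = int(rng.integers(len(sentences) - 1))
            sentences[p], sentences[p + 1] = sentences[p + 1], sentences[p]

    # paraphrase
    sentences = [
        _paraphrase_sentence(s, config.p_paraphrase, config.n_synonyms, rng)
        for s in sentences
    ]

    # intrusion of novel content
    if rng.random() < config.p_intrude:
        uid = int(rng.integers(1_000_000))
        intrusion = (
            " ".join(_distractor_token(uid, k) for k in range(config.tokens_per_event))
            + "."
        )
        pos = int(rng.integers(len(sentences) + 1))
        sentences.insert(pos, intrusion)

    return Story(
        story_id=story_id or f"{source.story_id}-d{day}",
        participant_id=source.participant_id,
        condition=source.condition,
        day=day,
        raw_text=" ".join(sentences),
        sentences=sentences,
    )


@dataclass
class ConditionSpec:
    """One simulated condition: a name plus overrides of the base config.

    ``scramble_stimulus`` turns the shared base story into a randomly
    shuffled stimulus (an incoherent-story condition). ``attractor`` sets
    the convergence target order: ``"stimulus"`` (that condition's stimulus
    order) or an explicit event-index sequence.
    """

    name: str
    overrides: dict = field(default_factory=dict)
    scramble_stimulus: bool = False
    attractor: str | Sequence[int] = "stimulus"


def settling_config() -> GeneratorConfig:
    """Repeated-reproduction scenario: noisy first recall, then settling.

    The halving noise schedule makes the first retelling the most distorted
    and later ones progressively faithful copies of their predecessors — the
    regime in which adjacent-day similarity is lowest for (Initial, Day 1)
    and similarity to the final retelling grows monotonically.
    """
    return GeneratorConfig()


def convergence_scenario() -> tuple[GeneratorConfig, list["ConditionSpec"]]:
    """Two-condition scenario contrasting schema-driven convergence.

    Both conditions share heavy, constant day-to-day reordering; in the
    ``convergent`` condition every transposition is a bubble-sort step toward
    the shared stimulus order (a strong common schema), while the ``drifting``
    condition reorders at random. Cross-participant dispersion (day-5 SDD)
    should come out lower for the convergent condition.
    """
    config = GeneratorConfig(
        n_events=12,
        tokens_per_event=6,
        p_forget=0.05,
        n_transpositions=14,
        p_paraphrase=0.05,
        p_intrude=0.05,
        noise_schedule="constant",
    )
    conditions = [
        ConditionSpec("convergent", overrides={"convergence": 1.0}),
        ConditionSpec("drifting", overrides={"convergence": 0.0}),
    ]
    return config, conditions


def calibration_config() -> GeneratorConfig:
    """Small, fast configuration for null-calibration simulations."""
    return GeneratorConfig(
        n_events=6,
        tokens_per_event=4,
        p_forget=0.1,
        n_transpositions=2,
        p_paraphrase=0.1,
        p_intrude=0.05,
        noise_schedule="constant",
        n_days=3,
    )


def _spawn_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_corpus(
    config: GeneratorConfig,
    n_participants: int,
    conditions: Sequence[ConditionSpec],
    seed: int,
    out_dir: str | Path | None = None,
) -> list[RetellingLineage]:
    """Simulate a full study: per condition, per participant, a lineage.

    All conditions share one base story (so between-condition contrasts are
    exchangeable under the null of identical settings); each condition may
    override any config field, scramble its stimulus, or set its attractor.
    With ``out_dir`` set, story files, a ``manifest.csv`` consumable by
    :func:`retell.corpus_io.load_manifest`, and the resolved config JSON are
    written there. Byte-identical regeneration from the same seed.
    """
    if n_participants < 1:
        raise ContractError("n_participants must be >= 1")
    if not conditions:
        raise ContractError("at least one condition is required")

    root = np.random.SeedSequence(seed)
    base_seq, scramble_seq, participants_seq = root.spawn(3)
    base = generate_base_story(config, _spawn_int(base_seq))

    lineages: list[RetellingLineage] = []
    manifest_rows: list[dict] = []
    stimulus_files: dict[str, str] = {}

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "stories").mkdir(parents=True, exist_ok=True)

    scramble_seeds = scramble_seq.spawn(len(conditions))
    part_seqs = participants_seq.spawn(len(conditions))

    for ci, cond in enumerate(conditions):
        cfg = dataclasses.replace(config, **cond.overrides)
        stimulus = base
        if cond.scramble_stimulus:
            stimulus = scramble_story(base, _spawn_int(scramble_seeds[ci]))
        stimulus = dataclasses.replace(
            stimulus, story_id=f"stim-{cond.name}", condition=cond.name
        )
        if cond.attractor == "stimulus":
            attractor = [
                e for e in (_sentence_event(s) for s in stimulus.sentences) if e is not None
            ]
        else:
            attractor = list(cond.attractor)

        if out_path is not None:
            stim_file = f"stories/stim_{cond.name}.txt"
            (out_path / stim_file).write_text(stimulus.raw_text + "\n", encoding="utf-8")
            stimulus_files[cond.name] = stim_file

        per_participant = part_seqs[ci].spawn(n_participants)
        for p in range(n_participants):
            pid = f"p{p + 1:03d}"
            day_seqs = per_participant[p].spawn(cfg.n_days)
            day0 = dataclasses.replace(
                stimulus, participant_id=pid, story_id=f"{cond.name}-{pid}-d0"
            )
            stories = [day0]
            prev = day0
            for day in range(1, cfg.n_days + 1):
                source = day0 if cfg.chain_mode == "from_stimulus" else prev
                retelling = generate_retelling(
                    source,
                    cfg,
                    day,
                    _spawn_int(day_seqs[day - 1]),
                    attractor=attractor,
                    story_id=f"{cond.name}-{pid}-d{day}",
                )
                stories.append(retelling)
                prev = retelling
            lineages.append(RetellingLineage(pid, cond.name, stories))

            if out_path is not None:
                for story in stories:
                    if story.day == 0:
                        rel = stimulus_files[cond.name]
                    else:
                        rel = f"stories/{story.story_id}.txt"
                        (out_path / rel).write_text(
                            story.raw_text + "\n", encoding="utf-8"
                        )
                    manifest_rows.append(
                        {
                            "participant_id": pid,
                            "condition": cond.name,
                            "day": story.day,
                            "path": rel,
                        }
                    )

    if out_path is not None:
        import pandas as pd

        pd.DataFrame(manifest_rows).to_csv(out_path / "manifest.csv", index=False)
        resolved = {
            "seed": seed,
            "n_participants": n_participants,
            "config": dataclasses.asdict(config),
            "conditions": [
                {
                    "name": c.name,
                    "overrides": c.overrides,
                    "scramble_stimulus": c.scramble_stimulus,
                    "attractor": c.attractor
                    if isinstance(c.attractor, str)
                    else list(c.attractor),
                }
                for c in conditions
            ],
        }
        (out_path / "config.json").write_text(
            json.dumps(resolved, indent=2, default=list) + "\n", encoding="utf-8"
        )
    return lineages
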