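"""Corpus input/output: stories, lineages, cleaning, and sentence segmentation.

A *story* is one written text at one point in a retelling lineage — either the
stimulus participants heard/read (day 0) or one of their recalls (day 1..T).
Sentences stand in as the unit of narrative events throughout the package, so
segmentation here defines what every downstream measure treats as "an event".

Cleaning removes meta-commentary (hedges such as "if I remember correctly")
that describes the act of remembering rather than the story itself; the
similarity measures should never credit two participants for hedging alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError

__all__ = [
    "Story",
    "RetellingLineage",
    "CleaningConfig",
    "DEFAULT_META_PHRASES",
    "load_manifest",
    "clean_text",
    "segment_sentences",
    "prepare_lineage",
    "write_matrix",
    "read_matrix",
]

#: Hedging phrases removed from every retelling before analysis.
DEFAULT_META_PHRASES: tuple[str, ...] = (
    "if i remember correctly",
    "i recall",
    "i believe",
    "i think",
)

# Tokens after which a period does not end a sentence.
_ABBREVIATIONS = {
    "mr", "mrs", "ms", "dr", "prof", "sr", "jr", "st", "vs", "etc",
    "e.g", "i.e", "cf", "fig", "no", "al", "inc", "ltd", "dept", "approx",
}

_TERMINAL = ".!?"
_TRAILING = "\"')]"  # closing quotes/brackets that may follow the terminal mark


@dataclass
class Story:
    """One text at one point in a retelling lineage.

    ``day`` 0 is reserved for the stimulus story; days 1..T are retellings.
    ``participant_id`` is ``None`` for stimulus stories that belong to a
    condition rather than to a person. ``sentences`` stays empty until the
    story has been cleaned and segmented (see :func:`prepare_lineage`).
    """

    story_id: str
    participant_id: str | None
    condition: str
    day: int
    raw_text: str
    sentences: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class RetellingLineage:
    """Day-ordered stories of one participant in one condition."""

    participant_id: str
    condition: str
    stories: list[Story]

    def __post_init__(self) -> None:
        days = [s.day for s in self.stories]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DataError(
                f"lineage ({self.participant_id}, {self.condition}): "
                f"days not strictly increasing: {days}"
            )

    @property
    def days(self) -> list[int]:
        return [s.day for s in self.stories]

    def story_on(self, day: int) -> Story:
        for s in self.stories:
            if s.day == day:
                return s
        raise DataError(
            f"lineage ({self.participant_id}, {self.condition}) has no day {day}"
        )


@dataclass
class CleaningConfig:
    """Settings for meta-commentary removal.

    ``meta_phrases`` are matched case-insensitively at word boundaries and
    deleted wherever they occur. Any sentence left with fewer than
    ``min_content_tokens`` tokens afterwards is dropped entirely — this is how
    whole task-difficulty remarks disappear once their core phrase is listed.
    """

    meta_phrases: tuple[str, ...] = DEFAULT_META_PHRASES
    min_content_tokens: int = 2

    def __post_init__(self) -> None:
        if self.min_content_tokens < 1:
            raise ConfigurationError("min_content_tokens must be >= 1")

    def with_extra_phrases(self, phrases: Iterable[str]) -> "CleaningConfig":
        return replace(self, meta_phrases=self.meta_phrases + tuple(phrases))


def _tokenize(text: str) -> list[str]:
    """Lowercase word tokens with punctuation stripped."""
    return re.findall(r"[^\W_]+", text.lower())


def _phrase_pattern(phrase: str) -> re.Pattern[str]:
    words = [re.escape(w) for w in phrase.split()]
    return re.compile(r"\b" + r"\s+".join(words) + r"\b", re.IGNORECASE)


def segment_sentences(text: str) -> list[str]:
    """Split ``text`` into trimmed sentences on terminal punctuation.

    Periods after common abbreviations (``Dr.``, ``e.g.``) and after single
    initials do not end a sentence. Deterministic; empty input yields ``[]``.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in _TERMINAL:
            j = i
            while j + 1 < n and text[j + 1] in _TERMINAL + _TRAILING:
                j += 1
            at_end = j + 1 >= n
            if at_end or text[j + 1].isspace():
                if text[i] == "." and not _boundary_after_period(text, start, i):
                    i += 1
                    continue
                sent = text[start : j + 1].strip()
                if sent:
                    sentences.append(sent)
                start = j + 1
                i = j + 1
                continue
        i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _boundary_after_period(text: str, start: int, i: int) -> bool:
    """True when the period at ``text[i]`` really ends a sentence."""
    prev = text[start:i].split()
    if not prev:
        return True
    word = prev[-1].rstrip(".").lstrip("(\"'").lower()
    if word in _ABBREVIATIONS:
        return False
    if len(word) == 1 and word.isalpha():  # single initial, "J."
        return False
    return True


def clean_text(raw_text: str, config: CleaningConfig | None = None) -> str:
    """Remove meta-commentary from ``raw_text`` and normalize whitespace.

    Every occurrence of each configured phrase is deleted (case-insensitive,
    word-boundary anchored); sentences left with fewer than
    ``min_content_tokens`` tokens are dropped whole. Idempotent: cleaning
    already-clean text is the identity. Empty output is legal.
    """
    config = config or CleaningConfig()
    text = raw_text
    for phrase in config.meta_phrases:
        text = _phrase_pattern(phrase).sub(" ", text)
    kept: list[str] = []
    for sent in segment_sentences(text):
        sent = sent.lstrip(" \t,;:-")
        sent = re.sub(r"\s+", " ", sent)
        sent = re.sub(r"\s+([.,!?;:])", r"\1", sent)
        if len(_tokenize(sent)) >= config.min_content_tokens:
            kept.append(sent)
    return " ".join(kept)


def prepare_lineage(
    lineage: RetellingLineage, config: CleaningConfig | None = None
) -> RetellingLineage:
    """Clean and segment every story of a lineage, ready for analysis.

    Stories that come out empty (no sentence survives cleaning) are rejected
    with a :class:`DataError` rather than silently admitted, since every
    similarity operation requires at least one sentence.
    """
    out: list[Story] = []
    for story in lineage.stories:
        cleaned = clean_text(story.raw_text, config)
        sentences = segment_sentences(cleaned)
        if not sentences:
            raise DataError(
                f"story {story.story_id!r} has no sentences after cleaning"
            )
        out.append(replace(story, sentences=sentences))
    return RetellingLineage(lineage.participant_id, lineage.condition, out)


_MANIFEST_COLUMNS = ("participant_id", "condition", "day", "path")


def load_manifest(manifest_path: str | Path) -> list[RetellingLineage]:
    """Read a manifest CSV and return lineages grouped by (participant, condition).

    The manifest needs columns ``participant_id,condition,day,path``; relative
    paths resolve against the manifest's own directory. Stories come back with
    ``raw_text`` populated and ``sentences`` empty — call
    :func:`prepare_lineage` (or the CLI) to clean and segment them.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype={"participant_id": str, "condition": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(
            f"manifest {manifest_path} is missing column(s): {', '.join(missing)}"
        )
    dupes = table[table.duplicated(["participant_id", "condition", "day"], keep=False)]
    if not dupes.empty:
        keys = sorted(
            set(zip(dupes.participant_id, dupes.condition, dupes.day.astype(int)))
        )
        raise DataError(f"duplicate (participant, condition, day) rows: {keys}")

    lineages: list[RetellingLineage] = []
    for (pid, cond), group in table.groupby(["participant_id", "condition"], sort=True):
        stories = []
        for row in group.sort_values("day").itertuples():
            path = Path(row.path)
            if not path.is_absolute():
                path = manifest_path.parent / path
            try:
                raw = path.read_text(encoding="utf-8")
            except OSError as exc:
                raise DataError(f"cannot read story file {path}: {exc}") from exc
            day = int(row.day)
            stories.append(
                Story(
                    story_id=f"{pid}-{cond}-d{day}",
                    participant_id=pid if day > 0 else pid,
                    condition=cond,
                    day=day,
                    raw_text=raw,
                )
            )
        lineages.append(RetellingLineage(str(pid), str(cond), stories))
    return lineages


def write_matrix(
    matrix: np.ndarray | Sequence[Sequence[float]],
    ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a square score matrix as CSV with ``ids`` as header row/column."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ContractError(f"matrix must be square, got shape {arr.shape}")
    if arr.shape[0] != len(ids):
        raise ContractError(
            f"{len(ids)} ids for a {arr.shape[0]}x{arr.shape[1]} matrix"
        )
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(arr, index=list(ids), columns=list(ids)).to_csv(
        path, float_format="%.17g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`write_matrix`; round-trips bit-exactly."""
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return table.to_numpy(dtype=float), [str(c) for c in table.columns]
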