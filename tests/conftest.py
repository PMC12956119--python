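from __future__ import annotations

import numpy as np
import pytest

from retell import LexicalBackend, Story


@pytest.fixture(scope="session")
def lexical():
    return LexicalBackend()


def make_story(sentences, story_id="s", condition="c", day=0, participant=None):
    return Story(
        story_id=story_id,
        participant_id=participant,
        condition=condition,
        day=day,
        raw_text=" ".join(sentences),
        sentences=list(sentences),
    )


@pytest.fixture
def toy_pair():
    """The worked 3-vs-2-sentence example with hand-derivable scores."""
    a = make_story(
        ["the cat sat.", "the dog ran.", "birds sing loudly."], story_id="A"
    )
    b = make_story(["the cat sat.", "birds sing loudly."], story_id="B")
    return a, b


_POOL = [
    "cat", "dog", "bird", "ran", "sat", "sang", "home", "park",
]


def random_story(rng: np.random.Generator, max_sentences: int = 6, story_id="r"):
    """Short stories over a small shared vocabulary, rich in ties and overlap."""
    n = int(rng.integers(1, max_sentences + 1))
    sentences = []
    for _ in range(n):
        k = int(rng.integers(2, 5))
        words = rng.choice(_POOL, size=k, replace=False)
        sentences.append(" ".join(words) + ".")
    return make_story(sentences, story_id=story_id)
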