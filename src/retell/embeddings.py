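"""Sentence-pair similarity backends.

Every matching algorithm in the package consumes a single contract: a
:class:`SimilarityBackend` maps a pair of sentences to a finite score in
[-1, 1] that is symmetric, with self-similarity 1 for any sentence with at
least one in-vocabulary token.

Two backends are provided. The *lexical* backend (Jaccard index over token
sets) is fully deterministic and dependency-free, which makes every test and
simulation exactly reproducible. The *vector* backend averages word vectors
per sentence and takes the cosine — the standard distributional-semantics
sentence score — and accepts any word2vec-format text table, so paraphrase
sensitivity depends entirely on the vectors supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ContractError

__all__ = [
    "SimilarityBackend",
    "LexicalBackend",
    "VectorBackend",
    "WordVectorTable",
    "load_word_vectors",
    "lexical_similarity",
    "vector_similarity",
    "pairwise_matrix",
    "get_backend",
]

_TOKEN_RE = re.compile(r"[^\W\d_]+")


def tokenize(sentence: str) -> list[str]:
    """Lowercased alphabetic tokens; punctuation and digits are stripped."""
    return _TOKEN_RE.findall(sentence.lower())


class SimilarityBackend:
    """Contract: symmetric sentence-pair similarity in [-1, 1]."""

    name: str = "abstract"

    def sim(self, s1: str, s2: str) -> float:
        raise NotImplementedError

    def __call__(self, s1: str, s2: str) -> float:
        return self.sim(s1, s2)


@lru_cache(maxsize=1 << 16)
def _token_set(sentence: str) -> frozenset[str]:
    return frozenset(tokenize(sentence))


def lexical_similarity(s1: str, s2: str) -> float:
    """Jaccard index of the two sentences' token sets, in [0, 1].

    Equal non-empty sets score 1, disjoint sets 0, and an empty set on either
    side scores 0 (a sentence with no alphabetic content carries no evidence).
    """
    a, b = _token_set(s1), _token_set(s2)
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


class LexicalBackend(SimilarityBackend):
    """Deterministic token-overlap backend (Jaccard index)."""

    name = "lexical"

    def sim(self, s1: str, s2: str) -> float:
        return lexical_similarity(s1, s2)


@dataclass
class WordVectorTable:
    """Lowercase token -> vector mapping with a fixed dimension."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ConfigurationError("word-vector table is empty")
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ConfigurationError(
                    f"vector for {tok!r} has shape {vec.shape}, expected ({self.dim},)"
                )

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Load a word2vec-format text table: one ``token v1 .. vd`` per line.

    A leading ``count dim`` header line (two integers) is auto-detected and
    skipped. Tokens are lowercased; on duplicates the first entry wins.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 0 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            token = parts[0].lower()
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=float)
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}: malformed vector on line {lineno + 1}"
                ) from exc
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ConfigurationError(
                    f"{path}: line {lineno + 1} has {vec.size} components, expected {dim}"
                )
            vectors.setdefault(token, vec)
    if dim is None:
        raise ConfigurationError(f"{path}: no vectors found")
    return WordVectorTable(vectors, dim)


def vector_similarity(s1: str, s2: str, table: WordVectorTable) -> float:
    """Cosine of the mean in-vocabulary word vectors of each sentence.

    Falls back to 0 when either sentence has no in-vocabulary token (no
    evidence either way); the result is clipped to [-1, 1] against rounding.
    """
    if not isinstance(table, WordVectorTable):
        raise ConfigurationError("vector_similarity requires a WordVectorTable")
    means = []
    for sent in (s1, s2):
        vecs = [table.vectors[t] for t in tokenize(sent) if t in table]
        if not vecs:
            return 0.0
        means.append(np.mean(vecs, axis=0))
    n1, n2 = np.linalg.norm(means[0]), np.linalg.norm(means[1])
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.clip(np.dot(means[0], means[1]) / (n1 * n2), -1.0, 1.0))


class VectorBackend(SimilarityBackend):
    """Average-word-vector cosine backend over a loaded vector table."""

    name = "vectors"

    def __init__(self, table: WordVectorTable):
        self.table = table

    def sim(self, s1: str, s2: str) -> float:
        return vector_similarity(s1, s2, self.table)


def pairwise_matrix(
    backend: SimilarityBackend,
    sents_a: list[str],
    sents_b: list[str],
) -> np.ndarray:
    """|A| x |B| matrix with entry (i, j) = backend.sim(A_i, B_j)."""
    if not sents_a or not sents_b:
        raise ContractError("pairwise_matrix requires non-empty sentence lists")
    out = np.empty((len(sents_a), len(sents_b)))
    for i, sa in enumerate(sents_a):
        for j, sb in enumerate(sents_b):
            out[i, j] = backend.sim(sa, sb)
    return out


def get_backend(name: str, vectors: str | Path | None = None) -> SimilarityBackend:
    """Construct a backend by name: ``lexical`` or ``vectors`` (needs a table path)."""
    if name == "lexical":
        return LexicalBackend()
    if name == "vectors":
        if vectors is None:
            raise ConfigurationError("the 'vectors' backend requires a vector table path")
        return VectorBackend(load_word_vectors(vectors))
    raise ConfigurationError(f"unknown backend {name!r}")
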