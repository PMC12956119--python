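"""Naive reference implementations used only to cross-check the package.

Everything here is written as directly as possible from the definitions —
explicit double loops, hand-rolled average ranks, textbook Pearson — and
deliberately shares no code with ``retell``.
"""

from __future__ import annotations

import math


def oracle_tokens(sentence: str) -> frozenset[str]:
    out = []
    for raw in sentence.lower().split():
        word = "".join(ch for ch in raw if ch.isalpha())
        if word:
            out.append(word)
    return frozenset(out)


def oracle_jaccard(s1: str, s2: str) -> float:
    a, b = oracle_tokens(s1), oracle_tokens(s2)
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def oracle_thresholds(sentences: list[str]) -> list[float]:
    thetas = []
    for i, si in enumerate(sentences):
        best = 0.0
        for j, sj in enumerate(sentences):
            if i != j:
                best = max(best, oracle_jaccard(si, sj))
        thetas.append(best if len(sentences) > 1 else 0.0)
    return thetas


def oracle_best_matches(ref: list[str], target: list[str]) -> tuple[list[int], list[float]]:
    """Lowest-index best match for every reference sentence."""
    indices, sims = [], []
    for s in ref:
        best_j, best_v = 0, -math.inf
        for j, t in enumerate(target):
            v = oracle_jaccard(s, t)
            if v > best_v:  # strict: ties keep the earlier index
                best_j, best_v = j, v
        indices.append(best_j)
        sims.append(best_v)
    return indices, sims


def oracle_remembered(ref: list[str], target: list[str]) -> list[bool]:
    thetas = oracle_thresholds(ref)
    _, sims = oracle_best_matches(ref, target)
    return [sim > theta for sim, theta in zip(sims, thetas)]


def oracle_average_ranks(values: list[float]) -> list[float]:
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(smaller + (equal + 1) / 2.0)
    return ranks


def oracle_pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def oracle_spearman(x: list[float], y: list[float]) -> float:
    return oracle_pearson(oracle_average_ranks(x), oracle_average_ranks(y))


def oracle_directional_sequence(ref: list[str], target: list[str]) -> float:
    indices, _ = oracle_best_matches(ref, target)
    matched = [j + 1 for j in indices]
    if len(ref) < 2 or len(set(matched)) == 1:
        return 0.0
    rho = oracle_spearman(list(range(1, len(ref) + 1)), matched)
    return 0.0 if math.isnan(rho) else rho


def oracle_story_similarity(a: list[str], b: list[str]) -> dict[str, float]:
    content_ab = sum(oracle_remembered(a, b)) / len(a)
    content_ba = sum(oracle_remembered(b, a)) / len(b)
    content = (content_ab + content_ba) / 2.0
    seq_ab = oracle_directional_sequence(a, b)
    seq_ba = oracle_directional_sequence(b, a)
    sequence = (seq_ab + seq_ba) / 2.0
    return {
        "content_ab": content_ab,
        "content_ba": content_ba,
        "content": content,
        "sequence_ab": seq_ab,
        "sequence_ba": seq_ba,
        "sequence": sequence,
        "combined": content * sequence,
    }


def oracle_sdd(points: list[tuple[float, float]]) -> float:
    n = len(points)
    mx = sum(p[0] for p in points) / n
    my = sum(p[1] for p in points) / n
    return math.sqrt(sum((x - mx) ** 2 + (y - my) ** 2 for x, y in points) / n)
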