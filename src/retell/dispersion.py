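"""Cross-participant convergence: similarity -> distance -> MDS -> SDD.

To ask whether different people converge on the same story, all stories are
compared pairwise, the combined similarities are converted to distances, the
stories are embedded in a shared 2-D space by multidimensional scaling, and
each condition's spread is summarized by the Standard Distance Deviation —
the root-mean-square distance of its points from their centroid:

    SDD = sqrt( sum_i[(x_i - mean x)^2 + (y_i - mean y)^2] / N )

Lower SDD means tighter clustering, i.e. greater mnemonic convergence across
participants. A label-shuffle permutation test decides whether two
conditions' SDDs differ more than chance relabeling would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import MDS

from .corpus_io import Story
from .embeddings import SimilarityBackend
from .errors import ContractError
from .embeddings import pairwise_matrix
from .similarity import _scores_from_cross, story_similarity, within_story_thresholds

__all__ = [
    "DispersionResult",
    "all_pairs_matrix",
    "similarity_to_distance",
    "embed_2d",
    "kruskal_stress",
    "standard_distance_deviation",
    "dispersion_permutation_test",
]


def all_pairs_matrix(
    stories: list[Story],
    backend: SimilarityBackend,
    threshold_mode: str = "per_sentence",
) -> np.ndarray:
    """Symmetric combined-similarity matrix over all story pairs.

    Each pair is computed once (the measure is symmetric by construction);
    the diagonal is each story's self-similarity, 1 whenever a story's
    sentences are pairwise distinct under the backend.
    """
    n = len(stories)
    if n < 2:
        raise ContractError("all_pairs_matrix requires >= 2 stories")
    # thresholds are a per-story quantity; compute them once, not per pair
    thetas = [
        within_story_thresholds(s.sentences, backend, threshold_mode) for s in stories
    ]
    out = np.empty((n, n))
    for i in range(n):
        out[i, i] = story_similarity(stories[i], stories[i], backend, threshold_mode).combined
        for j in range(i + 1, n):
            cross = pairwise_matrix(backend, stories[i].sentences, stories[j].sentences)
            _, _, content, _, _, sequence = _scores_from_cross(cross, thetas[i], thetas[j])
            out[i, j] = out[j, i] = content * sequence
    return out


def similarity_to_distance(matrix: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Convert similarities to distances, ``d = 1 - s`` (or ``(1 - s)/2``).

    Similarities live in [-1, 1], so the default transform yields distances
    in [0, 2]; ``normalize=True`` rescales to [0, 1]. The diagonal is forced
    to 0. Asymmetry beyond 1e-9 is rejected.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ContractError(f"similarity matrix must be square, got {matrix.shape}")
    if not np.all(np.abs(matrix - matrix.T) <= 1e-9):
        raise ContractError("similarity matrix is asymmetric beyond 1e-9")
    dist = 1.0 - matrix
    if normalize:
        dist /= 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def embed_2d(
    distances: np.ndarray,
    method: str = "classical",
    seed: int | None = None,
) -> np.ndarray:
    """Embed a distance matrix in 2-D by multidimensional scaling.

    ``classical``: Torgerson double-centering plus the top-2 eigenpairs
    (negative eigenvalues truncated to 0) — fully deterministic, and exact
    for distances that are genuinely 2-D Euclidean. ``stress``: iterative
    metric MDS (SMACOF) with a fixed seed. Axis signs are normalized so the
    largest-magnitude coordinate on each axis is positive.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ContractError(f"distance matrix must be square, got {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ContractError("distance matrix contains non-finite entries")
    n = d.shape[0]
    if method == "classical":
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        eigvals, eigvecs = np.linalg.eigh(b)
        order = np.argsort(eigvals)[::-1][:2]
        lam = np.clip(eigvals[order], 0.0, None)
        coords = eigvecs[:, order] * np.sqrt(lam)
    elif method == "stress":
        mds = MDS(
            n_components=2,
            metric="precomputed",
            random_state=seed,
            n_init=4,
            init="random",
            normalized_stress=False,
        )
        coords = mds.fit_transform(d)
    else:
        raise ContractError(f"unknown MDS method {method!r}")
    # deterministic axis orientation
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def kruskal_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against the input distances."""
    d = np.asarray(distances, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    emb = np.sqrt((diff**2).sum(axis=-1))
    denom = (d**2).sum()
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((d - emb) ** 2).sum() / denom))


def standard_distance_deviation(points: np.ndarray) -> float:
    """Root-mean-square distance of 2-D points from their centroid.

    Zero iff all points coincide; invariant under translation and rotation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ContractError("standard_distance_deviation requires >= 1 point")
    pts = pts.reshape(len(pts), -1)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum() / len(pts)))


@dataclass
class DispersionResult:
    """SDD contrast between two conditions in a shared embedding."""

    story_ids: list[str]
    coordinates: np.ndarray
    conditions: tuple[str, str]
    sdd: dict[str, float]
    observed_difference: float  # SDD(cond1) - SDD(cond2)
    p_value: float
    n_perm: int
    seed: int | None = None
    labels: np.ndarray = field(repr=False, default=None)


def dispersion_permutation_test(
    points: np.ndarray,
    labels: list[str] | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    story_ids: list[str] | None = None,
) -> DispersionResult:
    """Test whether two conditions differ in SDD on fixed coordinates.

    Condition labels are shuffled over the points ``n_perm`` times; the
    two-sided add-one p-value counts permuted |ΔSDD| at least as large as
    the observed one. Deterministic given ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(pts):
        raise ContractError(f"{len(labels)} labels for {len(pts)} points")
    conditions = sorted(set(labels.tolist()))
    if len(conditions) != 2:
        raise ContractError(f"need exactly 2 conditions, got {conditions}")
    counts = {c: int((labels == c).sum()) for c in conditions}
    if min(counts.values()) < 2:
        raise ContractError(f"each condition needs >= 2 stories, got {counts}")

    c1, c2 = conditions
    sdd = {c: standard_distance_deviation(pts[labels == c]) for c in conditions}
    observed = sdd[c1] - sdd[c2]

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        delta = standard_distance_deviation(pts[perm == c1]) - standard_distance_deviation(
            pts[perm == c2]
        )
        if abs(delta) >= abs(observed):
            count += 1
    return DispersionResult(
        story_ids=story_ids or [str(i) for i in range(len(pts))],
        coordinates=pts,
        conditions=(c1, c2),
        sdd=sdd,
        observed_difference=float(observed),
        p_value=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        labels=labels,
    )
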