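"""Local Subspace Affinity (LSA) segmentation of mixed sequence stacks.

Each sequence is one point in R^M.  The pipeline: (1) project points
onto the top right-singular directions of the stack and normalize onto
the unit sphere; (2) fit a local d-dimensional basis around every point
from its angular nearest neighbors; (3) build a pairwise affinity
exp(-sum sin^2 theta) from the principal angles between local bases;
(4) spectrally cluster the affinity into K groups.  Points whose local
neighborhoods lie in the same underlying subspace receive near-unit
affinity, so the spectral step recovers the subspace membership.

All stages draw from seed streams spawned off one master seed, and the
k-means stage operates in a canonical data order, so results are
reproducible and equivariant under permutations of the input rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .seqio import EncodedMatrix

__all__ = ["LsaConfig", "ClusterAssignment", "lsa_affinity", "lsa_segment"]


@dataclass
class LsaConfig:
    """Tunables of the LSA pipeline.

    ``d`` is the assumed dimension of each cluster subspace (default 7);
    ``projection_rank`` the global SVD projection dimension, "auto" =
    min(K*d, N-1, M); ``n_neighbors`` counts the points (self included)
    used to fit each local basis, default d + 2 and never below d + 1.
    """

    K: int
    d: int = 7
    projection_rank: int | str = "auto"
    n_neighbors: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("local dimension d must be >= 1")
        if self.K < 1:
            raise ValueError("number of clusters K must be >= 1")
        if self.n_neighbors is None:
            self.n_neighbors = self.d + 2
        if self.n_neighbors < self.d + 1:
            raise ValueError("n_neighbors must be at least d + 1")


@dataclass
class ClusterAssignment:
    """Labels in [1, K] plus the symmetric LSA affinity matrix."""

    labels: np.ndarray
    affinity: np.ndarray


def _data_matrix(W: EncodedMatrix | np.ndarray) -> np.ndarray:
    vals = W.values if isinstance(W, EncodedMatrix) else np.asarray(W, dtype=float)
    if vals.ndim != 2 or vals.size == 0:
        raise ValueError("expected a non-empty 2-d matrix")
    return vals


def _validate(vals: np.ndarray, config: LsaConfig) -> None:
    N = vals.shape[0]
    if config.K > N:
        raise ValueError(f"K={config.K} exceeds the number of points N={N}")
    if config.n_neighbors >= N:
        raise ValueError(
            f"n_neighbors={config.n_neighbors} must be smaller than N={N}"
        )
    if np.all(vals == vals[0]):
        raise ValueError("all rows are identical; no subspace structure to segment")


def _local_bases(vals: np.ndarray, config: LsaConfig) -> tuple[np.ndarray, list]:
    """Stages 1-2: sphere projection and per-point local bases."""
    N, M = vals.shape
    rank = config.projection_rank
    if rank == "auto":
        rank = min(config.K * config.d, N - 1, M)
    if not 1 <= rank <= min(N, M):
        raise ValueError(f"projection_rank {rank} outside [1, {min(N, M)}]")
    _, _, vt = np.linalg.svd(vals, full_matrices=False)
    X = vals @ vt[:rank].T
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms < 1e-12).any():
        raise ValueError("degenerate point with zero projection norm")
    X = X / norms
    # canonical column signs make the projected coordinates independent of
    # the input row order (SVD fixes right-singular vectors only up to sign)
    for c in range(X.shape[1]):
        pivot = np.argmax(np.abs(X[:, c]))
        if X[pivot, c] < 0:
            X[:, c] = -X[:, c]
    # order-invariant tie-break rank: lexicographic position of each point
    point_rank = np.empty(N, dtype=int)
    point_rank[np.lexsort(X.T[::-1])] = np.arange(N)
    # projective angular distance: x and -x span the same line, so the
    # cosine enters by magnitude.  Self is always nearest; exact ties
    # (e.g. orthogonal points at 90 degrees) break by canonical rank
    angles = np.arccos(np.clip(np.abs(X @ X.T), 0.0, 1.0))
    d_local = min(config.d, rank)
    bases = []
    for i in range(N):
        order = np.lexsort((point_rank, np.round(angles[i], 6)))
        neighborhood = order[: config.n_neighbors]
        neighborhood = neighborhood[np.argsort(point_rank[neighborhood])]
        _, _, local_vt = np.linalg.svd(X[neighborhood], full_matrices=False)
        bases.append(local_vt[:d_local])
    return X, bases


def lsa_affinity(
    W: EncodedMatrix | np.ndarray, config: LsaConfig
) -> np.ndarray:
    """Symmetric LSA affinity: exp(-sum_m sin^2 theta_m) per point pair.

    The theta_m are the principal angles between the two local bases;
    entries lie in (0, 1] with a unit diagonal.
    """
    vals = _data_matrix(W)
    _validate(vals, config)
    _, bases = _local_bases(vals, config)
    N = len(bases)
    A = np.ones((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            cosines = np.clip(
                np.linalg.svd(bases[i] @ bases[j].T, compute_uv=False), 0.0, 1.0
            )
            A[i, j] = A[j, i] = np.exp(-np.sum(1.0 - cosines**2))
    return A


def _spectral_embed(A: np.ndarray, K: int) -> np.ndarray:
    """Top-K eigenvectors of the symmetric-normalized affinity, rows on
    the unit sphere, with a canonical sign per eigenvector."""
    degree = A.sum(axis=1)
    A_norm = A / np.sqrt(np.outer(degree, degree))
    _, vectors = np.linalg.eigh(A_norm)
    emb = vectors[:, -K:]
    # canonical sign: largest-magnitude entry of each eigenvector positive
    for c in range(emb.shape[1]):
        pivot = np.argmax(np.abs(emb[:, c]))
        if emb[pivot, c] < 0:
            emb[:, c] = -emb[:, c]
    norms = np.maximum(np.linalg.norm(emb, axis=1, keepdims=True), 1e-12)
    return emb / norms


def _canonical_kmeans(emb: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Seeded k-means run in lexicographic data order.

    Sorting the points first makes the restart trajectory independent of
    the input row order, and numbering the centers lexicographically
    makes the label ids order-independent too, so permuting the input
    permutes the output labels identically.
    """
    order = np.lexsort(emb.T[::-1])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(emb[order])
    centers = km.cluster_centers_
    center_rank = np.empty(K, dtype=int)
    center_rank[np.lexsort(centers.T[::-1])] = np.arange(K)
    labels = np.empty(len(emb), dtype=int)
    labels[order] = center_rank[km.labels_]
    return labels + 1


def lsa_segment(
    W: EncodedMatrix | np.ndarray, config: LsaConfig
) -> ClusterAssignment:
    """Assign each row of W to one of K subspaces.

    Deterministic given ``config.seed``; labels are meaningful only up
    to cluster relabeling and should be scored with
    :func:`orthospace.stats.missrate`.
    """
    vals = _data_matrix(W)
    _validate(vals, config)
    A = lsa_affinity(vals, config)
    if config.K == 1:
        return ClusterAssignment(np.ones(vals.shape[0], dtype=int), A)
    emb = _spectral_embed(A, config.K)
    kmeans_seed = int(
        np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)
    )
    labels = _canonical_kmeans(emb, config.K, kmeans_seed)
    return ClusterAssignment(labels, A)
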