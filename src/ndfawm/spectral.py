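"""nDFA: normalized spectral clustering for weighted adjacency matrices.

The algorithm takes the top-k eigendecomposition of the (possibly
indefinite) symmetric adjacency matrix A, row-normalizes the n x k
eigenvector matrix, and runs k-means on the normalized rows.  Row
normalization cancels the per-node heterogeneity factor theta, which is
why nDFA recovers planted communities exactly on noiseless DCDFM
expectation matrices.

"Top-k" here means the k eigenpairs of largest *absolute* eigenvalue:
signed, Normal and Laplace networks make A indefinite, and the best
rank-k approximation of a symmetric matrix in spectral norm keeps the
largest-magnitude eigenvalues, negative ones included.  Ordering by
algebraic value instead is available via ``order="algebraic"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .samplers import as_adjacency

__all__ = ["Partition", "SpectralEmbedding", "top_k_eigendecomposition",
           "row_normalize", "ndfa"]

#: eigenvalues closer than this (relative) are treated as tied in magnitude
_EIG_TIE_TOL = 1e-12


@dataclass
class Partition:
    """A hard clustering into k communities, labels in {1..k}.

    ``k`` is the requested cluster count; ``k_effective`` counts the
    labels actually populated (k-means can return fewer distinct
    clusters when the embedding has fewer distinct rows than k).
    """

    labels: np.ndarray
    k: int
    k_effective: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


@dataclass
class SpectralEmbedding:
    """Top-k eigenpairs of A plus the row-normalized embedding."""

    U_hat: np.ndarray           # n x k, orthonormal columns
    Lambda_hat: np.ndarray      # k eigenvalues, sorted by decreasing |lambda|
    U_star: np.ndarray          # row-normalized U_hat
    zero_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def _eig_order(values: np.ndarray, order: str) -> np.ndarray:
    """Sort eigenvalue indices: magnitude (default) or algebraic, descending.

    Magnitude ties within relative 1e-12 fall back to algebraic value
    descending, so (+lam, -lam) pairs come out in a fixed order.
    """
    if order == "algebraic":
        return np.argsort(-values, kind="stable")
    mag = np.abs(values)
    scale = mag.max() if mag.size and mag.max() > 0 else 1.0
    quantized = np.round(mag / (scale * _EIG_TIE_TOL))
    return np.lexsort((-values, -quantized))


def full_eigendecomposition(A, order: str = "magnitude"):
    """All eigenpairs of symmetric A, sorted per ``order``.

    Used by the modularity curve to slice top-k embeddings for every
    candidate k from a single O(n^3) decomposition.
    """
    A = as_adjacency(A)
    values, vectors = scipy.linalg.eigh(A)
    idx = _eig_order(values, order)
    return values[idx], vectors[:, idx]


def top_k_eigendecomposition(A, k: int, order: str = "magnitude") -> SpectralEmbedding:
    """The k leading eigenpairs of A (by |eigenvalue|, descending)."""
    A = as_adjacency(A)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n = {n}, got k = {k}")
    values, vectors = full_eigendecomposition(A, order=order)
    U = vectors[:, :k]
    lam = values[:k]
    U_star, zero_rows = row_normalize(U)
    return SpectralEmbedding(U_hat=U, Lambda_hat=lam, U_star=U_star, zero_rows=zero_rows)


def row_normalize(U: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row of U by its Euclidean norm.

    Rows with norm <= tol are returned unchanged (still zero) and their
    indices reported, rather than dropped: downstream k-means then places
    all such nodes at the origin deterministically.
    """
    U = np.asarray(U, dtype=np.float64)
    norms = np.linalg.norm(U, axis=1)
    zero_rows = np.flatnonzero(norms <= tol)
    safe = np.where(norms > tol, norms, 1.0)
    return U / safe[:, None], zero_rows


def _relabel_consecutive(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary integer labels onto {1..k_eff}, first-seen order."""
    uniq, inv = np.unique(raw, return_inverse=True)
    first_pos = np.array([np.argmax(raw == u) for u in uniq])
    rank = np.empty(uniq.size, dtype=np.int64)
    rank[np.argsort(first_pos)] = np.arange(1, uniq.size + 1)
    return rank[inv], uniq.size


def ndfa(
    A,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    *,
    order: str = "magnitude",
    embedding: SpectralEmbedding | None = None,
) -> Partition:
    """Cluster the nodes of A into k communities with nDFA.

    k-means runs ``restarts`` seeded initializations on the normalized
    embedding and keeps the best-inertia solution, so the output is
    deterministic given (A, k, restarts, seed).  ``k = 1`` returns
    all-ones labels without touching the spectrum.  A precomputed
    ``embedding`` (with >= k columns) skips the eigendecomposition.
    """
    A = as_adjacency(A)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n = {n}, got k = {k}")
    if k == 1:
        return Partition(labels=np.ones(n, dtype=np.int64), k=1, k_effective=1)

    if embedding is not None and embedding.U_hat.shape[1] >= k:
        if embedding.U_hat.shape[1] == k:
            X = embedding.U_star
        else:
            X, _ = row_normalize(embedding.U_hat[:, :k])
    else:
        X = top_k_eigendecomposition(A, k, order=order).U_star

    with warnings.catch_warnings():
        # duplicate embedding rows (noiseless networks) trip a harmless
        # "fewer distinct clusters" warning inside sklearn
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        raw = km.fit_predict(X)
    labels, k_eff = _relabel_consecutive(raw)
    return Partition(labels=labels, k=k, k_effective=k_eff)
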