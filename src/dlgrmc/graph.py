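"""Graph Laplacians over the drug and target similarity networks.

The completion model penalizes the score matrix X through the quadratic
forms tr(XᵀL_d X) and tr(X L_t Xᵀ), where L_d = D_d − DS and
L_t = D_t − TS are unnormalized graph Laplacians of the drug–drug and
target–target similarity matrices (D is the diagonal degree matrix,
D_ii = Σ_j W_ij).  Self-similarity entries on the diagonal are retained:
they contribute to the degrees but cancel in the quadratic form.

By default the Laplacians are built on the dense similarity matrices.
Optional preprocessing — an RBF re-weighting of similarities and
k-nearest-neighbor sparsification — is available for experimenting with
sparser graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaplacianPair",
    "build_laplacian",
    "knn_sparsify",
    "rbf_reweight",
    "laplacian_pair",
    "laplacian_quadratic",
]

_TOL = 1e-10


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got {W.shape}")
    if np.max(np.abs(W - W.T), initial=0.0) > 1e-8:
        raise ValueError("weight matrix must be symmetric")
    if W.size and W.min() < 0:
        raise ValueError("weight matrix must be nonnegative")
    return W


@dataclass(frozen=True)
class LaplacianPair:
    """Drug and target Laplacians with their degree matrices.

    ``source`` records whether the weights were the dense similarity
    matrices or a kNN-sparsified version.
    """

    L_d: np.ndarray
    L_t: np.ndarray
    D_d: np.ndarray
    D_t: np.ndarray
    source: str = "dense_similarity"


def build_laplacian(W: np.ndarray) -> np.ndarray:
    """Unnormalized Laplacian L = D − W with D_ii = Σ_j W_ij.

    For any vector x, xᵀ L x = ½ Σ_ij W_ij (x_i − x_j)²; rows of L sum to
    zero and L is positive semidefinite for symmetric nonnegative W.
    """
    W = _check_weights(W)
    return np.diag(W.sum(axis=1)) - W


def knn_sparsify(W: np.ndarray, k: int) -> np.ndarray:
    """Keep W_ij iff j is among the k largest off-diagonal entries of row
    i, or i is among those of row j (symmetric union).  The diagonal is
    preserved.  Monotone in k: the kept edge set grows with k.
    """
    W = _check_weights(W)
    n = W.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    keep = np.zeros_like(W, dtype=bool)
    for i in range(n):
        top = np.argpartition(off[i], -k)[-k:]
        keep[i, top] = True
    keep |= keep.T
    out = np.where(keep, W, 0.0)
    np.fill_diagonal(out, np.diag(W))
    return out


def rbf_reweight(W: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian re-weighting W' = exp(−(1 − W)² / (2σ²)), unit diagonal.

    Treats 1 − W as a dissimilarity and maps it through an RBF kernel of
    width σ; applied before any kNN sparsification.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W = _check_weights(W)
    out = np.exp(-((1.0 - W) ** 2) / (2.0 * sigma**2))
    np.fill_diagonal(out, 1.0)
    return out


def laplacian_pair(
    DS: np.ndarray,
    TS: np.ndarray,
    knn_k: int | None = None,
    rbf_sigma: float | None = None,
) -> LaplacianPair:
    """Build the drug/target Laplacian pair, with optional preprocessing."""
    source = "dense_similarity"
    if rbf_sigma is not None:
        DS, TS = rbf_reweight(DS, rbf_sigma), rbf_reweight(TS, rbf_sigma)
    if knn_k is not None:
        DS, TS = knn_sparsify(DS, knn_k), knn_sparsify(TS, knn_k)
        source = "knn_sparsified"
    D_d = np.diag(np.asarray(DS, dtype=float).sum(axis=1))
    D_t = np.diag(np.asarray(TS, dtype=float).sum(axis=1))
    return LaplacianPair(build_laplacian(DS), build_laplacian(TS), D_d, D_t, source)


def laplacian_quadratic(L: np.ndarray, X: np.ndarray, side: str) -> float:
    """Smoothness penalty tr(Xᵀ L X) (side='rows') or tr(X L Xᵀ) (side='cols').

    The row form penalizes differences between rows of X across drug-graph
    edges; the column form penalizes differences between columns across
    target-graph edges.  Each equals half the weighted pairwise sum
    Σ_ij W_ij ‖x_i − x_j‖².
    """
    L = np.asarray(L, dtype=float)
    X = np.asarray(X, dtype=float)
    if side == "rows":
        if L.shape[1] != X.shape[0]:
            raise ValueError(f"shape mismatch: L {L.shape} vs X {X.shape}")
        return float(np.trace(X.T @ L @ X))
    if side == "cols":
        if L.shape[0] != X.shape[1]:
            raise ValueError(f"shape mismatch: X {X.shape} vs L {L.shape}")
        return float(np.trace(X @ L @ X.T))
    raise ValueError(f"side must be 'rows' or 'cols', got {side!r}")
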