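"""Generalized eigenvalue and singular value decompositions.

The decompositions here operate on a pair of data matrices ``A`` (m x N) and
``B`` (p x N) sharing their sample dimension N, or on the corresponding pair
of Gram/covariance matrices ``(A^T A, B^T B)``.  The GSVD is computed through
the inverse square root of ``B^T B``:

    A (B^T B)^{-1/2} = P diag(d) Q^T          (thin SVD)

from which generalized singular vectors and the generalized eigenvalues
``lambda_i = (sigma_A,i / sigma_B,i)^2`` follow.  The GEVD of a symmetric
pencil ``(S1, S2)`` with S2 positive definite is solved by the symmetric
reduction ``S2^{-1/2} S1 S2^{-1/2}``, which keeps eigenvalues real and
eigenvectors well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class GSVDResult:
    """Generalized SVD of a matrix pair (A, B) sharing the column dimension.

    Satisfies ``A = U @ diag(sigma_a) @ X.T`` and
    ``B = V @ diag(sigma_b) @ X.T`` with orthonormal-column U and V, and
    ``sigma_a**2 + sigma_b**2 = 1`` componentwise (cosine-sine normalization).
    """

    U: np.ndarray
    V: np.ndarray
    sigma_a: np.ndarray
    sigma_b: np.ndarray
    X: np.ndarray

    @property
    def generalized_eigenvalues(self) -> np.ndarray:
        """(sigma_a / sigma_b)**2 — eigenvalues of the pencil (A^T A, B^T B)."""
        return (self.sigma_a / self.sigma_b) ** 2


@dataclass
class GEVDResult:
    """Eigenpairs of the symmetric pencil S1 u = lambda S2 u."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns; generalized eigenvectors
    jitter_used: float = 0.0

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not np.all(np.isfinite(self.eigenvalues)):
            raise ValueError("non-finite generalized eigenvalues")


def _check_symmetric(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8 * (1.0 + np.abs(S).max())):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (S + S.T)


def inv_sqrt_psd(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Inverse square root of a symmetric PSD matrix via its eigendecomposition.

    Eigenvalues below ``tol * max(eigenvalue)`` are treated as exact zeros and
    inverted to zero (pseudo-inverse square root), so the result M satisfies
    ``M @ S @ M = I`` on the range of S.

    Raises
    ------
    ValueError
        If an eigenvalue is materially negative, i.e. below
        ``-tol * trace(S) / n``.
    """
    S = _check_symmetric(S, "S")
    n = S.shape[0]
    w, T = scipy.linalg.eigh(S)
    floor = -tol * max(np.trace(S), n * np.finfo(float).eps) / n
    if w.min() < floor:
        raise ValueError(
            f"matrix is not PSD: eigenvalue {w.min():.6e} below tolerance {floor:.6e}"
        )
    cut = tol * max(w.max(), 0.0)
    q = np.where(w > cut, 1.0 / np.sqrt(np.maximum(w, cut)), 0.0)
    M = (T * q) @ T.T
    return 0.5 * (M + M.T)


def gsvd(
    A: np.ndarray, B: np.ndarray, tol: float = 1e-10, allow_singular: bool = False
) -> GSVDResult:
    """Generalized SVD of (A, B) via the SVD of ``A @ (B^T B)^{-1/2}``.

    All N generalized singular pairs are retained.  When ``B^T B`` is
    invertible both reconstruction identities hold exactly; if it is rank
    deficient an error is raised unless ``allow_singular`` is set, in which
    case the pseudo-inverse square root is used and the identities hold only
    on the range of B.

    Factors are normalized so that ``sigma_a**2 + sigma_b**2 = 1``
    (cosine-sine form); pairs are sorted by ``sigma_a / sigma_b`` descending.
    When m < N the trailing N - m columns of U carry zero generalized singular
    values and are stored as zero vectors, so U^T U = I on the support of
    sigma_a.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"A and B must share columns: {A.shape} vs {B.shape}")
    m, N = A.shape
    StB = B.T @ B
    w = scipy.linalg.eigvalsh(StB)
    if w.min() <= tol * max(w.max(), 0.0) and not allow_singular:
        raise ValueError(
            "B^T B is numerically rank deficient; pass allow_singular=True for the "
            "pseudo-inverse construction (reconstructions then hold on range(B) only)"
        )
    M = inv_sqrt_psd(StB, tol=tol)  # (B^T B)^{-1/2}
    P, d, Qt = scipy.linalg.svd(A @ M, full_matrices=True)
    Q = Qt.T  # N x N orthogonal
    d_full = np.zeros(N)
    d_full[: d.shape[0]] = d

    # cosine-sine normalization: sigma_a = d/sqrt(1+d^2), sigma_b = 1/sqrt(1+d^2);
    # X column i scaled by sqrt(1+d_i^2) keeps both reconstructions exact.
    scale = np.sqrt(1.0 + d_full**2)
    sigma_a = d_full / scale
    sigma_b = 1.0 / scale
    w2, T = scipy.linalg.eigh(StB)
    S_half = (T * np.sqrt(np.maximum(w2, 0.0))) @ T.T  # (B^T B)^{1/2}
    X = (S_half @ Q) * scale  # N x N
    U = np.zeros((m, N))
    k = min(m, N)
    U[:, :k] = P[:, :k]
    V = B @ (M @ Q)  # p x N; orthonormal columns when B^T B invertible
    return GSVDResult(U=U, V=V, sigma_a=sigma_a, sigma_b=sigma_b, X=X)


def default_jitter(S2: np.ndarray) -> float:
    """Diagonal regularization scaled to the pencil: 1e-8 * trace(S2) / n."""
    S2 = np.asarray(S2, dtype=float)
    n = S2.shape[0]
    return 1e-8 * max(np.trace(S2), 0.0) / n


def gevd(S1: np.ndarray, S2: np.ndarray, jitter: float | None = None) -> GEVDResult:
    """Solve the symmetric-definite generalized eigenproblem S1 u = lambda S2 u.

    ``S2 + jitter*I`` must be positive definite; ``jitter=None`` applies the
    default ``1e-8 * trace(S2)/n``.  The problem is reduced to an ordinary
    symmetric eigenproblem on ``S2^{-1/2} S1 S2^{-1/2}``; eigenvalues are
    returned descending, and each eigenvector's largest-magnitude component is
    made positive to fix the sign.
    """
    S1 = _check_symmetric(S1, "S1")
    S2 = _check_symmetric(S2, "S2")
    if S1.shape != S2.shape:
        raise ValueError(f"shape mismatch: {S1.shape} vs {S2.shape}")
    if jitter is None:
        jitter = default_jitter(S2)
    n = S2.shape[0]
    S2j = S2 + jitter * np.eye(n)
    w2 = scipy.linalg.eigvalsh(S2j)
    if w2.min() <= 0:
        raise ValueError(
            f"S2 + jitter*I is not positive definite (min eigenvalue {w2.min():.3e}); "
            "increase jitter"
        )
    M = inv_sqrt_psd(S2j, tol=1e-14)
    C = M @ S1 @ M
    C = 0.5 * (C + C.T)
    w, W = scipy.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = w[order]
    U = M @ W[:, order]  # generalized eigenvectors: S1 u = lambda S2j u
    # deterministic sign: largest-|.| component of each eigenvector positive
    piv = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[piv, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    return GEVDResult(eigenvalues=w, eigenvectors=U, jitter_used=float(jitter))
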