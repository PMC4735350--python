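"""Shared dense/restricted symmetric eigensolver helpers and small utilities."""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

# Below this matrix size (or above this k/n ratio) a dense subset solver is
# both faster and exact; ARPACK pays off only on genuinely large covariances.
_DENSE_CUTOFF = 600
_DENSE_RATIO = 0.2


def topk_eigh(C: np.ndarray, k: int, tol: float = 1e-6, maxiter: int = 1000):
    """Top-k eigenpairs of a symmetric matrix, eigenvalues descending.

    Uses a restricted Lanczos/IRAM-style solver (``scipy.sparse.linalg.eigsh``)
    for large matrices and a dense LAPACK subset solver for small ones.
    """
    n = C.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n}x{n} matrix")
    if n <= _DENSE_CUTOFF or k >= n - 1 or k > _DENSE_RATIO * n:
        w, V = scipy.linalg.eigh(C, subset_by_index=[n - k, n - 1])
    else:
        w, V = scipy.sparse.linalg.eigsh(C, k=k, which="LA", tol=tol, maxiter=maxiter)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def full_eigh_desc(C: np.ndarray):
    """Full symmetric EVD with eigenvalues sorted descending."""
    w, V = scipy.linalg.eigh(C)
    return w[::-1], V[:, ::-1]


def fix_signs(B: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry of each column > 0."""
    if B.size == 0:
        return B
    idx = np.argmax(np.abs(B), axis=0)
    s = np.sign(B[idx, np.arange(B.shape[1])])
    s[s == 0] = 1.0
    return B * s


def column_signs(B: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(B), axis=0)
    s = np.sign(B[idx, np.arange(B.shape[1])])
    s[s == 0] = 1.0
    return s


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical angles (radians, descending) between the column spaces of A and B."""
    return scipy.linalg.subspace_angles(A, B)


def max_principal_angle(A: np.ndarray, B: np.ndarray) -> float:
    ang = principal_angles(A, B)
    return float(ang[0]) if ang.size else 0.0


def normalize_columns(B: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(B, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot normalize zero column")
    return B / norms


def drop_tiny(w: np.ndarray, rel: float = 1e-12, what: str = "matrix"):
    """Indices of eigenvalues to keep, dropping numerically null ones with a warning."""
    if w.size == 0:
        return np.array([], dtype=int)
    cut = rel * max(float(np.max(np.abs(w))), np.finfo(float).tiny)
    keep = np.flatnonzero(w > cut)
    if keep.size < w.size:
        warnings.warn(
            f"{what}: dropping {w.size - keep.size} numerically rank-deficient "
            "direction(s)",
            stacklevel=3,
        )
    return keep
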