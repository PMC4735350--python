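"""First-stage (subject-level) PCA.

Each subject's centered voxels x time matrix ``Z`` is reduced along time to its
top ``p`` principal component score vectors, optionally whitened to unit sample
variance. For long time series the t x t covariance can be accumulated in
voxel blocks so the full matrix never needs to be resident at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import fix_signs
from .provider import DataMatrix

__all__ = ["ReducedSubject", "subject_cov_blockwise", "reduce_subject"]

# above this many time points the covariance itself dominates memory and the
# small-dimension regime assumption breaks down
_SMALL_TIME_DIM = 10000


@dataclass
class ReducedSubject:
    """Top-p subject principal components.

    scores       v x p score (or whitened score) matrix Y_i
    eigenvalues  p descending eigenvalues of the t x t covariance
    basis        v x p orthonormal spatial basis (left singular vectors)
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    subject_id: str
    basis: np.ndarray
    whitened: bool = False


def subject_cov_blockwise(z: DataMatrix, voxel_block: int) -> np.ndarray:
    """t x t covariance Z^T Z/(v-1) accumulated over voxel blocks.

    The result is independent of the block size (summation is associative);
    blocks only bound how many voxels are resident at once.
    """
    if not z.centered:
        raise ValueError("subject matrix must be centered before covariance")
    if voxel_block < 1:
        raise ValueError("voxel_block must be >= 1")
    v, t = z.values.shape
    if t > _SMALL_TIME_DIM:
        warnings.warn(
            f"t={t} time points exceeds the small-dimension regime "
            f"(t < {_SMALL_TIME_DIM}); the t x t covariance will be large",
            stacklevel=2,
        )
    C = np.zeros((t, t))
    for start in range(0, v, voxel_block):
        blk = z.values[start : start + voxel_block]
        C += blk.T @ blk
    C /= v - 1
    return (C + C.T) / 2.0


def reduce_subject(z: DataMatrix, p: int, whiten: bool = True) -> ReducedSubject:
    """Reduce a centered subject matrix to its top-p principal components.

    With ``whiten=True`` each score column is rescaled to unit sample variance
    (``scores^T scores/(v-1) = I``); the orthonormal spatial basis is kept
    separately in either case.
    """
    if not z.centered:
        raise ValueError("subject matrix must be centered before PCA")
    v, t = z.values.shape
    if p > min(v, t):
        raise ValueError(f"p={p} exceeds min(v, t) = {min(v, t)}")
    U, s, _ = np.linalg.svd(z.values, full_matrices=False)
    if s[0] == 0:
        raise ValueError("zero-variance data")
    eigenvalues = s**2 / (v - 1)
    eigenvalues = np.where((eigenvalues < 0) & (eigenvalues > -1e-12), 0.0, eigenvalues)
    basis = fix_signs(U[:, :p])
    if whiten:
        scores = basis * np.sqrt(v - 1)
    else:
        scores = basis * s[:p]
    return ReducedSubject(
        scores=scores,
        eigenvalues=eigenvalues[:p],
        subject_id=z.subject_id,
        basis=basis,
        whitened=whiten,
    )
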