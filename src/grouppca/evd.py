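"""Exact group PCA by eigenvalue decomposition of the sample covariance.

The covariance of the concatenated data ``Y`` (v x Mp) can be formed in either
dimension:

* time path   — the Mp x Mp cross-covariance ``C`` with subject blocks
  ``C_ij = Y_i^T Y_j/(v-1)``, computable with only two subjects resident;
* voxel path  — the v x v covariance ``C^v = sum_i Y_i Y_i^T/(v-1)``,
  accumulated one subject at a time (exactly M dataloads) and sharing the
  nonzero spectrum of ``C``.

``evd_group_pca`` picks the smaller dimension automatically and is the
accuracy reference for every iterative solver in this package.
"""

from __future__ import annotations

import numpy as np

from ._linalg import column_signs, fix_signs, normalize_columns, topk_eigh
from .provider import GroupProvider
from .results import PCAResult, build_result

__all__ = ["cross_cov_time", "voxel_cov_sum", "evd_group_pca"]

DEFAULT_DIM_CAP = 20000


def cross_cov_time(provider: GroupProvider, cap: int = DEFAULT_DIM_CAP) -> np.ndarray:
    """Mp x Mp covariance C with blocks Y_i^T Y_j/(v-1).

    Holds at most two subjects in memory at a time in unstacked mode; the
    off-diagonal blocks take M(M-1)/2 pair computations.
    """
    Mp = provider.total_cols
    if Mp > cap:
        raise ValueError(
            f"Mp={Mp} exceeds the covariance dimension cap ({cap}); "
            "use an iterative solver (mpowit / large_pca) instead"
        )
    M, p, v = provider.M, provider.p, provider.v
    C = np.empty((Mp, Mp))
    for i in range(M):
        Yi = provider.get_subject(i)
        C[i * p : (i + 1) * p, i * p : (i + 1) * p] = Yi.T @ Yi / (v - 1)
        for j in range(i + 1, M):
            Yj = provider.get_subject(j)
            blk = Yi.T @ Yj / (v - 1)
            C[i * p : (i + 1) * p, j * p : (j + 1) * p] = blk
            C[j * p : (j + 1) * p, i * p : (i + 1) * p] = blk.T
    return (C + C.T) / 2.0


def voxel_cov_sum(provider: GroupProvider, cap: int = DEFAULT_DIM_CAP) -> np.ndarray:
    """v x v covariance C^v = sum_i Y_i Y_i^T/(v-1), one subject resident at a time."""
    v = provider.v
    if v > cap:
        raise ValueError(
            f"v={v} exceeds the covariance dimension cap ({cap}); "
            "use an iterative solver (mpowit / large_pca) instead"
        )
    C = np.zeros((v, v))
    for _, Yi in provider.iter_subjects():
        C += Yi @ Yi.T
    C /= v - 1
    return (C + C.T) / 2.0


def evd_group_pca(
    provider: GroupProvider,
    k: int,
    cap: int = DEFAULT_DIM_CAP,
    tol: float = 1e-6,
    maxiter: int = 1000,
) -> PCAResult:
    """Exact top-k group PCA via EVD of the covariance in its smallest dimension.

    Eigenvalue extraction uses a restricted symmetric eigensolver (dense subset
    solver for small covariances) with the stated tolerance and iteration cap.
    """
    v, Mp = provider.v, provider.total_cols
    if k < 1 or k > min(v, Mp):
        raise ValueError(f"k={k} exceeds min(v, Mp) = {min(v, Mp)}")
    if min(v, Mp) > cap:
        raise ValueError(
            f"both covariance dimensions (v={v}, Mp={Mp}) exceed the cap ({cap}); "
            "use mpowit or large_pca"
        )
    loads0 = provider.dataloads
    if Mp < v and Mp <= cap:
        C = cross_cov_time(provider, cap=cap)
        w, F = topk_eigh(C, k, tol=tol, maxiter=maxiter)
        if w[k - 1] <= 1e-12 * max(w[0], 1e-300):
            raise ValueError(f"k={k} exceeds the numerical rank of the data")
        # X = Y F ((v-1) Lambda)^(-1/2): unit-variance whitening convention
        basis = provider.project(F) / np.sqrt((v - 1) * w)
        signs = column_signs(basis)  # deterministic regardless of backend sign
        basis = basis * signs
        backproj = F * signs
        method = "evd"
    else:
        Cv = voxel_cov_sum(provider, cap=cap)
        w, chi = topk_eigh(Cv, k, tol=tol, maxiter=maxiter)
        if w[k - 1] <= 1e-12 * max(w[0], 1e-300):
            raise ValueError(f"k={k} exceeds the numerical rank of the data")
        basis = fix_signs(chi)
        backproj = normalize_columns(provider.adjoint(basis))
        method = "evd"
    res = build_result(
        basis,
        w,
        method,
        v,
        backproj=backproj,
        extra={"dataloads": provider.dataloads - loads0, "path": "time" if Mp < v else "voxel"},
    )
    return res
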