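"""Randomized block-Lanczos group PCA ("Large PCA") with a convergence check.

A block Krylov subspace ``Kr = [X_0, X_1, ..., X_j]`` is grown from a Gaussian
random start (or a warm-start basis), where ``X_j = Y (X_{j-1}^T Y)^T`` applies
one power of ``Y Y^T`` per block. Ritz singular values are extracted by an
economy QR of ``Kr``, the projection ``F = Y^T chi``, and an economy SVD of
``F``. Instead of fixing the block count in advance, the Krylov basis keeps
growing until the top-k singular values stabilize:

    || S_j - S_{j-1} || < tol     (absolute L2 over the top k)

With a random start the basis is grown to ``j0`` blocks before the first
check; with an STP/SVP warm start ``j0 = 1`` suffices. Per-block Frobenius
normalization guards against overflow from unnormalized covariance powers and
leaves span(Kr), chi, and all Ritz values unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._linalg import column_signs
from .provider import GroupProvider
from .results import ConvergenceTrace, PCAResult, build_result

__all__ = ["KrylovState", "extend_krylov", "ritz_values", "large_pca"]

DEFAULT_BLOCK = 170
DEFAULT_J0 = 6
WARM_J0 = 1


@dataclass
class KrylovState:
    """Blocks of the growing Krylov basis plus the singular-value history."""

    blocks: list = field(default_factory=list)
    b: int = DEFAULT_BLOCK
    singular_history: list = field(default_factory=list)

    @property
    def j(self) -> int:
        return len(self.blocks) - 1

    def krylov_matrix(self) -> np.ndarray:
        return np.hstack(self.blocks)


def _append_block(state: KrylovState, X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise FloatingPointError(
            "non-finite entries in Krylov block (covariance powers overflowed); "
            "rescale the data to a smaller magnitude"
        )
    nrm = np.linalg.norm(X)
    if nrm == 0:
        raise ValueError("zero Krylov block; data has no variance along the start")
    state.blocks.append(X / nrm)


def init_krylov(
    provider: GroupProvider,
    b: int = DEFAULT_BLOCK,
    seed: int | None = None,
    init: PCAResult | None = None,
) -> KrylovState:
    """X_0 = Y F_0 from a Gaussian F_0, or the warm-start basis directly."""
    if init is not None:
        comps = np.asarray(init.extra.get("all_components", init.basis))
        state = KrylovState(b=comps.shape[1])
        _append_block(state, comps.copy())
        return state
    rng = np.random.default_rng(seed)
    F0 = rng.standard_normal((provider.total_cols, b))
    state = KrylovState(b=b)
    _append_block(state, provider.project(F0))  # M dataloads
    return state


def extend_krylov(state: KrylovState, provider: GroupProvider) -> KrylovState:
    """Append X_j = Y (X_{j-1}^T Y)^T, accumulated one subject at a time."""
    if not state.blocks:
        raise ValueError("Krylov state not initialized")
    _append_block(state, provider.apply_cov(state.blocks[-1]))  # M dataloads
    return state


def ritz_values(state: KrylovState, provider: GroupProvider, k: int):
    """Top-k Ritz singular values of Y on span(Kr), plus finalization factors.

    Economy QR of Kr (rank-revealing; dependent columns dropped with a
    warning), projection F = Y^T chi, economy SVD of F. Returns
    ``(s_topk, chi, B, P)`` with ``F = P diag(s) B^T``; the group PCA basis is
    ``chi @ B`` and the back-projection eigenvectors are the columns of ``P``.
    """
    Kr = state.krylov_matrix()
    v = provider.v
    if Kr.shape[1] > v:
        raise ValueError("Krylov basis wider than the voxel dimension")
    Q, R, _ = scipy.linalg.qr(Kr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(diag[0], np.finfo(float).tiny) * 1e-12))
    if rank < Kr.shape[1]:
        warnings.warn(
            f"rank-deficient Krylov basis: keeping {rank} of {Kr.shape[1]} columns",
            stacklevel=2,
        )
    chi = Q[:, :rank]
    F = provider.adjoint(chi)  # M dataloads
    P, s, Bt = np.linalg.svd(F, full_matrices=False)
    kk = min(k, s.size)
    state.singular_history.append(s[:kk].copy())
    return s[:kk], chi, Bt.T, P


def large_pca(
    provider: GroupProvider,
    k: int,
    b: int = DEFAULT_BLOCK,
    j0: int | None = None,
    tol: float = 1e-6,
    max_j: int | None = None,
    init: PCAResult | None = None,
    seed: int | None = None,
    norm: str = "abs",
) -> PCAResult:
    """Convergence-checked randomized block-Lanczos group PCA.

    In un-stacked mode the dataload total matches the known accounting for
    this scheme, ``(2j - j0 + 2) M`` at stopping index ``j``: one pass per
    block built, plus one per singular-value check from ``j0`` onward.
    """
    v, Mp = provider.v, provider.total_cols
    if k < 1 or k > min(v, Mp):
        raise ValueError(f"k={k} exceeds min(v, Mp) = {min(v, Mp)}")
    if tol <= 0:
        raise ValueError("tol must be positive (use numpy.inf for a single check)")
    if j0 is None:
        j0 = WARM_J0 if init is not None else DEFAULT_J0
    if init is None and (j0 + 2) * b > v:
        b_new = max(k, v // (j0 + 2))
        warnings.warn(
            f"block length reduced from {b} to {b_new} so the initial Krylov "
            f"basis fits the voxel dimension (v={v})",
            stacklevel=2,
        )
        b = b_new
    loads0 = provider.dataloads

    state = init_krylov(provider, b=b, seed=seed, init=init)
    if max_j is None:
        max_j = max(v // state.b - 1, j0 + 1)
    while state.j < j0:
        extend_krylov(state, provider)

    trace = ConvergenceTrace()
    s_prev, chi, B, P = ritz_values(state, provider, k)
    trace.record(s_prev)

    converged = False
    while True:
        if (state.j + 2) * state.b > v:
            break
        extend_krylov(state, provider)
        s, chi, B, P = ritz_values(state, provider, k)
        diff = trace.record(s)
        if norm == "rel":
            diff = diff / max(np.linalg.norm(s), np.finfo(float).tiny)
        trace.iterations = state.j - j0
        if diff < tol:
            converged = True
            break
        if state.j >= max_j:
            break
        s_prev = s

    trace.converged = converged
    trace.extra["j_final"] = state.j
    trace.extra["j0"] = j0
    trace.extra["singular_history"] = state.singular_history
    if not converged:
        err = RuntimeError(
            f"Large PCA did not converge by j={state.j} "
            f"(last change {trace.diff_norms[-1]:.3e})"
        )
        err.trace = trace
        raise err

    kk = min(k, s.size)
    basis = chi @ B[:, :kk]
    signs = column_signs(basis)
    basis = basis * signs
    backproj = P[:, :kk] * signs
    eigenvalues = s[:kk] ** 2 / (v - 1)
    res = build_result(
        basis,
        eigenvalues,
        "large_pca",
        v,
        backproj=backproj,
        trace=trace,
        extra={
            "b": state.b,
            "j0": j0,
            "j_final": state.j,
            "dataloads": provider.dataloads - loads0,
        },
    )
    return res
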