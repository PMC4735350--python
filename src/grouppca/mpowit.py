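"""Multi power iteration (MPOWIT): subspace iteration on an enlarged block.

Subspace (orthogonal) iteration converges slowly for the trailing eigenvalues
of the block. MPOWIT runs the iteration on an enlarged ``l*k``-dimensional
subspace while monitoring convergence only on the top ``k`` eigenvalues: the
extra ``(l-1)k`` columns absorb the slowly-converging directions, so the
monitored set converges in a handful of iterations. Orthonormalization uses a
fast EVD-based factorization of the small Gram matrix instead of QR.

Each iteration touches every subject exactly once (M dataloads in un-stacked
mode), for a total of ``(j + 1) M`` over ``j`` iterations including the
initial covariance product. Classic single-vector power iteration is included
as a reference.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._linalg import (
    drop_tiny,
    fix_signs,
    full_eigh_desc,
    normalize_columns,
)
from .provider import GroupProvider
from .results import ConvergenceTrace, PCAResult, build_result

__all__ = ["orth_evd", "power_iteration", "mpowit"]

SUBSPACE_CAP = 500  # beyond l*k = 500 the small-EVD orth step stops being cheap


def orth_evd(m: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the column space of ``m`` via a small EVD.

    Factorizes ``m^T m = F D F^T`` and returns ``m F L^{-1}`` where ``L`` holds
    the column norms of ``m F``. Spans the same space as ``m``; numerically
    dependent columns are dropped with a warning.
    """
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    v, c = m.shape
    if c > v:
        raise ValueError("more columns than rows; cannot orthonormalize")
    G = m.T @ m
    w, F = full_eigh_desc((G + G.T) / 2.0)
    keep = drop_tiny(w, what="orth_evd Gram")
    if keep.size == 0:
        raise ValueError("zero matrix has no orthonormal basis")
    Xf = m @ F[:, keep]
    L = np.linalg.norm(Xf, axis=0)
    return Xf / L


def power_iteration(cov_apply, v: int, tol: float = 1e-6, max_iter: int = 1000, seed=None):
    """Classic power iteration for the dominant eigenpair of a symmetric PSD
    operator given as a matvec ``cov_apply``.

    Stops when the iterate's direction changes by less than ``tol`` (up to
    sign); the eigenvalue is the Rayleigh quotient at the final iterate.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(v)
    x /= np.linalg.norm(x)
    for _ in range(max_iter):
        y = cov_apply(x)
        ny = np.linalg.norm(y)
        if ny == 0:
            return x, 0.0
        y = y / ny
        change = min(np.linalg.norm(y - x), np.linalg.norm(y + x))
        x = y
        if change < tol:
            lam = float(x @ cov_apply(x))
            return x, lam
    err = RuntimeError(
        f"power iteration did not converge in {max_iter} iterations "
        "(spectral gap too small?)"
    )
    err.last_iterate = x
    raise err


def _warm_block(init: PCAResult, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``width`` components and eigenvalues from a warm-start result."""
    comps = init.extra.get("all_components", init.basis)
    eigs = init.extra.get("all_eigenvalues", init.eigenvalues)
    return np.asarray(comps)[:, :width], np.asarray(eigs)


def mpowit(
    provider: GroupProvider,
    k: int,
    l: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: PCAResult | None = None,
    init_matrix: np.ndarray | None = None,
    seed: int | None = None,
    norm: str = "abs",
    verbatim_scaling: bool = False,
    compute_backproj: bool = True,
    allow_large_subspace: bool = False,
    record_subspaces: bool = False,
) -> PCAResult:
    """Top-k group PCA by multi power iteration with an l*k projecting subspace.

    Initialization is a standard Gaussian random block (or the top ``l*k``
    components of a warm-start result such as STP/SVP, whose eigenvalues seed
    the convergence reference). Per iteration: EVD-based orthonormalization,
    one covariance product accumulated subject-by-subject, and a full EVD of
    the small ``(lk) x (lk)`` projected covariance, keeping the top ``k``
    eigenvalues. Stops when the L2 change of those eigenvalues drops below
    ``tol`` (``norm="rel"`` scales by the current eigenvalue norm).
    """
    v, Mp = provider.v, provider.total_cols
    if l < 1:
        raise ValueError("l must be a positive integer")
    if k < 1 or k > min(v, Mp):
        raise ValueError(f"k={k} exceeds min(v, Mp) = {min(v, Mp)}")
    lk = l * k
    if lk > SUBSPACE_CAP and not allow_large_subspace:
        raise ValueError(
            f"l*k = {lk} > {SUBSPACE_CAP}; pass allow_large_subspace=True to override"
        )
    if lk > min(v, Mp):
        lk = min(v, Mp)
        warnings.warn(
            f"l*k exceeds the data rank bound; projecting subspace reduced to {lk}",
            stacklevel=2,
        )

    trace = ConvergenceTrace()
    loads0 = provider.dataloads

    if init_matrix is not None:
        X0 = np.asarray(init_matrix, dtype=float)
        if X0.shape != (v, lk):
            raise ValueError(f"init_matrix must have shape ({v}, {lk})")
        lam_prev = np.zeros(k)
    elif init is not None:
        X0, warm_eigs = _warm_block(init, lk)
        if X0.shape[1] < lk:
            lk = X0.shape[1]
            warnings.warn(
                f"warm start provides only {lk} components; subspace reduced",
                stacklevel=2,
            )
            if lk < k:
                raise ValueError("warm start has fewer than k components")
        lam_prev = np.asarray(warm_eigs, dtype=float)[:k]
    else:
        rng = np.random.default_rng(seed)
        X0 = rng.standard_normal((v, lk))
        lam_prev = np.zeros(k)

    trace.record(lam_prev)
    chi = provider.apply_cov(X0)  # M dataloads
    init_loads = provider.dataloads - loads0

    converged = False
    X = W = lam_full = None
    subspaces = [] if record_subspaces else None
    for j in range(1, max_iter + 1):
        X = orth_evd(chi)
        if subspaces is not None:
            subspaces.append(X.copy())
        chi = provider.apply_cov(X)  # M dataloads per iteration
        S = X.T @ chi / (v - 1)
        lam_full, W = full_eigh_desc((S + S.T) / 2.0)
        lam = lam_full[:k]
        diff = trace.record(lam)
        if norm == "rel":
            diff = diff / max(np.linalg.norm(lam), np.finfo(float).tiny)
        trace.iterations = j
        if diff < tol:
            converged = True
            break
        lam_prev = lam

    trace.converged = converged
    iter_loads = provider.dataloads - loads0 - init_loads
    trace.extra["dataloads"] = {
        "init": init_loads,
        "iterations": iter_loads,
        "per_iteration": provider.M,
    }
    if subspaces is not None:
        trace.extra["subspaces"] = subspaces
    if not converged:
        err = RuntimeError(
            f"MPOWIT did not converge within {max_iter} iterations "
            f"(last eigenvalue change {trace.diff_norms[-1]:.3e})"
        )
        err.trace = trace
        raise err

    basis = fix_signs(X @ W[:, :k])
    res = build_result(
        basis,
        lam_full[:k],
        "mpowit",
        v,
        trace=trace,
        extra={
            "l": l,
            "lk": lk,
            "iterations": trace.iterations,
            "dataloads": provider.dataloads - loads0,
        },
    )
    if verbatim_scaling:
        # printed finalization X_j W_j Lambda_j^{-1/2}: column norms lambda^{-1/2}
        res.whitened = basis / np.sqrt(lam_full[:k])
    if compute_backproj:
        F = provider.adjoint(basis)  # M additional dataloads
        res.backproj = normalize_columns(F)
        res.extra["dataloads_total_with_backproj"] = provider.dataloads - loads0
    return res
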