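"""Fast approximate group PCA by subsampling: SVP (voxel lattice) and STP (time).

Both return a :class:`~grouppca.results.PCAResult` that can be used directly or
as a warm start for the convergence-checked iterative solvers (MPOWIT, Large
PCA), where it typically cuts the remaining iterations to two or three.

SVP (subsampled voxel PCA) exploits spatial smoothness: the all-odd and
all-even voxel sublattices each carry nearly the full covariance structure, so
an exact EVD in the (8x smaller, for depth 2 in 3-D) subsampled voxel space,
projected back to all voxels and merged, approximates the full decomposition
with at most two dataloads per subject.

STP (sub-sampled time PCA) streams subjects in groups of ``g``, computes an
exact PCA per group, and merges each group estimate into a running v x k'
subspace — a single pass over the data. Group blocks carry their variance
weights into the merge (no intermediate whitening). MIGP is the g = 1 special
case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import drop_tiny, fix_signs, full_eigh_desc, topk_eigh
from .provider import BrainMask, GroupProvider
from .results import PCAResult, attach_backproj, build_result

__all__ = ["SubsampleScheme", "build_scheme", "svp", "stp"]


@dataclass
class SubsampleScheme:
    """Disjoint all-odd / all-even voxel index sets into the masked ordering."""

    depth: int
    odd_index_set: np.ndarray
    even_index_set: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.odd_index_set, self.even_index_set).size:
            raise ValueError("subsample index sets must be disjoint")


def build_scheme(mask_or_v: BrainMask | int, depth: int = 2) -> SubsampleScheme:
    """All-odd / all-even lattice index sets (1-based parity) at the given depth.

    For spatial data, a masked voxel belongs to the odd set iff all three of
    its grid coordinates are odd under 1-based indexing (0-based: multiples of
    ``depth``), and to the even set iff all are even (0-based: ``depth - 1``
    mod ``depth``). For non-spatial fixture data (an integer row count),
    strided sets with offsets 0 and ``depth - 1`` are used.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth == 1:
        raise ValueError("no subsampling: depth 1 makes disjoint sets impossible")
    if isinstance(mask_or_v, BrainMask):
        coords = mask_or_v.coordinates()
        odd = np.flatnonzero(np.all(coords % depth == 0, axis=1))
        even = np.flatnonzero(np.all(coords % depth == depth - 1, axis=1))
    else:
        v = int(mask_or_v)
        idx = np.arange(v)
        odd = idx[idx % depth == 0]
        even = idx[idx % depth == depth - 1]
    if odd.size == 0 or even.size == 0:
        raise ValueError("subsample scheme produced an empty index set")
    return SubsampleScheme(depth=depth, odd_index_set=odd, even_index_set=even)


def svp(
    provider: GroupProvider,
    k: int,
    k_intermediate: int = 500,
    scheme: SubsampleScheme | None = None,
    depth: int = 2,
    compute_backproj: bool = False,
) -> PCAResult:
    """Subsampled voxel PCA.

    Pass 1 accumulates the odd- and even-lattice voxel covariances; an exact
    EVD in each subsampled space yields spatial eigenvectors, which pass 2
    converts to time-dimension eigenvector estimates and projects back onto
    the full-voxel data. A joint EVD over the two projected blocks merges them
    into the final top-k estimate. At most two dataloads per subject.
    """
    v, Mp = provider.v, provider.total_cols
    if scheme is None:
        scheme = build_scheme(v, depth=depth)
    if k > k_intermediate:
        raise ValueError("k must be <= k_intermediate")
    if k_intermediate > Mp:
        raise ValueError(f"k_intermediate={k_intermediate} exceeds Mp={Mp}")
    rows_a, rows_b = scheme.odd_index_set, scheme.even_index_set
    if k_intermediate > min(rows_a.size, rows_b.size):
        raise ValueError(
            "k_intermediate exceeds the subsampled voxel count "
            f"(min(v_a, v_b) = {min(rows_a.size, rows_b.size)})"
        )
    loads0 = provider.dataloads

    # pass 1: subsampled covariances (both lattices from the same dataload)
    Caa = np.zeros((rows_a.size, rows_a.size))
    Cbb = np.zeros((rows_b.size, rows_b.size))
    for _, Yi in provider.iter_subjects():
        Ya, Yb = Yi[rows_a], Yi[rows_b]
        Caa += Ya @ Ya.T
        Cbb += Yb @ Yb.T
    Caa /= v - 1
    Cbb /= v - 1

    wa, Xa_sub = topk_eigh((Caa + Caa.T) / 2.0, k_intermediate)
    wb, Xb_sub = topk_eigh((Cbb + Cbb.T) / 2.0, k_intermediate)
    ka = drop_tiny(wa, what="SVP odd-lattice covariance")
    kb = drop_tiny(wb, what="SVP even-lattice covariance")
    if ka.size < k or kb.size < k:
        raise ValueError("rank collapse in subsampled covariance (fewer than k directions)")
    Xa_sub, Xb_sub = Xa_sub[:, ka], Xb_sub[:, kb]

    # pass 2: F_a = Y_a^T X_a per subject block; X_a = Y F_a on full voxels.
    # F columns are normalized to unit L2 (the eigenvector convention), which
    # is applied after accumulation since normalization is linear.
    Xa = np.zeros((v, Xa_sub.shape[1]))
    Xb = np.zeros((v, Xb_sub.shape[1]))
    na = np.zeros(Xa_sub.shape[1])
    nb = np.zeros(Xb_sub.shape[1])
    for _, Yi in provider.iter_subjects():
        Fa_i = Yi[rows_a].T @ Xa_sub
        Fb_i = Yi[rows_b].T @ Xb_sub
        na += np.sum(Fa_i**2, axis=0)
        nb += np.sum(Fb_i**2, axis=0)
        Xa += Yi @ Fa_i
        Xb += Yi @ Fb_i
    Xa /= np.sqrt(na)
    Xb /= np.sqrt(nb)

    # joint merge: the two blocks estimate the *same* covariance, so their
    # Gram is averaged (divided by 2) to stay on the exact eigenvalue scale
    Z = np.hstack([Xa, Xb])
    G = Z.T @ Z / (2.0 * (v - 1))
    w, W = full_eigh_desc((G + G.T) / 2.0)
    keep = drop_tiny(w, what="SVP joint Gram")
    if keep.size < k:
        raise ValueError("rank collapse in the SVP joint Gram")
    w, W = w[keep], W[:, keep]

    basis = (Z @ W[:, :k]) / np.sqrt(2.0 * (v - 1) * w[:k])
    basis = fix_signs(basis)
    res = build_result(
        basis,
        w[:k],
        "svp",
        v,
        extra={
            "dataloads": provider.dataloads - loads0,
            "scheme_depth": scheme.depth,
            "k_intermediate": k_intermediate,
            "all_eigenvalues": w,
            "all_components": (Z @ W) / np.sqrt(2.0 * (v - 1) * w),
        },
    )
    if compute_backproj:
        attach_backproj(res, provider)
    return res


@dataclass
class StpState:
    """Running STP merge state: the current v x k' subspace and its spectrum."""

    current_basis: np.ndarray
    current_eigenvalues: np.ndarray
    groups_consumed: int
    g: int
    k_intermediate: int


def _group_block(provider: GroupProvider, members, k_int: int):
    """Exact PCA of one subject group: X_g = Y_g F_g with variance weights."""
    v = provider.v
    Yg = np.hstack([provider.get_subject(i) for i in members])
    gp = Yg.shape[1]
    kk = min(k_int, gp)
    Cg = Yg.T @ Yg / (v - 1)
    wg, Fg = topk_eigh((Cg + Cg.T) / 2.0, kk)
    keep = drop_tiny(wg, what="STP group covariance")
    return Yg @ Fg[:, keep], wg[keep]


def stp(
    provider: GroupProvider,
    k: int,
    k_intermediate: int = 500,
    g: int = 20,
    shuffle: bool = False,
    seed: int | None = None,
    compute_backproj: bool = False,
) -> PCAResult:
    """Sub-sampled time PCA: one streaming pass, incremental group merges.

    Subjects are partitioned into groups of ``g`` in input order (optionally a
    seeded shuffle). Each group's exact PCA block ``X_g = Y_g F_g`` is merged
    into the running subspace through a 2k' x 2k' joint EVD, truncating back to
    the top k' columns after every merge; a single ``Lambda^{-1/2}``
    normalization is applied at the end. Exactly one dataload per subject.
    """
    v, M, p = provider.v, provider.M, provider.p
    if k > k_intermediate:
        raise ValueError("k must be <= k_intermediate")
    order = np.arange(M)
    if shuffle:
        order = np.random.default_rng(seed).permutation(M)
    groups = [order[i : i + g] for i in range(0, M, g)]
    loads0 = provider.dataloads

    first_cap = len(groups[0]) * p
    k_int = k_intermediate
    if k_int > first_cap:
        warnings.warn(
            f"k_intermediate lowered from {k_int} to {first_cap} "
            "(first group has only that many columns)",
            stacklevel=2,
        )
        k_int = first_cap
    if k > k_int:
        raise ValueError("k exceeds the attainable intermediate model order")

    Xg, wg = _group_block(provider, groups[0], k_int)
    state = StpState(Xg, wg, 1, g, k_int)

    for members in groups[1:]:
        Xh, _ = _group_block(provider, members, k_int)
        Z = np.hstack([state.current_basis, Xh])
        G = Z.T @ Z / (v - 1)
        w, W = full_eigh_desc((G + G.T) / 2.0)
        keep = drop_tiny(w, what="STP merge Gram")
        kk = min(k_int, keep.size)
        state.current_basis = Z @ W[:, keep[:kk]]
        state.current_eigenvalues = w[keep[:kk]]
        state.groups_consumed += 1

    w = state.current_eigenvalues
    if w.size < k or w[k - 1] <= 0:
        raise ValueError("rank collapse: fewer than k positive directions in STP")
    basis = state.current_basis[:, :k] / np.sqrt((v - 1) * w[:k])
    basis = fix_signs(basis)
    res = build_result(
        basis,
        w[:k],
        "stp",
        v,
        extra={
            "dataloads": provider.dataloads - loads0,
            "g": g,
            "k_intermediate": k_int,
            "groups": len(groups),
            "all_eigenvalues": w,
            "all_components": state.current_basis / np.sqrt((v - 1) * w),
        },
    )
    if compute_backproj:
        attach_backproj(res, provider)
    return res
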