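"""Synthetic multi-subject group datasets with known ground truth.

Every subject shares a planted orthonormal spatial basis with a planted
variance spectrum; subjects differ through random orthonormal temporal mixing,
optional i.i.d. Gaussian noise, and (optionally) spatial smoothness of the
basis over a synthetic 3-D voxel grid. With zero noise, the concatenated group
covariance has eigenvalues exactly ``M * spectrum`` on the planted subspace,
so solver recovery can be checked to numerical precision.

The fixtures run the full two-stage pipeline: raw ``v x t`` subjects are
reduced by subject-level PCA before the group provider is built, exactly as
with real data. Subject whitening is off by default here — it is an optional
step of the pipeline, and skipping it keeps the planted group spectrum
identifiable (whitening a shared-basis construction collapses the group
spectrum into a cluster at M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import fix_signs
from .provider import DataMatrix, GroupProvider, center_columns, make_provider
from .subject import reduce_subject

__all__ = ["SyntheticGroundTruth", "generate_group", "default_fixture", "FixtureBundle"]


@dataclass
class SyntheticGroundTruth:
    planted_basis: np.ndarray  # v x r orthonormal, zero-mean columns
    planted_spectrum: np.ndarray  # r descending positive eigenvalues (per subject)
    group_spectrum: np.ndarray  # M * planted_spectrum: noiseless group eigenvalues
    noise_sd: float
    smoothness: float
    seed: int
    subject_params: list = field(default_factory=list)  # per-subject t x r mixing


def _planted_basis(rng, v: int, r: int, smoothness: float, grid_shape=None) -> np.ndarray:
    G = rng.standard_normal((v, r))
    if smoothness > 0:
        from scipy.ndimage import gaussian_filter

        if grid_shape is None:
            side = int(np.ceil(v ** (1 / 3)))
            grid_shape = (side, side, side)
        if int(np.prod(grid_shape)) < v:
            raise ValueError("grid_shape too small for v voxels")
        fields = np.empty((v, r))
        for j in range(r):
            f = rng.standard_normal(grid_shape)
            f = gaussian_filter(f, sigma=smoothness)
            fields[:, j] = f.ravel(order="F")[:v]
        G = fields
    G = G - G.mean(axis=0, keepdims=True)  # zero-mean columns survive QR
    Q, _ = np.linalg.qr(G)
    return fix_signs(Q)


def generate_group(
    v: int,
    t: int,
    M: int,
    r: int,
    spectrum,
    noise_sd: float = 0.0,
    smoothness: float = 0.0,
    seed: int = 0,
    grid_shape=None,
):
    """Generate M centered v x t subject matrices sharing a planted basis.

    Each subject is ``Q diag(sqrt(spectrum * (v-1))) A_i^T + noise`` with
    ``A_i`` a random orthonormal t x r temporal mixing, so a noiseless
    subject's time-dimension covariance has eigenvalues exactly ``spectrum``.
    Deterministic for a fixed seed.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if r > min(v, t):
        raise ValueError(f"r={r} exceeds min(v, t) = {min(v, t)}")
    if spectrum.shape != (r,):
        raise ValueError("spectrum must have length r")
    if np.any(spectrum <= 0) or np.any(np.diff(spectrum) > 0):
        raise ValueError("spectrum must be positive and descending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    Q = _planted_basis(rng, v, r, smoothness, grid_shape)
    scale = np.sqrt(spectrum * (v - 1))
    subjects = []
    mixings = []
    for i in range(M):
        A, _ = np.linalg.qr(rng.standard_normal((t, r)))
        Z = Q @ (scale[:, None] * A.T)
        if noise_sd > 0:
            Z = Z + noise_sd * rng.standard_normal((v, t))
        dm = center_columns(DataMatrix(Z, subject_id=f"sim{i:03d}"))
        subjects.append(dm)
        mixings.append(A)
    truth = SyntheticGroundTruth(
        planted_basis=Q,
        planted_spectrum=spectrum,
        group_spectrum=M * spectrum,
        noise_sd=noise_sd,
        smoothness=smoothness,
        seed=seed,
        subject_params=mixings,
    )
    return subjects, truth


# ---------------------------------------------------------------------------
# canonical desk-scale fixtures

#   profile: v, t, M, p, r, spectrum top, noise_sd, solver params (k, k', g)
# k_intermediate keeps the 5k ratio used at full scale (k=100 -> k'=500); the
# STP group size is chosen so several merge steps actually happen.
_PROFILES = {
    "tiny": dict(v=500, t=30, M=4, p=10, r=8, top=8.0, noise_sd=0.5, seed=0,
                 params=dict(k=5, k_intermediate=20, g=2)),
    "small": dict(v=3000, t=60, M=10, p=20, r=20, top=20.0, noise_sd=1.0, seed=0,
                  params=dict(k=10, k_intermediate=50, g=3)),
    "medium": dict(v=8000, t=90, M=40, p=30, r=25, top=25.0, noise_sd=1.0, seed=0,
                   params=dict(k=10, k_intermediate=60, g=8)),
}


@dataclass
class FixtureBundle:
    provider: GroupProvider
    truth: SyntheticGroundTruth
    params: dict
    profile: str
    reduced: list  # per-subject ReducedSubject objects
    raw_subjects: list  # per-subject centered DataMatrix (v x t)


def default_fixture(
    profile: str = "small",
    mode: str = "stacked",
    noise_sd: float | None = None,
    whiten: bool = False,
    seed: int | None = None,
) -> FixtureBundle:
    """Standard fixture: generate, run subject-level PCA, build the provider."""
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    cfg = _PROFILES[profile]
    r = cfg["r"]
    spectrum = np.linspace(cfg["top"], 1.0, r)
    subjects, truth = generate_group(
        v=cfg["v"],
        t=cfg["t"],
        M=cfg["M"],
        r=r,
        spectrum=spectrum,
        noise_sd=cfg["noise_sd"] if noise_sd is None else noise_sd,
        seed=cfg["seed"] if seed is None else seed,
    )
    reduced = [reduce_subject(z, p=cfg["p"], whiten=whiten) for z in subjects]
    provider = make_provider(
        [rs.scores for rs in reduced],
        mode=mode,
        subject_ids=[rs.subject_id for rs in reduced],
    )
    return FixtureBundle(
        provider=provider,
        truth=truth,
        params=dict(cfg["params"]),
        profile=profile,
        reduced=reduced,
        raw_subjects=subjects,
    )
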