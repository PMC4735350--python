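"""Result containers shared by all group-PCA solvers.

Every solver returns a :class:`PCAResult` holding the orthonormal spatial basis
(the left singular subspace of the concatenated data ``Y``), the eigenvalues of
the group covariance ``C = Y^T Y/(v-1)``, a whitened copy of the basis scaled to
unit sample variance, and (optionally) the back-projection eigenvector matrix
``F`` needed by downstream GICA1-style back-reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import normalize_columns


@dataclass
class ConvergenceTrace:
    """Per-iteration eigenvalue (or singular value) estimates and their changes.

    ``history`` holds one vector per evaluation, starting with the initial
    reference (all zeros for cold starts), so ``len(history) ==
    len(diff_norms) + 1``.
    """

    history: list = field(default_factory=list)
    diff_norms: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    extra: dict = field(default_factory=dict)

    def record(self, values: np.ndarray) -> float | None:
        values = np.asarray(values, dtype=float).copy()
        diff = None
        if self.history:
            prev = self.history[-1]
            m = min(prev.size, values.size)
            diff = float(np.linalg.norm(values[:m] - prev[:m]))
            self.diff_norms.append(diff)
        self.history.append(values)
        return diff


@dataclass
class PCAResult:
    """Top-k group PCA decomposition.

    basis        v x k orthonormal (left singular subspace of Y)
    eigenvalues  k descending eigenvalues of C = Y^T Y/(v-1)
    whitened     v x k, basis scaled so columns have unit sample variance
    backproj     (M p) x k eigenvector matrix F with unit-L2 columns, or None
                 when the solver's dataload contract forbids the extra pass
                 (subsampled initializers); see ``attach_backproj``.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    whitened: np.ndarray
    method: str
    backproj: np.ndarray | None = None
    trace: ConvergenceTrace | None = None
    extra: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        k = self.k
        v = self.basis.shape[0]
        if not np.allclose(self.basis.T @ self.basis, np.eye(k), atol=atol):
            raise AssertionError("basis not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise AssertionError("eigenvalues not descending")
        if np.any(self.eigenvalues < -1e-10):
            raise AssertionError("negative eigenvalue")
        if not np.allclose(
            self.whitened.T @ self.whitened / (v - 1), np.eye(k), atol=1e-6
        ):
            raise AssertionError("whitened columns lack unit sample variance")
        if self.backproj is not None:
            norms = np.linalg.norm(self.backproj, axis=0)
            if not np.allclose(norms, 1.0, atol=atol):
                raise AssertionError("backproj columns not unit norm")


def build_result(
    basis: np.ndarray,
    eigenvalues: np.ndarray,
    method: str,
    v: int,
    backproj: np.ndarray | None = None,
    trace: ConvergenceTrace | None = None,
    extra: dict | None = None,
) -> PCAResult:
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    eigenvalues = np.where(
        (eigenvalues < 0) & (eigenvalues > -1e-12), 0.0, eigenvalues
    )
    whitened = basis * np.sqrt(v - 1)
    return PCAResult(
        basis=basis,
        eigenvalues=eigenvalues,
        whitened=whitened,
        method=method,
        backproj=backproj,
        trace=trace,
        extra=extra or {},
    )


def attach_backproj(result: PCAResult, provider) -> PCAResult:
    """Compute F = Y^T basis (unit-norm columns) with one extra pass over the data."""
    F = provider.adjoint(result.basis)
    result.backproj = normalize_columns(F)
    result.extra["backproj_dataloads"] = provider.M
    return result
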