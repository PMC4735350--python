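"""HDF5 persistence for reduced subjects and PCA results."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .results import PCAResult, build_result
from .subject import ReducedSubject

__all__ = [
    "save_subject_matrix",
    "save_reduced_subject",
    "load_reduced_subject",
    "save_result",
    "load_result",
]


def save_subject_matrix(path, Y: np.ndarray, subject_id: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=np.asarray(Y, dtype=np.float64))
        f.attrs["subject_id"] = subject_id


def save_reduced_subject(path, rs: ReducedSubject) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=np.asarray(rs.scores, dtype=np.float64))
        f.create_dataset("eigenvalues", data=np.asarray(rs.eigenvalues, dtype=np.float64))
        f.attrs["subject_id"] = rs.subject_id
        f.attrs["whitened"] = bool(rs.whitened)


def load_reduced_subject(path):
    with h5py.File(path, "r") as f:
        return {
            "Y": np.asarray(f["Y"]),
            "eigenvalues": np.asarray(f["eigenvalues"]),
            "subject_id": str(f.attrs.get("subject_id", "")),
            "whitened": bool(f.attrs.get("whitened", True)),
        }


def save_result(path, result: PCAResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("basis", data=result.basis)
        f.create_dataset("eigenvalues", data=result.eigenvalues)
        f.create_dataset("whitened", data=result.whitened)
        if result.backproj is not None:
            f.create_dataset("backproj", data=result.backproj)
        f.attrs["method"] = result.method
        if result.trace is not None:
            g = f.create_group("trace")
            g.attrs["converged"] = bool(result.trace.converged)
            g.attrs["iterations"] = int(result.trace.iterations)
            g.create_dataset("diff_norms", data=np.asarray(result.trace.diff_norms))
            for i, h in enumerate(result.trace.history):
                g.create_dataset(f"history/{i:04d}", data=np.asarray(h))


def load_result(path) -> PCAResult:
    with h5py.File(path, "r") as f:
        basis = np.asarray(f["basis"])
        res = build_result(
            basis,
            np.asarray(f["eigenvalues"]),
            str(f.attrs["method"]),
            basis.shape[0],
            backproj=np.asarray(f["backproj"]) if "backproj" in f else None,
        )
        return res
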