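"""Loading, masking, centering, and group-level access to multi-subject data.

A group analysis works on the temporal concatenation ``Y = [Y_1 ... Y_M]`` of
per-subject voxels x components matrices. :class:`GroupProvider` presents that
conceptual matrix through a uniform interface in two modes:

* ``stacked``   — all subject matrices are materialized in memory up front;
* ``unstacked`` — subjects are (re)loaded from their sources one at a time per
  pass, with a dataload counter tracking I/O cost (one dataload = one read of a
  subject matrix into memory).

Both modes drive solvers through the same per-subject arithmetic, so results
are identical bit-for-bit across modes; only residency and accounting differ.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DataMatrix",
    "BrainMask",
    "GroupProvider",
    "subject_mask",
    "common_mask",
    "center_columns",
    "apply_mask",
    "make_provider",
    "load_matrix",
]


@dataclass
class DataMatrix:
    """One subject's voxels x time (or voxels x components) matrix."""

    values: np.ndarray
    subject_id: str = ""
    centered: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DataMatrix contains NaN or Inf entries")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class BrainMask:
    """Boolean voxel-inclusion flags over a 3-D grid."""

    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 3:
            raise ValueError("BrainMask requires a 3-D boolean array")

    @property
    def grid_shape(self):
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    def linear_flags(self) -> np.ndarray:
        """Flags linearized in fixed column-major (Fortran) grid order."""
        return self.flags.ravel(order="F")

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) grid coordinates of masked voxels, column-major order."""
        lin = np.flatnonzero(self.linear_flags())
        return np.column_stack(np.unravel_index(lin, self.grid_shape, order="F"))


def subject_mask(volume_series: np.ndarray) -> BrainMask:
    """Per-subject brain mask: a voxel is kept iff, at every time point, its
    value is >= the mean over the entire volume at that time point.

    The per-timepoint masks are combined by element-wise AND (the logical
    analogue of multiplying binary masks).
    """
    arr = np.asarray(volume_series, dtype=float)
    if arr.ndim != 4 or arr.shape[3] < 1:
        raise ValueError("expected a 4-D volume series with >= 1 time point")
    if not np.all(np.isfinite(arr)):
        raise ValueError("volume series contains NaN or Inf")
    flags = np.ones(arr.shape[:3], dtype=bool)
    for ti in range(arr.shape[3]):
        vol = arr[..., ti]
        if not np.any(vol):
            raise ValueError("degenerate volume: all-zero volume at time point %d" % ti)
        flags &= vol >= vol.mean()
    return BrainMask(flags)


def common_mask(masks: list[BrainMask]) -> BrainMask:
    """Element-wise AND of individual subject masks (the group analysis mask)."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].grid_shape
    flags = np.ones(shape, dtype=bool)
    for m in masks:
        if m.grid_shape != shape:
            raise ValueError(f"mask shape mismatch: {m.grid_shape} vs {shape}")
        flags &= m.flags
    out = BrainMask(flags)
    if out.n_voxels == 0:
        raise ValueError("empty common mask")
    return out


def apply_mask(volume_series: np.ndarray, mask: BrainMask, subject_id: str = "") -> DataMatrix:
    """Extract the masked voxels x time matrix, voxels in column-major grid order."""
    arr = np.asarray(volume_series, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a 4-D volume series")
    if arr.shape[:3] != mask.grid_shape:
        raise ValueError("volume grid does not match mask grid")
    t = arr.shape[3]
    flat = arr.reshape(-1, t, order="F")
    return DataMatrix(flat[mask.linear_flags()], subject_id=subject_id)


def center_columns(m: DataMatrix) -> DataMatrix:
    """Remove each column's mean (zero-mean at each time point). Idempotent."""
    if m.values.shape[0] < 2:
        raise ValueError("centering requires >= 2 rows")
    vals = m.values - m.values.mean(axis=0, keepdims=True)
    return DataMatrix(vals, subject_id=m.subject_id, centered=True)


# --------------------------------------------------------------------------
# sources and the group provider


def load_matrix(path: str | os.PathLike, dataset: str = "Y") -> np.ndarray:
    """Read a subject matrix from HDF5 (dataset "Y"), MATLAB v7 .mat, or .npy."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    suffix = p.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(p, "r") as f:
            if dataset in f:
                return np.asarray(f[dataset], dtype=float)
            for key in f:
                obj = f[key]
                if hasattr(obj, "ndim") and obj.ndim == 2:
                    return np.asarray(obj, dtype=float)
        raise ValueError(f"no 2-D dataset found in {p}")
    if suffix == ".mat":
        from scipy.io import loadmat

        data = loadmat(p)
        if dataset in data:
            return np.asarray(data[dataset], dtype=float)
        for key, val in data.items():
            if not key.startswith("__") and getattr(val, "ndim", 0) == 2:
                return np.asarray(val, dtype=float)
        raise ValueError(f"no 2-D matrix variable found in {p}")
    if suffix == ".npy":
        return np.asarray(np.load(p), dtype=float)
    raise ValueError(f"unsupported matrix container: {p.suffix}")


def _resolve(source, subject_id: str) -> np.ndarray:
    if isinstance(source, DataMatrix):
        arr = source.values
    elif isinstance(source, np.ndarray):
        arr = np.asarray(source, dtype=float)
    elif isinstance(source, (str, os.PathLike)):
        try:
            arr = load_matrix(source)
        except Exception as exc:
            raise ValueError(f"unreadable source for subject {subject_id!r}: {exc}") from exc
    else:
        raise TypeError(f"unsupported source type for subject {subject_id!r}: {type(source)}")
    if arr.ndim != 2:
        raise ValueError(f"subject {subject_id!r}: expected a 2-D matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"subject {subject_id!r}: matrix contains NaN or Inf")
    return arr


class GroupProvider:
    """Uniform access to the concatenated group matrix Y = [Y_1 ... Y_M].

    Sources are treated as immutable during a run: in-memory arrays are copied
    at construction, and repeated iteration yields bit-identical matrices.
    """

    def __init__(self, sources, mode: str = "stacked", subject_ids=None):
        if mode not in ("stacked", "unstacked"):
            raise ValueError("mode must be 'stacked' or 'unstacked'")
        sources = list(sources)
        if not sources:
            raise ValueError("need at least one subject source")
        self.mode = mode
        if subject_ids is None:
            subject_ids = [
                s.subject_id
                if isinstance(s, DataMatrix) and s.subject_id
                else f"subject{i:03d}"
                for i, s in enumerate(sources)
            ]
        self.subject_ids = list(subject_ids)
        self._dataloads = 0

        # shape check touches every source once (not counted as a dataload for
        # in-memory sources; file sources are validated lazily below)
        self._sources = []
        v = p = None
        for sid, src in zip(self.subject_ids, sources):
            if isinstance(src, (str, os.PathLike)):
                self._sources.append(src)
                continue
            arr = _resolve(src, sid).copy()
            self._sources.append(arr)

        self._cache = None
        if mode == "stacked":
            mats = [self._load(i) for i in range(len(self._sources))]
            self._check_shapes(mats)
            self._cache = mats
            self._dataloads = len(mats)
        else:
            # validate shapes with one throwaway pass, then reset the counter
            mats = [self._load(i) for i in range(len(self._sources))]
            self._check_shapes(mats)
            del mats
            self._dataloads = 0

    def _check_shapes(self, mats):
        v = mats[0].shape[0]
        p = mats[0].shape[1]
        for sid, m in zip(self.subject_ids, mats):
            if m.shape[0] != v:
                raise ValueError(
                    f"inconsistent row count for subject {sid!r}: {m.shape[0]} != {v}"
                )
            if m.shape[1] != p:
                raise ValueError(
                    f"inconsistent column count for subject {sid!r}: {m.shape[1]} != {p}"
                )
        self._v, self._p = v, p

    def _load(self, i: int) -> np.ndarray:
        src = self._sources[i]
        if isinstance(src, np.ndarray):
            return src
        return _resolve(src, self.subject_ids[i])

    # -- basic geometry ----------------------------------------------------
    @property
    def v(self) -> int:
        return self._v

    @property
    def p(self) -> int:
        return self._p

    @property
    def M(self) -> int:
        return len(self._sources)

    @property
    def total_cols(self) -> int:
        return self.M * self.p

    # -- dataload accounting ----------------------------------------------
    @property
    def dataloads(self) -> int:
        return self._dataloads

    def reset_dataloads(self) -> None:
        self._dataloads = 0

    # -- access ------------------------------------------------------------
    def get_subject(self, i: int) -> np.ndarray:
        if self.mode == "stacked":
            return self._cache[i]
        self._dataloads += 1
        return self._load(i)

    def iter_subjects(self):
        for i in range(self.M):
            yield i, self.get_subject(i)

    def stacked_matrix(self) -> np.ndarray:
        """The materialized v x Mp matrix Y (stacked mode only)."""
        if self.mode != "stacked":
            raise RuntimeError(
                "stacked_matrix() unavailable in unstacked mode "
                "(would violate the one-subject-resident contract)"
            )
        return np.hstack(self._cache)

    # -- group-level products (one pass, one subject resident at a time) ---
    def apply_cov(self, X: np.ndarray) -> np.ndarray:
        """(Y Y^T) X accumulated per subject: sum_i Y_i (X^T Y_i)^T."""
        acc = np.zeros((self.v, X.shape[1]))
        for _, Yi in self.iter_subjects():
            acc += Yi @ (Yi.T @ X)
        return acc

    def adjoint(self, X: np.ndarray) -> np.ndarray:
        """Y^T X, stacked per-subject blocks (Mp x c)."""
        blocks = [Yi.T @ X for _, Yi in self.iter_subjects()]
        return np.vstack(blocks)

    def project(self, F: np.ndarray) -> np.ndarray:
        """Y F for a block matrix F of shape (Mp x c)."""
        if F.shape[0] != self.total_cols:
            raise ValueError("row count of F does not match M*p")
        acc = np.zeros((self.v, F.shape[1]))
        for i, Yi in self.iter_subjects():
            acc += Yi @ F[i * self.p : (i + 1) * self.p]
        return acc


def make_provider(sources, mode: str = "stacked", subject_ids=None) -> GroupProvider:
    """Build a :class:`GroupProvider` over in-memory matrices or file paths."""
    return GroupProvider(sources, mode=mode, subject_ids=subject_ids)
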