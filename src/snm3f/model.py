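"""Space-by-time decomposition model of muscle activity.

A single-trial muscle pattern ``M^s`` (``T`` time steps x ``M`` muscles,
non-negative) is approximated by the tri-factorization

    M^s  ~=  W_t  A^s  W_s      for every trial s,

where the columns of ``W_t`` (T x P) are *temporal modules* shared across
trials, the rows of ``W_s`` (N x M) are *spatial modules* shared across
trials, and ``A^s`` (P x N) holds the per-trial non-negative activation
coefficients that couple temporal module i with spatial module j.

This module houses the container types (:class:`EMGDataset`,
:class:`SpaceByTimeModel`), reconstruction, the reconstruction error
:func:`e_nmf`, the variance-accounted-for metric :func:`vaf`, the
module-normalization convention, and the parameter-count bookkeeping that
quantifies the compression achieved by the decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMGDataset",
    "SpaceByTimeModel",
    "ParameterCounts",
    "reconstruct",
    "e_nmf",
    "total_scatter_about_mean",
    "vaf",
    "parameter_counts",
    "normalize_modules",
]


class DegenerateDataError(ValueError):
    """Raised when a metric is undefined for the given data (e.g. VAF on
    a dataset whose trials are all identical)."""


@dataclass
class EMGDataset:
    """A set of S single-trial EMG matrices with optional task labels.

    Parameters
    ----------
    data
        Array of shape (S, T, M): S trials, T time steps, M muscles.
        All entries must be non-negative and finite.
    labels
        Optional integer task id per trial. Task ids may be any integers;
        every present task must have at least one trial.
    muscle_names
        Optional sequence of M muscle names (used by the CSV writer).
    """

    data: np.ndarray
    labels: np.ndarray | None = None
    muscle_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (S, T, M), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if np.any(self.data < 0):
            raise ValueError("EMG data must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError(
                    f"labels shape {self.labels.shape} does not match S={self.data.shape[0]}"
                )
        if self.muscle_names is not None:
            self.muscle_names = list(self.muscle_names)
            if len(self.muscle_names) != self.data.shape[2]:
                raise ValueError("muscle_names length does not match M")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.data.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.data.shape[2]

    @property
    def dims(self) -> tuple[int, int, int]:
        """(S, T, M)."""
        return self.data.shape

    @property
    def n_tasks(self) -> int:
        if self.labels is None:
            raise ValueError("dataset has no task labels")
        return len(np.unique(self.labels))

    def subset(self, indices) -> "EMGDataset":
        """Dataset restricted to the given trial indices (order preserved)."""
        indices = np.asarray(indices)
        return EMGDataset(
            self.data[indices],
            None if self.labels is None else self.labels[indices],
            self.muscle_names,
        )

    @classmethod
    def from_matrices(cls, matrices, labels=None, muscle_names=None) -> "EMGDataset":
        """Build a dataset from an iterable of T x M trial matrices."""
        mats = [np.asarray(m, dtype=float) for m in matrices]
        if not mats:
            raise ValueError("empty trial collection")
        shape = mats[0].shape
        for i, m in enumerate(mats):
            if m.shape != shape:
                raise ValueError(
                    f"trial {i} has shape {m.shape}, expected {shape}: "
                    "all trials must share (T, M)"
                )
        return cls(np.stack(mats), labels, muscle_names)


@dataclass
class SpaceByTimeModel:
    """Fitted space-by-time decomposition.

    Attributes
    ----------
    temporal_modules
        (T, P) non-negative; each column is one temporal module w_i(t).
        After :func:`normalize_modules`, each column sums to 1.
    spatial_modules
        (N, M) non-negative; each row is one spatial module w_j. After
        :func:`normalize_modules`, each row sums to 1.
    coefficients
        (S, P, N) non-negative per-trial activation coefficients a^s_ij.
    """

    temporal_modules: np.ndarray
    spatial_modules: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.temporal_modules = np.asarray(self.temporal_modules, dtype=float)
        self.spatial_modules = np.asarray(self.spatial_modules, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.temporal_modules.ndim != 2 or self.spatial_modules.ndim != 2:
            raise ValueError("module matrices must be 2-D")
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must be 3-D (S, P, N)")
        T, P = self.temporal_modules.shape
        N, M = self.spatial_modules.shape
        if self.coefficients.shape[1:] != (P, N):
            raise ValueError(
                f"coefficients shape {self.coefficients.shape} inconsistent with "
                f"P={P}, N={N}"
            )
        for name, arr in (
            ("temporal_modules", self.temporal_modules),
            ("spatial_modules", self.spatial_modules),
            ("coefficients", self.coefficients),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int, int, int]:
        """(T, M, P, N, S)."""
        T, P = self.temporal_modules.shape
        N, M = self.spatial_modules.shape
        return T, M, P, N, self.coefficients.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]

    def reconstruct_all(self) -> np.ndarray:
        """All S reconstructions W_t A^s W_s, shape (S, T, M)."""
        return np.einsum(
            "tp,spn,nm->stm",
            self.temporal_modules,
            self.coefficients,
            self.spatial_modules,
        )


@dataclass
class ParameterCounts:
    """Parameter bookkeeping for the space-by-time compression argument."""

    full: int
    coeff: int
    modules: int
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.coeff + self.modules


def reconstruct(model: SpaceByTimeModel, s: int) -> np.ndarray:
    """Reconstruction W_t A^s W_s of trial ``s`` (0-based storage index)."""
    S = model.n_samples
    if not 0 <= s < S:
        raise IndexError(f"sample index {s} out of range [0, {S})")
    return model.temporal_modules @ model.coefficients[s] @ model.spatial_modules


def e_nmf(data: EMGDataset, model: SpaceByTimeModel) -> float:
    """Total squared reconstruction error sum_s ||M^s - W_t A^s W_s||_fro^2."""
    T, M, _, _, S = model.dims
    if data.dims != (S, T, M):
        raise ValueError(f"data dims {data.dims} do not match model (S,T,M)=({S},{T},{M})")
    resid = data.data - model.reconstruct_all()
    return float(np.sum(resid * resid))


def total_scatter_about_mean(data: EMGDataset) -> float:
    """sum_s ||M^s - Mbar||_fro^2 with Mbar the across-trial mean pattern."""
    centred = data.data - data.data.mean(axis=0, keepdims=True)
    return float(np.sum(centred * centred))


def vaf(data: EMGDataset, model: SpaceByTimeModel) -> float:
    """Variance accounted for: 1 - E^2_NMF / sum_s ||M^s - Mbar||_fro^2.

    Equals 1 for an exact reconstruction; can be negative for models worse
    than the across-trial mean pattern. Undefined (raises
    :class:`DegenerateDataError`) when all trials are identical.
    """
    denom = total_scatter_about_mean(data)
    # threshold relative to the data's own scale: summation round-off can
    # leave a ~1e-32 residual on exactly identical trials
    if denom <= 1e-12 * max(float(np.sum(data.data * data.data)), 1.0):
        raise DegenerateDataError(
            "VAF undefined: all trials are identical (zero scatter about the mean)"
        )
    return 1.0 - e_nmf(data, model) / denom


def parameter_counts(M: int, T: int, S: int, N: int, P: int) -> ParameterCounts:
    """Count free parameters: the full dataset (M*T*S) vs the decomposition.

    The decomposition needs N*P*S activation coefficients plus the shared
    modules (N*M spatial weights and T*P temporal samples).
    """
    for name, v in (("M", M), ("T", T), ("S", S), ("N", N), ("P", P)):
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return ParameterCounts(full=M * T * S, coeff=N * P * S, modules=N * M + T * P)


def normalize_modules(model: SpaceByTimeModel, compensate: bool = True) -> SpaceByTimeModel:
    """Rescale each temporal module (column of W_t) and each spatial module
    (row of W_s) to unit sum.

    With ``compensate=True`` the coefficient slices are multiplied by the
    inverse factors so every reconstruction W_t A^s W_s is unchanged. A
    degenerate all-zero module is replaced by a uniform 1/T (or 1/M) vector
    with a warning; its coefficient slice is zeroed so the reconstruction is
    still preserved.
    """
    Wt = model.temporal_modules.copy()
    Ws = model.spatial_modules.copy()
    A = model.coefficients.copy()
    T, P = Wt.shape
    N, M = Ws.shape

    col_sums = Wt.sum(axis=0)
    dead_t = col_sums <= 0.0
    if np.any(dead_t):
        warnings.warn(
            f"{int(dead_t.sum())} all-zero temporal module(s) replaced by uniform 1/T",
            RuntimeWarning,
            stacklevel=2,
        )
        Wt[:, dead_t] = 1.0 / T
    Wt[:, ~dead_t] /= col_sums[~dead_t]

    row_sums = Ws.sum(axis=1)
    dead_s = row_sums <= 0.0
    if np.any(dead_s):
        warnings.warn(
            f"{int(dead_s.sum())} all-zero spatial module(s) replaced by uniform 1/M",
            RuntimeWarning,
            stacklevel=2,
        )
        Ws[dead_s, :] = 1.0 / M
    Ws[~dead_s, :] /= row_sums[~dead_s, None]

    if compensate:
        # A^s <- D A^s E with D = diag(column sums of W_t), E = diag(row sums
        # of W_s); dead modules contributed nothing, so their slices go to 0.
        d = np.where(dead_t, 0.0, col_sums)
        e = np.where(dead_s, 0.0, row_sums)
        A = A * d[None, :, None] * e[None, None, :]
    return SpaceByTimeModel(Wt, Ws, A)
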