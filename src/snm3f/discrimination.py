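"""Fisher-style task-discrimination cost on activation coefficients.

Task discriminability of a space-by-time decomposition lives entirely in the
per-trial coefficient matrices A^s. With trials partitioned into K tasks
G_1..G_K, the within-task and between-task scatter matrices of the
vectorized coefficients are

    S_w = sum_k sum_{s in G_k} vec(A^s - Abar_k) vec(A^s - Abar_k)^T
    S_b = sum_k               vec(Abar_k - Abar) vec(Abar_k - Abar)^T

with Abar_k the task means and Abar the grand mean over all trials. Note
that each task contributes exactly once to S_b, *unweighted* by its trial
count n_k (this differs from the textbook LDA between-class scatter and is
kept deliberately). The combined fitting cost is

    E^2 = E^2_NMF + gamma * tr(S_w) - delta * tr(S_b),

so gamma penalizes within-task dispersion of the coefficients and delta
rewards between-task separation; gamma = delta = 0 recovers the pure
reconstruction problem. The discrimination ratio J = tr(S_w)/tr(S_b)
summarizes separability (smaller = more discriminable).

Traces are evaluated through the Frobenius identity
tr(S_w) = sum_k sum_{s in G_k} ||A^s - Abar_k||_fro^2 without materializing
the (P*N)^2 matrices; the full matrices are built only on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EMGDataset, SpaceByTimeModel, e_nmf

__all__ = [
    "DiscriminationParams",
    "ScatterSummary",
    "scatter",
    "total_cost",
    "j_ratio",
    "grad_trace_sw",
    "grad_trace_sb",
]

# vec(.) is column-stacking of a P x N matrix; the same convention is used
# for scatter matrices, LDA features and gradients throughout the package.
def _vec(a: np.ndarray) -> np.ndarray:
    return a.reshape(a.shape[0], -1, order="F") if a.ndim == 3 else a.ravel(order="F")


def _check_labels(coefficients: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (coefficients.shape[0],):
        raise ValueError(
            f"labels shape {labels.shape} does not match S={coefficients.shape[0]}"
        )
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 1):  # unreachable with np.unique; kept for clarity
        raise ValueError("every task must contain at least one trial")
    return labels, classes, counts


@dataclass
class DiscriminationParams:
    """Weights of the scatter penalty: gamma >= 0 on tr(S_w), delta >= 0 on
    tr(S_b). gamma = delta = 0 means pure reconstruction (sNM3F)."""

    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.delta < 0:
            raise ValueError("gamma and delta must be non-negative")

    @property
    def active(self) -> bool:
        return self.gamma > 0 or self.delta > 0


@dataclass
class ScatterSummary:
    """Scatter decomposition of a set of coefficient matrices."""

    tr_sw: float
    tr_sb: float
    class_means: np.ndarray  # (K, P, N), ordered by sorted task id
    global_mean: np.ndarray  # (P, N)
    classes: np.ndarray  # sorted task ids
    counts: np.ndarray  # trials per task
    sw: np.ndarray | None = None  # (P*N, P*N), built on demand
    sb: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "tr_sw": self.tr_sw,
            "tr_sb": self.tr_sb,
            "classes": self.classes.tolist(),
            "counts": self.counts.tolist(),
            "class_means": self.class_means.tolist(),
            "global_mean": self.global_mean.tolist(),
        }


def scatter(
    coefficients: np.ndarray,
    labels: np.ndarray,
    full_matrices: bool = False,
) -> ScatterSummary:
    """Within/between-task scatter of the coefficients.

    Parameters
    ----------
    coefficients
        (S, P, N) array (or list of S P x N matrices).
    labels
        Integer task id per trial.
    full_matrices
        Also build the (P*N) x (P*N) matrices S_w and S_b.
    """
    A = np.asarray(coefficients, dtype=float)
    labels, classes, counts = _check_labels(A, labels)
    global_mean = A.mean(axis=0)
    class_means = np.stack([A[labels == k].mean(axis=0) for k in classes])

    tr_sw = 0.0
    for k_idx, k in enumerate(classes):
        dev = A[labels == k] - class_means[k_idx]
        tr_sw += float(np.sum(dev * dev))
    dev_b = class_means - global_mean
    tr_sb = float(np.sum(dev_b * dev_b))

    sw = sb = None
    if full_matrices:
        d = A.shape[1] * A.shape[2]
        sw = np.zeros((d, d))
        for k_idx, k in enumerate(classes):
            dev = _vec(A[labels == k] - class_means[k_idx])
            sw += dev.T @ dev
        vb = _vec(dev_b)
        sb = vb.T @ vb
    return ScatterSummary(tr_sw, tr_sb, class_means, global_mean, classes, counts, sw, sb)


def total_cost(
    data: EMGDataset,
    model: SpaceByTimeModel,
    labels: np.ndarray | None,
    params: DiscriminationParams,
) -> float:
    """Combined cost E^2 = E^2_NMF + gamma tr(S_w) - delta tr(S_b).

    May be negative when delta tr(S_b) dominates. Labels are required when
    either weight is non-zero.
    """
    err = e_nmf(data, model)
    if not params.active:
        return err
    if labels is None:
        labels = data.labels
    if labels is None:
        raise ValueError("task labels required when gamma > 0 or delta > 0")
    summ = scatter(model.coefficients, labels)
    return err + params.gamma * summ.tr_sw - params.delta * summ.tr_sb


def j_ratio(summary: ScatterSummary) -> float:
    """Discrimination ratio J = tr(S_w) / tr(S_b); smaller is better."""
    if summary.tr_sb <= 0.0:
        raise ValueError(
            "J undefined: tr(S_b) = 0 (single task or identical task means)"
        )
    return summary.tr_sw / summary.tr_sb


def grad_trace_sw(coefficients: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d tr(S_w) / d A^s = 2 (A^s - Abar_l) for s in G_l; shape (S, P, N)."""
    A = np.asarray(coefficients, dtype=float)
    labels, classes, _ = _check_labels(A, labels)
    grad = np.empty_like(A)
    for k in classes:
        mask = labels == k
        grad[mask] = 2.0 * (A[mask] - A[mask].mean(axis=0))
    return grad


def grad_trace_sb(coefficients: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d tr(S_b) / d A^s = (2/n_l)(Abar_l - Abar) - (2/S) sum_k (Abar_k - Abar)."""
    A = np.asarray(coefficients, dtype=float)
    labels, classes, counts = _check_labels(A, labels)
    S = A.shape[0]
    global_mean = A.mean(axis=0)
    class_means = np.stack([A[labels == k].mean(axis=0) for k in classes])
    common = (2.0 / S) * (class_means - global_mean).sum(axis=0)
    grad = np.empty_like(A)
    for k_idx, k in enumerate(classes):
        mask = labels == k
        grad[mask] = (2.0 / counts[k_idx]) * (class_means[k_idx] - global_mean) - common
    return grad
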