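"""Task-decoding and model-comparison metrics.

A decomposition is judged on two axes: how well it reconstructs the EMG
(VAF) and how well its per-trial coefficients identify the task performed.
Task identification is measured by

* ``DEC`` — leave-one-out linear-discriminant decoding of the vectorized
  coefficients (fraction of trials whose task is predicted correctly);
* ``CLS`` — generalization to held-out trials: modules are fitted on
  training trials only, every trial is projected onto the fixed modules
  (no labels used), and a linear SVM trained on the training coefficients
  classifies the test coefficients, over repeated stratified splits;
* ``VDM = VAF x DEC`` — the single trade-off score used to tune the
  discrimination weights (clamped into [0, 1]).

Module similarity between two decompositions is the Pearson correlation of
matched module pairs under the assignment that maximizes total similarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.svm import SVC

from .discrimination import j_ratio, scatter
from .model import EMGDataset, SpaceByTimeModel, vaf
from .solvers import project_onto_modules

__all__ = [
    "EvaluationReport",
    "ModulePairing",
    "lda_decode_loo",
    "lda_decode_resubstitution",
    "vdm",
    "module_similarity",
    "svm_classify_cv",
    "compare_models",
]


def _vec_features(coefficients) -> np.ndarray:
    """Vectorize (S, P, N) coefficients by column-stacking each A^s."""
    A = np.asarray(coefficients, dtype=float)
    if A.ndim == 2:  # already vectorized
        return A
    return A.transpose(0, 2, 1).reshape(A.shape[0], -1)


class _PooledCovLDA:
    """Gaussian linear discriminant with pooled within-class covariance and
    empirical class priors. The pooled covariance is ridge-regularized
    (lambda = 1e-6 * trace / dim, with a warning) only when singular."""

    def fit(self, X, y):
        self.classes_, counts = np.unique(y, return_counts=True)
        d = X.shape[1]
        self.means_ = np.stack([X[y == k].mean(axis=0) for k in self.classes_])
        cov = np.zeros((d, d))
        for k_idx, k in enumerate(self.classes_):
            dev = X[y == k] - self.means_[k_idx]
            cov += dev.T @ dev
        cov /= max(len(X) - len(self.classes_), 1)
        try:
            coef = np.linalg.solve(cov, self.means_.T)
            if not np.all(np.isfinite(coef)) or np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular pooled covariance; applying ridge regularization",
                RuntimeWarning,
                stacklevel=3,
            )
            lam = 1e-6 * max(np.trace(cov), 1e-300) / d
            coef = np.linalg.solve(cov + lam * np.eye(d), self.means_.T)
        self.coef_ = coef.T  # (K, d)
        self.intercept_ = (
            -0.5 * np.sum(self.means_ * self.coef_, axis=1)
            + np.log(counts / counts.sum())
        )
        return self

    def predict(self, X):
        scores = X @ self.coef_.T + self.intercept_
        return self.classes_[np.argmax(scores, axis=1)]


def lda_decode_loo(coefficients, labels) -> float:
    """Leave-one-out LDA decoding fraction (DEC) of the coefficients."""
    X = _vec_features(coefficients)
    y = np.asarray(labels, dtype=int)
    S = len(X)
    classes, counts = np.unique(y, return_counts=True)
    if S < len(classes) + 1:
        raise ValueError("need at least K + 1 trials for leave-one-out decoding")
    if np.any(counts < 2):
        raise ValueError("every task needs at least 2 trials for leave-one-out decoding")
    correct = 0
    idx = np.arange(S)
    for s in range(S):
        train = idx != s
        pred = _PooledCovLDA().fit(X[train], y[train]).predict(X[s : s + 1])
        correct += int(pred[0] == y[s])
    return correct / S


def lda_decode_resubstitution(coefficients, labels) -> float:
    """LDA decoding fraction on the training data itself (no hold-out)."""
    X = _vec_features(coefficients)
    y = np.asarray(labels, dtype=int)
    pred = _PooledCovLDA().fit(X, y).predict(X)
    return float(np.mean(pred == y))


def vdm(vaf_value: float, dec: float) -> float:
    """Trade-off score VDM = VAF x DEC, clamped so 0 <= VDM <= 1.

    A negative VAF (model worse than the mean pattern) is clamped to 0.
    """
    if not 0.0 <= dec <= 1.0:
        raise ValueError(f"dec must lie in [0, 1], got {dec}")
    return max(vaf_value, 0.0) * dec


@dataclass
class ModulePairing:
    """Result of matching two sets of modules by maximal total correlation."""

    pairs: list  # (index_a, index_b) per matched pair
    correlations: list  # Pearson R per pair; None where undefined

    @property
    def mean_correlation(self) -> float:
        vals = [r for r in self.correlations if r is not None]
        return float(np.mean(vals)) if vals else float("nan")


def module_similarity(modules_a, modules_b) -> ModulePairing:
    """Match two equally-sized sets of modules and report per-pair Pearson R.

    Both arguments are (n_modules, length) arrays (spatial modules as
    stored; pass ``temporal_modules.T`` for temporal ones). The pairing
    maximizes the summed correlation over all assignments. A zero-variance
    module yields an undefined correlation, reported as ``None`` with a
    warning and treated as worst-case during assignment.
    """
    Amod = np.atleast_2d(np.asarray(modules_a, dtype=float))
    Bmod = np.atleast_2d(np.asarray(modules_b, dtype=float))
    if Amod.shape != Bmod.shape:
        raise ValueError(f"module sets differ in shape: {Amod.shape} vs {Bmod.shape}")
    n = Amod.shape[0]
    R = np.full((n, n), np.nan)
    sa = Amod.std(axis=1)
    sb = Bmod.std(axis=1)
    if np.any(sa == 0) or np.any(sb == 0):
        warnings.warn(
            "zero-variance module: correlation undefined for some pair(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    for i in range(n):
        for j in range(n):
            if sa[i] > 0 and sb[j] > 0:
                R[i, j] = np.corrcoef(Amod[i], Bmod[j])[0, 1]
    cost = np.where(np.isnan(R), 2.0, -R)  # NaN worse than any R in [-1, 1]
    rows, cols = linear_sum_assignment(cost)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    corrs = [None if np.isnan(R[i, j]) else float(R[i, j]) for i, j in pairs]
    return ModulePairing(pairs, corrs)


def svm_classify_cv(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    fit_fn,
    n_train_per_task: int,
    n_splits: int = 20,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, float]:
    """Generalization score CLS of a module-fitting procedure.

    For each of ``n_splits`` stratified splits: ``fit_fn(train_dataset)``
    must return a :class:`FitResult` (or model) fitted on the training
    trials only; all trials are then projected onto the fixed modules
    without label information, a linear SVM is trained on the training
    coefficients and scored on the test coefficients. Returns
    (mean, SD) of the test fraction correct over splits.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if n_train_per_task >= counts.min():
        raise ValueError(
            f"n_train_per_task={n_train_per_task} must be smaller than the "
            f"smallest task size ({counts.min()})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scores = []
    for _ in range(n_splits):
        train_idx = []
        for k in classes:
            members = np.flatnonzero(y == k)
            train_idx.extend(rng.choice(members, size=n_train_per_task, replace=False))
        train_idx = np.sort(np.asarray(train_idx))
        test_mask = np.ones(len(y), dtype=bool)
        test_mask[train_idx] = False
        if len(np.unique(y[train_idx])) < len(classes):
            raise RuntimeError("a task is absent from a training split")

        fitted = fit_fn(data.subset(train_idx))
        model = getattr(fitted, "model", fitted)
        coeffs = project_onto_modules(
            data, model.temporal_modules, model.spatial_modules
        )
        X = _vec_features(coeffs)
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train_idx], y[train_idx])
        scores.append(float(np.mean(clf.predict(X[test_mask]) == y[test_mask])))
    return float(np.mean(scores)), float(np.std(scores))


@dataclass
class EvaluationReport:
    """Metrics of one decomposition (optionally vs a reference model)."""

    vaf: float
    dec: float
    vdm: float
    tr_sw: float | None = None
    tr_sb: float | None = None
    j_ratio: float | None = None
    similarity: dict = field(default_factory=dict)
    cls_mean: float | None = None
    cls_sd: float | None = None
    n_train_per_task: int | None = None

    def to_dict(self) -> dict:
        return {
            "vaf": self.vaf,
            "dec": self.dec,
            "vdm": self.vdm,
            "tr_sw": self.tr_sw,
            "tr_sb": self.tr_sb,
            "j_ratio": self.j_ratio,
            "similarity": self.similarity,
            "cls_mean": self.cls_mean,
            "cls_sd": self.cls_sd,
            "n_train_per_task": self.n_train_per_task,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(s))


def _report_for(data, labels, model) -> EvaluationReport:
    v = vaf(data, model)
    dec = lda_decode_loo(model.coefficients, labels)
    summ = scatter(model.coefficients, labels)
    try:
        j = j_ratio(summ)
    except ValueError:
        j = None
    return EvaluationReport(
        vaf=v, dec=dec, vdm=vdm(v, dec), tr_sw=summ.tr_sw, tr_sb=summ.tr_sb, j_ratio=j
    )


def compare_models(
    data: EMGDataset,
    labels,
    model_a: SpaceByTimeModel,
    model_b: SpaceByTimeModel,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Side-by-side metrics for two decompositions of the same dataset,
    plus cross-model module similarities (no ranking verdict)."""
    rep_a = _report_for(data, labels, model_a)
    rep_b = _report_for(data, labels, model_b)
    spatial = module_similarity(model_a.spatial_modules, model_b.spatial_modules)
    temporal = module_similarity(
        model_a.temporal_modules.T, model_b.temporal_modules.T
    )
    cross = {
        "spatial": {
            "pairs": [list(p) for p in spatial.pairs],
            "correlations": spatial.correlations,
        },
        "temporal": {
            "pairs": [list(p) for p in temporal.pairs],
            "correlations": temporal.correlations,
        },
    }
    rep_a.similarity = cross
    rep_b.similarity = cross
    return rep_a, rep_b
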