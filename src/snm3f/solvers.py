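"""Optimizers for the (discriminative) space-by-time decomposition.

Three interchangeable solvers minimize the combined cost
E^2 = E^2_NMF + gamma tr(S_w) - delta tr(S_b) over non-negative factors
(W_t, {A^s}, W_s) subject to unit-sum temporal-module columns and
spatial-module rows:

``mult``
    Multiplicative updates. The module updates are the classic
    Lee-Seung-style rules on the vertically / horizontally concatenated
    trial blocks; the coefficient update splits the gradient of E^2 into
    its positive (denominator) and negative (numerator) parts, so the
    discrimination terms pull each A^s toward its task mean. Modules are
    renormalized to unit sum once per outer iteration. When the
    discrimination terms are inactive (gamma = delta = 0, the sNM3F
    baseline) the renormalization is compensated in the coefficients, the
    reconstruction is left untouched and E^2_NMF is non-increasing; with
    active discrimination terms the constraint is imposed without
    compensation and monotonicity is no longer guaranteed.
``als`` / ``als_qp``
    Alternating constrained least squares for the modules (coefficients
    keep the multiplicative rule). ``als`` solves the equality-constrained
    normal equations as a KKT linear system (via Kronecker lifting) and
    clips negative entries to zero afterwards; ``als_qp`` solves the
    non-negatively constrained quadratic program instead, which never
    increases the module-update objective.
``nlp``
    Joint constrained optimization of the stacked variable
    z = (vec(W_t), vec(A^1)..vec(A^S), vec(W_s)) with analytic gradients,
    bounds z >= 0 and the linear unit-sum constraints.

All solvers run a configurable number of random restarts and return the
best solution (lowest E^2, ties broken by lowest E^2_NMF, then lowest
restart index). Restart seeds are derived from the master seed, so a fit
is fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.optimize

from .discrimination import (
    DiscriminationParams,
    grad_trace_sb,
    grad_trace_sw,
    scatter,
    total_cost,
)
from .model import EMGDataset, SpaceByTimeModel, e_nmf, normalize_modules

__all__ = [
    "FitOptions",
    "FitResult",
    "FitHistory",
    "fit",
    "fit_snm3f",
    "fit_dsnm3f_mult",
    "fit_dsnm3f_als",
    "fit_dsnm3f_nlp",
    "project_onto_modules",
    "grad_e2_coefficients",
    "e2_with_gradients",
]

_SOLVERS = ("mult", "als", "als_qp", "nlp")


class SolverError(RuntimeError):
    """Raised when a solver fails on every restart; carries the best
    (possibly infeasible) iterate found."""

    def __init__(self, message, best_model=None):
        super().__init__(message)
        self.best_model = best_model


@dataclass
class FitOptions:
    """Knobs shared by all solvers.

    ``tol`` is the relative change of the solver's own objective (E^2_NMF
    for the pure-reconstruction problem, E^2 otherwise) below which the
    alternating loop stops. ``epsilon_guard`` is added to multiplicative
    denominators to avoid division by zero; an entry that reaches exactly
    zero stays zero (multiplicative absorption).
    """

    solver: str = "mult"
    max_iter: int = 500
    tol: float = 1e-8
    n_restarts: int = 1
    seed: int = 0
    epsilon_guard: float = 1e-12
    track_history: bool = True

    def __post_init__(self) -> None:
        if self.solver not in _SOLVERS:
            raise ValueError(f"solver must be one of {_SOLVERS}, got {self.solver!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0 or self.epsilon_guard <= 0:
            raise ValueError("tol and epsilon_guard must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class FitHistory:
    """Per-iteration traces of the cost components."""

    e_nmf: np.ndarray
    tr_sw: np.ndarray
    tr_sb: np.ndarray
    e2: np.ndarray

    @classmethod
    def from_records(cls, records) -> "FitHistory":
        arr = np.asarray(records, dtype=float).reshape(-1, 4)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])

    def __len__(self) -> int:
        return len(self.e2)


@dataclass
class FitResult:
    model: SpaceByTimeModel
    history: FitHistory | None
    converged: bool
    n_iter: int
    restart_index: int
    final_cost: float
    final_e_nmf: float
    restart_costs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

class _LabelInfo:
    """Precomputed label machinery shared across restarts/iterations."""

    __slots__ = ("labels", "classes", "inverse", "counts", "mean_map", "n_s")

    def __init__(self, labels, S):
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (S,):
            raise ValueError(f"labels shape {labels.shape} does not match S={S}")
        self.labels = labels
        self.classes, self.inverse, self.counts = np.unique(
            labels, return_inverse=True, return_counts=True
        )
        K = len(self.classes)
        # mean_map @ A_flat gives the K class means of the (S, ...) stack
        mm = np.zeros((K, S))
        mm[self.inverse, np.arange(S)] = 1.0
        self.mean_map = mm / self.counts[:, None]
        self.n_s = self.counts[self.inverse].astype(float)[:, None, None]


def _label_info(labels, S):
    return _LabelInfo(labels, S)


def _init_factors(rng, T, M, P, N, S):
    Wt = rng.uniform(size=(T, P))
    Wt /= Wt.sum(axis=0, keepdims=True)
    Ws = rng.uniform(size=(N, M))
    Ws /= Ws.sum(axis=1, keepdims=True)
    A = rng.uniform(size=(S, P, N))
    return Wt, Ws, A


def _recon(Wt, A, Ws):
    return np.matmul(np.matmul(Wt, A), Ws)


def _coeff_num_den(X, Wt, Ws, A, lab, params):
    """Numerator/denominator of the multiplicative coefficient update
    (equivalently, grad E^2 wrt A = 2 (den - num))."""
    num = np.matmul(np.matmul(Wt.T, X), Ws.T)
    # W_t^T (W_t A W_s) W_s^T  ==  (W_t^T W_t) A (W_s W_s^T)
    den = np.matmul(np.matmul(Wt.T @ Wt, A), Ws @ Ws.T)
    if params.active and lab is not None:
        S, P, N = A.shape
        K = len(lab.classes)
        global_mean = A.mean(axis=0)
        class_means = (lab.mean_map @ A.reshape(S, -1)).reshape(K, P, N)
        mean_s = class_means[lab.inverse]  # task mean of each trial's own task
        g, d = params.gamma, params.delta
        num = num + g * mean_s + (d / lab.n_s) * mean_s + (d * K / S) * global_mean
        den = den + g * A + (d / lab.n_s) * global_mean + (d / S) * class_means.sum(axis=0)
    return num, den


def grad_e2_coefficients(
    data: EMGDataset,
    model: SpaceByTimeModel,
    labels=None,
    params: DiscriminationParams | None = None,
) -> np.ndarray:
    """Analytic gradient of E^2 with respect to the coefficients, (S, P, N).

    Equals twice the (denominator - numerator) split used by the
    multiplicative update, which is how the update rule is derived.
    """
    params = params or DiscriminationParams()
    lab = None
    if params.active:
        if labels is None:
            labels = data.labels
        if labels is None:
            raise ValueError("labels required for active discrimination terms")
        lab = _label_info(labels, data.n_samples)
    num, den = _coeff_num_den(
        data.data, model.temporal_modules, model.spatial_modules,
        model.coefficients, lab, params,
    )
    return 2.0 * (den - num)


def e2_with_gradients(X, Wt, A, Ws, labels=None, params=None):
    """E^2 and its analytic gradients wrt each factor block.

    Returns ``(value, gWt, gA, gWs)``. Used by the NLP solver and by the
    finite-difference validation of the gradients.
    """
    params = params or DiscriminationParams()
    resid = _recon(Wt, A, Ws) - X
    value = float(np.sum(resid * resid))
    R = np.einsum("spn,nm->spm", A, Ws)  # A^s W_s
    Q = np.einsum("tp,spn->stn", Wt, A)  # W_t A^s
    gWt = 2.0 * np.einsum("stm,spm->tp", resid, R)
    gWs = 2.0 * np.einsum("stn,stm->nm", Q, resid)
    gA = 2.0 * np.einsum("tp,stm,nm->spn", Wt, resid, Ws)
    if params.active:
        if labels is None:
            raise ValueError("labels required for active discrimination terms")
        summ = scatter(A, labels)
        value += params.gamma * summ.tr_sw - params.delta * summ.tr_sb
        gA = gA + params.gamma * grad_trace_sw(A, labels)
        gA = gA - params.delta * grad_trace_sb(A, labels)
    return value, gWt, gA, gWs


def _traces(A, lab):
    """Fast tr(S_w), tr(S_b) via the Frobenius identity."""
    S = A.shape[0]
    flat = A.reshape(S, -1)
    class_means = lab.mean_map @ flat
    dev_w = flat - class_means[lab.inverse]
    dev_b = class_means - flat.mean(axis=0)
    return float(np.sum(dev_w * dev_w)), float(np.sum(dev_b * dev_b))


def _objective(X, Wt, A, Ws, lab, params):
    resid = _recon(Wt, A, Ws) - X
    e2_nmf = float(np.sum(resid * resid))
    if lab is not None:
        tr_sw, tr_sb = _traces(A, lab)
    else:
        tr_sw = tr_sb = 0.0
    e2 = e2_nmf + params.gamma * tr_sw - params.delta * tr_sb
    return e2_nmf, tr_sw, tr_sb, e2


# ---------------------------------------------------------------------------
# MULT engine
# ---------------------------------------------------------------------------

def _normalize_inplace(Wt, Ws, A, compensate):
    """Unit-sum module normalization inside the solver loop; dead modules
    go uniform with their coefficient slice zeroed (reconstruction kept)."""
    cs = Wt.sum(axis=0)
    rs = Ws.sum(axis=1)
    dead_t = cs <= 0.0
    dead_s = rs <= 0.0
    if dead_t.any():
        Wt[:, dead_t] = 1.0 / Wt.shape[0]
        cs = np.where(dead_t, 1.0, cs)
    if dead_s.any():
        Ws[dead_s, :] = 1.0 / Ws.shape[1]
        rs = np.where(dead_s, 1.0, rs)
    Wt /= cs
    Ws /= rs[:, None]
    if compensate:
        d = np.where(dead_t, 0.0, cs)
        e = np.where(dead_s, 0.0, rs)
        A *= d[None, :, None] * e[None, None, :]
    return Wt, Ws, A


def _run_mult(X, lab, params, P, N, options, rng):
    S, T, M = X.shape
    eps = options.epsilon_guard
    compensate = not params.active
    Wt, Ws, A = _init_factors(rng, T, M, P, N, S)

    records = []
    prev = None
    converged = False
    n_iter = 0
    Q = np.matmul(Wt, A)  # stacked W_t A^s, kept in sync across iterations
    for it in range(options.max_iter):
        # spatial-module update (uses Q^s = W_t A^s)
        num_w = np.tensordot(Q, X, axes=([0, 1], [0, 1]))
        den_w = np.tensordot(Q, Q, axes=([0, 1], [0, 1])) @ Ws
        Ws = Ws * num_w / (den_w + eps)

        # temporal-module update (uses R^s = A^s W_s)
        R = np.matmul(A, Ws)
        num_t = np.tensordot(X, R, axes=([0, 2], [0, 2]))
        den_t = Wt @ np.tensordot(R, R, axes=([0, 2], [0, 2]))
        Wt = Wt * num_t / (den_t + eps)

        # unit-sum renormalization, once per outer iteration. It happens
        # before the coefficient update so the coefficients (not the
        # modules) carry the overall scale of the data: normalizing last
        # would let the module updates re-absorb the scale every iteration
        # and leave the feasible iterate systematically under-reconstructing.
        Wt, Ws, A = _normalize_inplace(Wt, Ws, A, compensate)

        # coefficient update (discrimination-aware)
        num_a, den_a = _coeff_num_den(X, Wt, Ws, A, lab, params)
        A = A * num_a / (den_a + eps)

        Q = np.matmul(Wt, A)
        resid = np.matmul(Q, Ws) - X
        e2_nmf = float(np.sum(resid * resid))
        tr_sw, tr_sb = _traces(A, lab) if lab is not None else (0.0, 0.0)
        e2 = e2_nmf + params.gamma * tr_sw - params.delta * tr_sb
        records.append((e2_nmf, tr_sw, tr_sb, e2))
        obj = e2 if params.active else e2_nmf
        n_iter = it + 1
        if prev is not None and abs(prev - obj) <= options.tol * max(abs(prev), 1e-30):
            converged = True
            break
        prev = obj
    return Wt, Ws, A, records, converged, n_iter


# ---------------------------------------------------------------------------
# ALS engine
# ---------------------------------------------------------------------------

def _kkt_solve(G, C, sum_axis_len, ridge_scale):
    """Solve min ||. - X G-form||^2 with unit-sum equality constraints via
    the lifted KKT system; returns the (possibly negative) unconstrained-
    sign solution X of shape C.shape.

    For the temporal step: G = sum_s R^s R^s.T (P x P), C = sum_s M^s R^s.T
    (T x P), constraint: each column of W_t sums to one.
    """
    T, P = C.shape
    top = np.kron(2.0 * G, np.eye(T))
    con = np.kron(np.eye(P), np.ones((T, 1)))
    kkt = np.block([[top, con], [con.T, np.zeros((P, P))]])
    rhs = np.concatenate([2.0 * C.ravel(order="F"), np.ones(P)])
    try:
        sol = scipy.linalg.solve(kkt, rhs)
        if not np.all(np.isfinite(sol)):
            raise scipy.linalg.LinAlgError("non-finite KKT solution")
    except (scipy.linalg.LinAlgError, ValueError):
        warnings.warn(
            "singular KKT system; re-solving with ridge stabilization",
            RuntimeWarning,
            stacklevel=2,
        )
        ridge = ridge_scale * max(np.trace(G) / max(P, 1), 1e-12)
        top = np.kron(2.0 * (G + ridge * np.eye(P)), np.eye(T))
        kkt = np.block([[top, con], [con.T, np.zeros((P, P))]])
        sol = scipy.linalg.lstsq(kkt, rhs)[0]
    return sol[: T * P].reshape((T, P), order="F")


def _qp_module_step(x0, G, C, n_rows):
    """Minimize f(X) = tr(X.T X G) - 2 tr(X.T C) (+const) over X >= 0 with
    unit sums along axis 0 of the (n_rows, k) matrix X; returns a feasible
    X no worse than x0 (which must be feasible)."""
    n, k = x0.shape

    def fun(v):
        Xm = v.reshape((n, k), order="F")
        return float(np.sum((Xm @ G) * Xm) - 2.0 * np.sum(Xm * C))

    def jac(v):
        Xm = v.reshape((n, k), order="F")
        return (2.0 * Xm @ G - 2.0 * C).ravel(order="F")

    Aeq = np.kron(np.eye(k), np.ones(n))

    res = scipy.optimize.minimize(
        fun,
        x0.ravel(order="F"),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, None)] * (n * k),
        constraints=[{"type": "eq", "fun": lambda v: Aeq @ v - 1.0, "jac": lambda v: Aeq}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    X = np.clip(res.x.reshape((n, k), order="F"), 0.0, None)
    X /= X.sum(axis=0, keepdims=True)
    # guard: keep the incumbent if the QP step did not improve
    if fun(X.ravel(order="F")) > fun(x0.ravel(order="F")):
        return x0
    return X


def _run_als(X, lab, params, P, N, options, rng, use_qp):
    S, T, M = X.shape
    eps = options.epsilon_guard
    Wt, Ws, A = _init_factors(rng, T, M, P, N, S)

    records = []
    prev = None
    converged = False
    n_iter = 0
    for it in range(options.max_iter):
        # temporal-module step: min sum_s ||M^s - W_t R^s||^2, columns sum to 1
        R = np.einsum("spn,nm->spm", A, Ws)
        G = np.einsum("spm,sqm->pq", R, R)
        C = np.einsum("stm,spm->tp", X, R)
        if use_qp:
            Wt = _qp_module_step(Wt, G, C, T)
        else:
            Wt = _kkt_solve(G, C, T, 1e-10)
            Wt = np.clip(Wt, 0.0, None)
            cs = Wt.sum(axis=0)
            dead = cs <= 0.0
            Wt[:, dead] = 1.0 / T
            Wt[:, ~dead] /= cs[~dead]

        # spatial-module step: min sum_s ||M^s - Q^s W_s||^2, rows sum to 1;
        # transposed problem has the same structure as the temporal step
        Q = np.einsum("tp,spn->stn", Wt, A)
        H = np.einsum("stn,stq->nq", Q, Q)
        D = np.einsum("stn,stm->nm", Q, X)
        if use_qp:
            Ws = _qp_module_step(Ws.T, H, D.T, M).T
        else:
            WsT = _kkt_solve(H, D.T, M, 1e-10)
            Ws = np.clip(WsT.T, 0.0, None)
            rs = Ws.sum(axis=1)
            dead = rs <= 0.0
            Ws[dead, :] = 1.0 / M
            Ws[~dead, :] /= rs[~dead, None]

        # coefficients keep the multiplicative rule
        num_a, den_a = _coeff_num_den(X, Wt, Ws, A, lab, params)
        A = A * num_a / (den_a + eps)

        e2_nmf, tr_sw, tr_sb, e2 = _objective(X, Wt, A, Ws, lab, params)
        records.append((e2_nmf, tr_sw, tr_sb, e2))
        obj = e2 if params.active else e2_nmf
        n_iter = it + 1
        if prev is not None and abs(prev - obj) <= options.tol * max(abs(prev), 1e-30):
            converged = True
            break
        prev = obj
    return Wt, Ws, A, records, converged, n_iter


# ---------------------------------------------------------------------------
# NLP engine
# ---------------------------------------------------------------------------

def _pack(Wt, A, Ws):
    S = A.shape[0]
    return np.concatenate(
        [Wt.ravel(order="F"), A.transpose(0, 2, 1).reshape(-1), Ws.ravel(order="F")]
    )


def _unpack(z, T, M, P, N, S):
    i1 = T * P
    i2 = i1 + S * P * N
    Wt = z[:i1].reshape((T, P), order="F")
    A = z[i1:i2].reshape(S, N, P).transpose(0, 2, 1)
    Ws = z[i2:].reshape((N, M), order="F")
    return Wt, A, Ws


def _constraint_matrix(T, M, P, N, S):
    """Linear map z -> (column sums of W_t, row sums of W_s)."""
    nz = T * P + S * P * N + N * M
    Aeq = np.zeros((P + N, nz))
    for j in range(P):
        Aeq[j, j * T : (j + 1) * T] = 1.0
    off = T * P + S * P * N
    for n in range(N):
        Aeq[P + n, off + n + N * np.arange(M)] = 1.0
    return Aeq


def _run_nlp(X, lab, params, P, N, options, rng):
    S, T, M = X.shape
    Wt0, Ws0, A0 = _init_factors(rng, T, M, P, N, S)
    lab_arr = lab.labels if lab is not None else None
    z0 = _pack(Wt0, A0, Ws0)
    Aeq = _constraint_matrix(T, M, P, N, S)
    beq = np.ones(P + N)

    def fun(z):
        Wt, A, Ws = _unpack(z, T, M, P, N, S)
        v, gWt, gA, gWs = e2_with_gradients(X, Wt, A, Ws, lab_arr, params)
        return v, _pack(gWt, gA, gWs)

    records = []
    if options.track_history:
        def cb(z):
            Wt, A, Ws = _unpack(z, T, M, P, N, S)
            records.append(_objective(X, np.clip(Wt, 0, None),
                                      np.clip(A, 0, None), np.clip(Ws, 0, None),
                                      lab, params))
    else:
        cb = None

    res = scipy.optimize.minimize(
        fun,
        z0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, None)] * len(z0),
        constraints=[{"type": "eq", "fun": lambda z: Aeq @ z - beq,
                      "jac": lambda z: Aeq}],
        callback=cb,
        options={"maxiter": options.max_iter, "ftol": 1e-12},
    )
    z = np.clip(res.x, 0.0, None)
    violation = float(np.max(np.abs(Aeq @ z - beq)))
    Wt, A, Ws = _unpack(z, T, M, P, N, S)
    records.append(_objective(X, Wt, A, Ws, lab, params))
    n_iter = len(records)
    return Wt, Ws, A, records, bool(res.success), n_iter, violation


# ---------------------------------------------------------------------------
# restart driver and public fit functions
# ---------------------------------------------------------------------------

def _fit(data, labels, P, N, params, options):
    S, T, M = data.dims
    if not (1 <= P <= T):
        raise ValueError(f"P must satisfy 1 <= P <= T (got P={P}, T={T})")
    if not (1 <= N <= M):
        raise ValueError(f"N must satisfy 1 <= N <= M (got N={N}, M={M})")
    if params.active and labels is None:
        raise ValueError("task labels required when gamma > 0 or delta > 0")
    lab = _label_info(labels, S) if labels is not None else None

    seeds = np.random.SeedSequence(options.seed).spawn(options.n_restarts)
    best = None
    restart_costs = []
    nlp_failures = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if options.solver == "mult":
            Wt, Ws, A, rec, conv, n_iter = _run_mult(
                data.data, lab, params, P, N, options, rng
            )
        elif options.solver in ("als", "als_qp"):
            Wt, Ws, A, rec, conv, n_iter = _run_als(
                data.data, lab, params, P, N, options, rng,
                use_qp=options.solver == "als_qp",
            )
        else:  # nlp
            Wt, Ws, A, rec, conv, n_iter, violation = _run_nlp(
                data.data, lab, params, P, N, options, rng
            )
            if violation >= 1e-6:
                nlp_failures.append((violation, Wt, Ws, A))
                restart_costs.append(float("nan"))
                continue
        e2_nmf, _, _, e2 = rec[-1]
        restart_costs.append(e2)
        key = (e2, e2_nmf, r)
        if best is None or key < best[0]:
            best = (key, Wt, Ws, A, rec, conv, n_iter, r)

    if best is None:
        viol, Wt, Ws, A = min(nlp_failures, key=lambda t: t[0])
        raise SolverError(
            f"all {options.n_restarts} NLP restarts violated the unit-sum "
            f"constraints (best violation {viol:.2e})",
            best_model=SpaceByTimeModel(Wt, Ws, np.clip(A, 0, None)),
        )

    _, Wt, Ws, A, rec, conv, n_iter, r = best
    model = SpaceByTimeModel(Wt, Ws, A)
    final_cost = total_cost(data, model, labels, params)
    return FitResult(
        model=model,
        history=FitHistory.from_records(rec) if options.track_history else None,
        converged=conv,
        n_iter=n_iter,
        restart_index=r,
        final_cost=final_cost,
        final_e_nmf=e_nmf(data, model),
        restart_costs=restart_costs,
    )


def fit_snm3f(data: EMGDataset, P: int, N: int, options: FitOptions | None = None) -> FitResult:
    """Unsupervised space-by-time decomposition (sNM3F): multiplicative
    updates minimizing E^2_NMF alone, with compensated unit-sum
    renormalization (E^2_NMF is non-increasing across iterations)."""
    options = replace(options or FitOptions(), solver="mult")
    return _fit(data, data.labels, P, N, DiscriminationParams(), options)


def fit_dsnm3f_mult(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    params: DiscriminationParams,
    options: FitOptions | None = None,
) -> FitResult:
    """Task-discriminative decomposition (DsNM3F) by multiplicative updates.

    With gamma = delta = 0 this is exactly :func:`fit_snm3f` (identical
    trajectory for the same seed)."""
    options = replace(options or FitOptions(), solver="mult")
    return _fit(data, labels, P, N, params, options)


def fit_dsnm3f_als(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    params: DiscriminationParams,
    options: FitOptions | None = None,
) -> FitResult:
    """DsNM3F with alternating constrained least-squares module updates.

    ``options.solver`` selects the KKT-with-clipping fast path (``"als"``,
    the default) or the non-negative QP variant (``"als_qp"``)."""
    options = options or FitOptions(solver="als")
    if options.solver not in ("als", "als_qp"):
        options = replace(options, solver="als")
    return _fit(data, labels, P, N, params, options)


def fit_dsnm3f_nlp(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    params: DiscriminationParams,
    options: FitOptions | None = None,
) -> FitResult:
    """DsNM3F as one joint constrained nonlinear program with analytic
    gradients."""
    options = replace(options or FitOptions(), solver="nlp")
    return _fit(data, labels, P, N, params, options)


def fit(
    data: EMGDataset,
    P: int,
    N: int,
    params: DiscriminationParams | None = None,
    labels=None,
    options: FitOptions | None = None,
) -> FitResult:
    """Dispatch on ``options.solver``; labels default to the dataset's."""
    params = params or DiscriminationParams()
    options = options or FitOptions()
    if labels is None:
        labels = data.labels
    return _fit(data, labels, P, N, params, options)


def project_onto_modules(
    data: EMGDataset,
    temporal_modules: np.ndarray,
    spatial_modules: np.ndarray,
    options: FitOptions | None = None,
) -> np.ndarray:
    """Non-negative coefficients of ``data`` on fixed modules, (S, P, N).

    Runs only the pure-reconstruction multiplicative coefficient update to
    convergence; no task information is used. This is how held-out trials
    are mapped into module space for generalization tests.
    """
    Wt = np.asarray(temporal_modules, dtype=float)
    Ws = np.asarray(spatial_modules, dtype=float)
    S, T, M = data.dims
    if Wt.shape[0] != T or Ws.shape[1] != M:
        raise ValueError(
            f"module shapes {Wt.shape}, {Ws.shape} inconsistent with data (T={T}, M={M})"
        )
    options = options or FitOptions(max_iter=50_000, tol=1e-14)
    rng = np.random.default_rng(np.random.SeedSequence(options.seed))
    A = rng.uniform(0.5, 1.5, size=(S, Wt.shape[1], Ws.shape[0]))
    params = DiscriminationParams()
    X = data.data
    # stopping is scaled to the data norm rather than the current error:
    # on noise-free data the error decays geometrically toward zero, so a
    # purely relative change criterion would never trigger
    scale = max(float(np.sum(X * X)), 1e-30)
    prev = None
    for _ in range(options.max_iter):
        num, den = _coeff_num_den(X, Wt, Ws, A, None, params)
        A = A * num / (den + options.epsilon_guard)
        resid = _recon(Wt, A, Ws) - X
        err = float(np.sum(resid * resid))
        if prev is not None and abs(prev - err) <= options.tol * scale:
            break
        prev = err
    return A
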