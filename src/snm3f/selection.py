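"""Tuning of the discrimination weights and of the model order.

The discrimination weights (gamma, delta) trade reconstruction against
task separation; they are tuned by maximizing VDM = VAF x DEC, first over
a coarse grid (log-spaced, including the pure-reconstruction cell (0, 0))
and then by a derivative-free local refinement in log10 space started at
the grid optimum. Fitting seeds are held fixed so the objective is
deterministic and the search reproducible.

The model order (P temporal, N spatial modules) is chosen by a
decoding-plateau rule: among all orders whose decoding is within a
tolerance of the best (default: one binomial standard error), take the
most compact one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .discrimination import DiscriminationParams
from .evaluation import lda_decode_loo, vdm
from .model import EMGDataset, vaf
from .solvers import FitOptions, fit

__all__ = [
    "GridCell",
    "GridSearchResult",
    "grid_search_gamma_delta",
    "refine_gamma_delta",
    "select_model_order",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_DELTA_GRID",
]

DEFAULT_GAMMA_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
DEFAULT_DELTA_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)

# floor used when log-scaling a weight whose start value is 0
_LOG_FLOOR = 1e-8


@dataclass
class GridCell:
    gamma: float
    delta: float
    vaf: float | None
    dec: float | None
    vdm: float | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "delta": self.delta,
            "vaf": self.vaf,
            "dec": self.dec,
            "vdm": self.vdm,
            "error": self.error,
        }


@dataclass
class GridSearchResult:
    grid: list  # GridCell records in evaluation order
    best: tuple  # (gamma, delta) attaining max vdm over the grid
    refined: tuple | None = None  # (gamma, delta) after local refinement
    refined_vdm: float | None = None

    @property
    def best_cell(self) -> GridCell:
        ok = [c for c in self.grid if c.vdm is not None]
        return max(ok, key=lambda c: c.vdm)

    def cell(self, gamma: float, delta: float) -> GridCell:
        for c in self.grid:
            if c.gamma == gamma and c.delta == delta:
                return c
        raise KeyError((gamma, delta))

    def to_dict(self) -> dict:
        return {
            "grid": [c.to_dict() for c in self.grid],
            "best": list(self.best),
            "refined": None if self.refined is None else list(self.refined),
            "refined_vdm": self.refined_vdm,
        }


def _evaluate_pair(data, labels, P, N, gamma, delta, fit_options, decoder):
    params = DiscriminationParams(gamma=gamma, delta=delta)
    result = fit(data, P, N, params=params, labels=labels, options=fit_options)
    v = vaf(data, result.model)
    dec = decoder(result.model.coefficients, labels)
    return v, dec, vdm(v, dec)


def grid_search_gamma_delta(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    gamma_grid=DEFAULT_GAMMA_GRID,
    delta_grid=DEFAULT_DELTA_GRID,
    fit_options: FitOptions | None = None,
    decoder=lda_decode_loo,
) -> GridSearchResult:
    """Evaluate VAF, DEC and VDM over a (gamma, delta) grid.

    Each cell fits the discriminative decomposition best-of-restarts with
    the same seeds, so the whole grid is reproducible. The (0, 0) cell,
    when present, is exactly the pure-reconstruction (sNM3F) result. A
    failed cell is recorded with its error and excluded from the argmax.
    """
    gamma_grid = list(gamma_grid)
    delta_grid = list(delta_grid)
    if not gamma_grid or not delta_grid:
        raise ValueError("grids must be non-empty")
    if any(g < 0 for g in gamma_grid) or any(d < 0 for d in delta_grid):
        raise ValueError("grid values must be non-negative")
    fit_options = fit_options or FitOptions(n_restarts=10)

    cells = []
    for g in gamma_grid:
        for d in delta_grid:
            try:
                v, dec, score = _evaluate_pair(
                    data, labels, P, N, g, d, fit_options, decoder
                )
                cells.append(GridCell(g, d, v, dec, score))
            except Exception as exc:  # pragma: no cover - defensive per-cell guard
                warnings.warn(
                    f"grid cell (gamma={g}, delta={d}) failed: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                cells.append(GridCell(g, d, None, None, None, error=str(exc)))
    ok = [c for c in cells if c.vdm is not None]
    if not ok:
        raise RuntimeError("every grid cell failed")
    best = max(ok, key=lambda c: c.vdm)
    return GridSearchResult(grid=cells, best=(best.gamma, best.delta))


def refine_gamma_delta(
    data: EMGDataset,
    labels,
    P: int,
    N: int,
    start: tuple,
    fit_options: FitOptions | None = None,
    decoder=lda_decode_loo,
    max_evals: int = 40,
) -> tuple:
    """Local derivative-free maximization of VDM(gamma, delta).

    Runs a Nelder-Mead simplex in log10 coordinates over the non-negative
    quadrant, started at the grid optimum (zeros floored at 1e-8). Fitting
    seeds are fixed, so the objective is deterministic. Returns
    ``(gamma, delta, vdm)`` with VDM never below the start's.
    """
    g0, d0 = start
    if g0 < 0 or d0 < 0:
        raise ValueError("start must be component-wise non-negative")
    fit_options = fit_options or FitOptions(n_restarts=10)

    def objective_log(x):
        g, d = 10.0 ** x[0], 10.0 ** x[1]
        _, _, score = _evaluate_pair(data, labels, P, N, g, d, fit_options, decoder)
        if not np.isfinite(score):
            raise RuntimeError(f"non-finite VDM at (gamma={g}, delta={d})")
        return -score

    _, _, start_vdm = _evaluate_pair(data, labels, P, N, g0, d0, fit_options, decoder)
    x0 = np.log10([max(g0, _LOG_FLOOR), max(d0, _LOG_FLOOR)])
    res = scipy.optimize.minimize(
        objective_log,
        x0,
        method="Nelder-Mead",
        options={"maxfev": max_evals, "xatol": 0.05, "fatol": 1e-4},
    )
    refined = (float(10.0 ** res.x[0]), float(10.0 ** res.x[1]))
    refined_vdm = -float(res.fun)
    if refined_vdm < start_vdm:  # keep the incumbent if the simplex drifted
        return (g0, d0, start_vdm)
    return (refined[0], refined[1], refined_vdm)


def select_model_order(
    data: EMGDataset,
    labels,
    P_range,
    N_range,
    fit_options: FitOptions | None = None,
    tolerance: float | None = None,
    params: DiscriminationParams | None = None,
    decoder=lda_decode_loo,
) -> tuple:
    """Most compact (P, N) whose decoding sits on the plateau of the best.

    Decoding (DEC) is computed for every order in ``P_range x N_range``;
    the selected pair is the one with the smallest P*N (ties: smallest
    P+N, then smallest P) among those with DEC >= max DEC - tolerance.
    The default tolerance is one binomial standard error of the maximal
    DEC at the dataset's trial count.
    """
    P_range = list(P_range)
    N_range = list(N_range)
    if not P_range or not N_range:
        raise ValueError("empty model-order range")
    S, T, M = data.dims
    if max(P_range) > T or max(N_range) > M:
        raise ValueError("model-order ranges must lie within [1, T] x [1, M]")
    fit_options = fit_options or FitOptions(n_restarts=10)
    params = params or DiscriminationParams()

    decs = {}
    for P in P_range:
        for N in N_range:
            result = fit(data, P, N, params=params, labels=labels, options=fit_options)
            decs[(P, N)] = decoder(result.model.coefficients, labels)
    best_dec = max(decs.values())
    if tolerance is None:
        tolerance = float(np.sqrt(max(best_dec * (1.0 - best_dec), 0.0) / S))
    admissible = [pn for pn, d in decs.items() if d >= best_dec - tolerance]
    return min(admissible, key=lambda pn: (pn[0] * pn[1], pn[0] + pn[1], pn[0]))
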