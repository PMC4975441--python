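"""Maximum-likelihood estimation: multi-start trust-region least squares.

Each start is minimized with a bound-constrained trust-region reflective
least-squares solver in log-parameter space.  Following common practice for
flat likelihood landscapes, termination is driven by the step-size
criterion (1e-6) with the objective-change criterion disabled; an iteration
cap bounds runtime.  Starts are drawn uniformly in log10 space within the
bounds from a seeded generator, so results are fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import IntegrationFailure
from .likelihood import PredictionError

__all__ = ["FitResult", "StartRecord", "fit", "multistart_fit", "FixedSubsetProblem"]

STEP_TOL = 1e-6
MAX_ITER = 1000


@dataclass
class StartRecord:
    start: np.ndarray
    theta: np.ndarray
    value: float
    converged: bool
    n_failures: int = 0


@dataclass
class FitResult:
    """Best fit plus the full multi-start record (sorted by final value)."""

    theta: np.ndarray
    value: float
    starts: list = field(default_factory=list)
    seed: int | None = None
    settings: dict = field(default_factory=dict)
    boundary_warnings: list = field(default_factory=list)

    @property
    def convergence_fraction(self) -> float:
        """Fraction of starts landing within 0.01 of the best value."""
        tol = self.settings.get("convergence_tol", 0.01)
        vals = np.array([s.value for s in self.starts])
        return float(np.mean(vals <= self.value + tol)) if len(vals) else 1.0


class FixedSubsetProblem:
    """A problem with some coordinates frozen (pattern refits, profiles)."""

    def __init__(self, inner, fixed: dict):
        self.inner = inner
        self.fixed = dict(fixed)  # joint index -> fixed value
        n = len(inner.coord_names())
        self.free_idx = [i for i in range(n) if i not in self.fixed]
        self._n = n

    def coord_names(self):
        names = self.inner.coord_names()
        return [names[i] for i in self.free_idx]

    @property
    def n_residuals(self):
        return self.inner.n_residuals

    def expand(self, theta_red) -> np.ndarray:
        full = np.empty(self._n)
        for i, v in self.fixed.items():
            full[i] = v
        full[self.free_idx] = theta_red
        return full

    def reduce(self, theta_full) -> np.ndarray:
        return np.asarray(theta_full)[self.free_idx]

    def bounds(self):
        lb, ub = self.inner.bounds()
        return lb[self.free_idx], ub[self.free_idx]

    def default_start(self):
        return self.reduce(self.inner.default_start())

    def has_free_sigmas(self):
        return self.inner.has_free_sigmas()

    def update_sigmas(self, theta_red):
        return self.inner.update_sigmas(self.expand(theta_red))

    def residuals_jac(self, theta_red, with_jac=True):
        r, J = self.inner.residuals_jac(self.expand(theta_red), with_jac)
        return (r, J[:, self.free_idx]) if with_jac else (r, None)

    def neg2loglik(self, theta_red):
        return self.inner.neg2loglik(self.expand(theta_red))


def _make_fun_jac(problem, fail_value=1e8):
    """Residual/Jacobian callbacks with a shared cache and failure guard.

    Trial points only need residuals (cheap simulation); the sensitivity-
    augmented system is integrated only when the optimizer requests the
    Jacobian at an accepted point.
    """
    n = problem.n_residuals
    ncol = len(problem.coord_names())
    cache = {"key": None, "r": None, "J": None}

    def evaluate(theta, need_jac):
        key = theta.tobytes()
        if key != cache["key"]:
            cache.update(key=key, r=None, J=None)
        if need_jac and cache["J"] is None:
            try:
                r, J = problem.residuals_jac(theta, with_jac=True)
            except (IntegrationFailure, PredictionError):
                r, J = np.full(n, fail_value), np.zeros((n, ncol))
            cache.update(r=r, J=J)
        elif not need_jac and cache["r"] is None:
            try:
                r, _ = problem.residuals_jac(theta, with_jac=False)
            except (IntegrationFailure, PredictionError):
                r = np.full(n, fail_value)
            cache.update(r=r)
        return cache["J"] if need_jac else cache["r"]

    return (lambda th: evaluate(th, False)), (lambda th: evaluate(th, True))


def fit(problem, start, max_iter: int = MAX_ITER, step_tol: float = STEP_TOL):
    """Single local optimization from ``start``; returns a StartRecord.

    Free sigma parameters are refreshed by their conditional ML values
    between least-squares passes until they stabilize.
    """
    lb, ub = problem.bounds()
    theta = np.clip(np.asarray(start, dtype=float), lb, ub)
    if theta.size == 0:  # fully determined (e.g. profiling the only parameter)
        return StartRecord(start=theta, theta=theta,
                           value=float(problem.neg2loglik(theta)), converged=True)
    fun, jac = _make_fun_jac(problem)
    record = None
    for _outer in range(8):
        res = least_squares(
            fun, theta, jac=jac, bounds=(lb, ub), method="trf",
            xtol=step_tol, ftol=None, gtol=None, max_nfev=max_iter,
        )
        theta = res.x
        if not problem.has_free_sigmas():
            break
        if problem.update_sigmas(theta) < 1e-6:
            break
        fun, jac = _make_fun_jac(problem)  # sigmas changed: drop cache
    try:
        value = problem.neg2loglik(theta)
    except (IntegrationFailure, PredictionError):
        value = np.inf
    return StartRecord(start=np.asarray(start, float), theta=theta,
                       value=float(value), converged=bool(res.status != 0))


def _boundary_check(problem, theta, tol=1e-6):
    lb, ub = problem.bounds()
    names = problem.coord_names()
    return [names[i] for i in range(len(theta))
            if theta[i] - lb[i] < tol or ub[i] - theta[i] < tol]


def multistart_fit(problem, n_starts: int, seed: int | None = None,
                   starts=None, max_iter: int = MAX_ITER,
                   enlarge_bounds: bool = False) -> FitResult:
    """Multi-start fit with uniform log-space start sampling.

    If the best estimate rests on a bound, a warning is recorded; with
    ``enlarge_bounds=True`` the affected bounds are widened by one decade
    and the best start is refit once.
    """
    lb, ub = problem.bounds()
    rng = np.random.default_rng(seed)
    if starts is None:
        starts = [lb + rng.uniform(size=len(lb)) * (ub - lb) for _ in range(n_starts)]
    records = [fit(problem, s, max_iter=max_iter) for s in starts]
    records.sort(key=lambda r: r.value)
    best = records[0]
    boundary = _boundary_check(problem, best.theta)
    if boundary and enlarge_bounds:
        for name in boundary:
            spec_idx = problem.coord_names().index(name)
            lb = lb.copy(); ub = ub.copy()
            lb[spec_idx] -= 1.0
            ub[spec_idx] += 1.0
        wide = _WidenedProblem(problem, lb, ub)
        redo = fit(wide, best.theta, max_iter=max_iter)
        if redo.value < best.value:
            records.insert(0, redo)
            best = redo
        boundary = _boundary_check(wide, best.theta)
    if boundary:
        warnings.warn(
            f"estimate at parameter-space boundary for: {boundary}", stacklevel=2
        )
    return FitResult(
        theta=best.theta, value=best.value, starts=records, seed=seed,
        settings={"n_starts": n_starts, "max_iter": max_iter,
                  "step_tol": STEP_TOL, "convergence_tol": 0.01},
        boundary_warnings=boundary,
    )


class _WidenedProblem:
    """Delegate with enlarged bounds (boundary-escape refits)."""

    def __init__(self, inner, lb, ub):
        self.inner = inner
        self._lb, self._ub = lb, ub

    def bounds(self):
        return self._lb, self._ub

    def __getattr__(self, item):
        return getattr(self.inner, item)
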