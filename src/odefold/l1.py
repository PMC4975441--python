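"""Joint two-cell-type estimation with L1-regularized fold-changes.

Cell type 1 is parameterized by ``p_i`` and cell type 2 by ``r_i * p_i``;
the log fold-changes ``d_i = log10 r_i`` of a designated testable subset of
M parameters are estimated jointly with everything else.  The constrained
objective is

    C = L_ct1 + L_ct2 + lambda * sum_i |d_i|

(L denoting -2 log-likelihood).  The penalized optimizer is an orthant-aware
Levenberg-Marquardt loop: proposed steps that would change the sign of a
fold-change are truncated so the coordinate lands exactly at zero, and a
coordinate resting at zero is released only when the magnitude of the
unpenalized likelihood gradient exceeds the penalty slope lambda
(subgradient condition).  Inactive fold-changes are therefore stored as
exact zeros (r_i = 1).

Scanning lambda over a log grid (default 49 points on [1e-4, 1e4]) with
warm starts yields the regularization path; each distinct specificity
pattern along the path is refit without regularization and compared to the
full model by a likelihood-ratio test (D = L_lambda - L_full against
chi2_{M-N, 1-alpha}); the parsimonious model is the pattern with the
fewest cell type-specific parameters that cannot be rejected.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve as lin_solve
from scipy.stats import chi2

from .model import IntegrationFailure, ModelConfigError, OdeModel
from .likelihood import DataSet, PredictionError, Problem
from .estimation import FitResult, FixedSubsetProblem, fit, multistart_fit

__all__ = [
    "JointProblem",
    "RegularizationPath",
    "Selection",
    "penalty_value",
    "penalized_fit",
    "scan_path",
    "select_parsimonious",
    "count_specific",
    "exhaustive_selection_oracle",
    "default_lambda_grid",
    "lrt_threshold",
]

D_BOUND = 4.0  # |log10 r| bound for fold-change coordinates


def default_lambda_grid(n: int = 49, lo: float = 1e-4, hi: float = 1e4) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def lrt_threshold(dof: int, alpha: float = 0.05) -> float:
    """chi2 quantile used by the likelihood-ratio model selection."""
    if dof == 0:
        return 0.0
    return float(chi2.ppf(1.0 - alpha, dof))


def penalty_value(d, lam: float) -> float:
    """lambda * sum_i |log10 r_i|; exactly zero whenever all r_i = 1."""
    return float(lam * np.sum(np.abs(d)))


def count_specific(d, tol: float = 1e-6) -> int:
    """Number of cell type-specific parameters (|d_i| above numerical dust)."""
    return int(np.sum(np.abs(np.asarray(d)) > tol))


def _specialize(model: OdeModel, fixed_specific: dict, which: int) -> OdeModel:
    """Model copy with cell-type-specific fixed quantities pinned."""
    params = []
    for p in model.params:
        if p.name in fixed_specific:
            params.append(dataclasses.replace(
                p, value=float(fixed_specific[p.name][which]), fixed=True))
        else:
            params.append(dataclasses.replace(p))
    return OdeModel(
        name=f"{model.name}_ct{which + 1}",
        states=list(model.states), params=params, odes=dict(model.odes),
        rates=dict(model.rates), x0=dict(model.x0), inputs=list(model.inputs),
        observables=list(model.observables), conditions=list(model.conditions),
    )


class JointProblem:
    """Two cell types coupled by fold-changes over a shared parameter vector.

    Free vector layout: shared model parameters (cell type 1 values, on
    their estimation scales), then d = log10 fold-changes of the testable
    parameters, then cell-type-local observation parameters of each cell
    type.  Error parameters are cell-type-local and handled by the
    profile-sigma scheme; they are never testable or penalized.
    """

    def __init__(self, model: OdeModel, dataset_ct1: DataSet, dataset_ct2: DataSet,
                 testable: list, fixed_specific: dict | None = None,
                 rtol: float = 1e-6, atol: float = 1e-6):
        fixed_specific = fixed_specific or {}
        overlap = set(testable) & set(fixed_specific)
        if overlap:
            raise ModelConfigError(
                f"testable and fixed_specific overlap: {sorted(overlap)}")
        names = model.param_names()
        for t in testable:
            if t not in names:
                raise ModelConfigError(f"testable parameter {t!r} not in model")
            spec = model.param(t)
            if spec.fixed:
                raise ModelConfigError(f"testable parameter {t!r} is fixed")
            if spec.scale != "log10":
                raise ModelConfigError(
                    f"testable parameter {t!r} must be log10-scaled")
        self.model = model
        self.testable = list(testable)
        self.fixed_specific = fixed_specific
        self.p1 = Problem(_specialize(model, fixed_specific, 0), dataset_ct1,
                          rtol=rtol, atol=atol)
        self.p2 = Problem(_specialize(model, fixed_specific, 1), dataset_ct2,
                          rtol=rtol, atol=atol)
        # joint layout
        self.shared = [p.name for p in self.p1.free
                       if p.role in ("kinetic", "initial_concentration")]
        self.local1 = [p.name for p in self.p1.free if p.name not in self.shared]
        self.local2 = [p.name for p in self.p2.free if p.name not in self.shared]
        self._names = (
            self.shared
            + [f"d_{t}" for t in self.testable]
            + [f"ct1_{n}" for n in self.local1]
            + [f"ct2_{n}" for n in self.local2]
        )
        ns, m = len(self.shared), len(self.testable)
        self._d_slice = slice(ns, ns + m)
        self._l1_slice = slice(ns + m, ns + m + len(self.local1))
        self._l2_slice = slice(ns + m + len(self.local1), len(self._names))
        # column maps: sub-problem free index -> joint column(s)
        self._map1 = [self._names.index(n) if n in self.shared
                      else self._names.index(f"ct1_{n}")
                      for n in self.p1.free_names]
        self._map2 = [self._names.index(n) if n in self.shared
                      else self._names.index(f"ct2_{n}")
                      for n in self.p2.free_names]
        self._d_cols = {n: ns + i for i, n in enumerate(self.testable)}

    # -- protocol --------------------------------------------------------
    def coord_names(self) -> list:
        return list(self._names)

    @property
    def n_params(self) -> int:
        return len(self._names)

    @property
    def M(self) -> int:
        return len(self.testable)

    @property
    def n_residuals(self) -> int:
        return self.p1.n_residuals + self.p2.n_residuals

    def d_indices(self) -> np.ndarray:
        return np.arange(self._d_slice.start, self._d_slice.stop)

    def bounds(self):
        lb = np.empty(self.n_params)
        ub = np.empty(self.n_params)
        for j, name in enumerate(self._names):
            if name.startswith("d_") and name[2:] in self.testable:
                lb[j], ub[j] = -D_BOUND, D_BOUND
            else:
                raw = name.split("_", 1)[1] if name.startswith(("ct1_", "ct2_")) else name
                spec = self.model.param(raw)
                lb[j], ub[j] = spec.lower, spec.upper
        return lb, ub

    def default_start(self) -> np.ndarray:
        theta = np.zeros(self.n_params)
        for j, name in enumerate(self._names):
            if name.startswith("d_"):
                theta[j] = 0.0
            else:
                raw = name.split("_", 1)[1] if name.startswith(("ct1_", "ct2_")) else name
                spec = self.model.param(raw)
                theta[j] = spec.to_scale(spec.value)
        return theta

    def split(self, theta):
        """(theta_ct1, theta_ct2) sub-problem vectors from the joint vector."""
        theta = np.asarray(theta, dtype=float)
        t1 = theta[self._map1]
        t2 = theta[self._map2].copy()
        for i, name in enumerate(self.p2.free_names):
            if name in self._d_cols:
                t2[i] += theta[self._d_cols[name]]
        return t1, t2

    def d_values(self, theta) -> np.ndarray:
        return np.asarray(theta)[self._d_slice]

    def has_free_sigmas(self) -> bool:
        return self.p1.has_free_sigmas() or self.p2.has_free_sigmas()

    def update_sigmas(self, theta) -> float:
        t1, t2 = self.split(theta)
        return max(self.p1.update_sigmas(t1), self.p2.update_sigmas(t2))

    def residuals_jac(self, theta, with_jac=True):
        t1, t2 = self.split(theta)
        r1, J1 = self.p1.residuals_jac(t1, with_jac)
        r2, J2 = self.p2.residuals_jac(t2, with_jac)
        r = np.concatenate([r1, r2])
        if not with_jac:
            return r, None
        J = np.zeros((r.size, self.n_params))
        for j, col in enumerate(self._map1):
            J[: r1.size, col] += J1[:, j]
        for j, (col, name) in enumerate(zip(self._map2, self.p2.free_names)):
            J[r1.size:, col] += J2[:, j]
            if name in self._d_cols:
                J[r1.size:, self._d_cols[name]] += J2[:, j]
        return r, J

    def neg2loglik(self, theta) -> float:
        t1, t2 = self.split(theta)
        return self.p1.neg2loglik(t1) + self.p2.neg2loglik(t2)

    def objective(self, theta, lam: float) -> float:
        """Constrained objective C = L1 + L2 + lambda * sum |d|."""
        return self.neg2loglik(theta) + penalty_value(self.d_values(theta), lam)

    def pattern_problem(self, pattern) -> FixedSubsetProblem:
        """Joint problem with d_i frozen at 0 for parameters outside ``pattern``."""
        fixed = {self._d_cols[t]: 0.0 for t in self.testable if t not in pattern}
        return FixedSubsetProblem(self, fixed)


def build_joint_problem(model, dataset_ct1, dataset_ct2, testable,
                        fixed_specific=None, **kw) -> JointProblem:
    """Couple two cell types through fold-changes on the testable parameters."""
    return JointProblem(model, dataset_ct1, dataset_ct2, testable,
                        fixed_specific, **kw)


# ---------------------------------------------------------------------------
# penalized optimization (orthant-aware Levenberg-Marquardt)
# ---------------------------------------------------------------------------


@dataclass
class PenalizedFit:
    theta: np.ndarray
    objective: float  # C = -2logL + penalty
    neg2loglik: float
    lam: float
    converged: bool
    n_iter: int


def penalized_fit(joint: JointProblem, lam: float, start,
                  max_iter: int = 300, step_tol: float = 1e-6) -> PenalizedFit:
    """Minimize C = L1 + L2 + lambda * sum |d_i| from ``start``.

    Sign changes of fold-change coordinates are truncated to an exact zero;
    zero coordinates stay frozen unless the unpenalized gradient magnitude
    exceeds lambda.  With lambda = 0 this reduces to the plain joint fit.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0.0:
        rec = fit(joint, start)
        return PenalizedFit(rec.theta, rec.value, rec.value, 0.0,
                            rec.converged, 0)
    lb, ub = joint.bounds()
    theta = np.clip(np.asarray(start, dtype=float), lb, ub)
    d_idx = joint.d_indices()
    d_set = set(int(i) for i in d_idx)
    n = joint.n_params

    def objective(th):
        return joint.neg2loglik(th) + penalty_value(th[d_idx], lam)

    try:
        r, J = joint.residuals_jac(theta)
    except (IntegrationFailure, PredictionError):
        return PenalizedFit(theta, np.inf, np.inf, lam, False, 0)
    C = objective(theta)
    mu = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = 2.0 * (J.T @ r)
        s = np.zeros(n)
        free = np.ones(n, dtype=bool)
        for i in d_idx:
            if theta[i] != 0.0:
                s[i] = np.sign(theta[i])
            elif abs(g[i]) > lam:
                s[i] = -np.sign(g[i])  # release against the gradient
            else:
                free[i] = False  # penalty dominates: derivative zeroed
        idx = np.nonzero(free)[0]
        Jf = J[:, idx]
        gf = g[idx] + lam * s[idx]
        H = 2.0 * (Jf.T @ Jf)
        diag = np.maximum(np.diag(H), 1e-8)
        accepted = False
        for _damp in range(30):
            A = H + mu * np.diag(diag)
            try:
                dx = lin_solve(A, -gf, assume_a="sym")
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            cand = theta.copy()
            cand[idx] += dx
            # zero-crossing truncation: d_i may not change sign in one step
            for i in d_idx:
                if free[i] and s[i] != 0.0 and cand[i] * s[i] < 0.0:
                    cand[i] = 0.0
            np.clip(cand, lb, ub, out=cand)
            try:
                C_new = objective(cand)
            except (IntegrationFailure, PredictionError):
                C_new = np.inf
            if C_new < C:
                step = np.max(np.abs(cand - theta))
                theta, C = cand, C_new
                mu = max(mu / 3.0, 1e-12)
                accepted = True
                break
            mu *= 4.0
        if not accepted:
            converged = True  # no descent direction left at this damping
            break
        if step < step_tol:
            converged = True
            break
        try:
            r, J = joint.residuals_jac(theta)
        except (IntegrationFailure, PredictionError):
            break
    return PenalizedFit(theta, float(C), float(joint.neg2loglik(theta)),
                        lam, converged, it)


# ---------------------------------------------------------------------------
# regularization path and parsimonious selection
# ---------------------------------------------------------------------------


@dataclass
class RegularizationPath:
    """Per-lambda estimates along the scan (raw values retained)."""

    lambdas: np.ndarray
    d_names: list
    d_matrix: np.ndarray        # (n_lambda, M)
    objective: np.ndarray       # constrained C per lambda
    neg2loglik: np.ndarray      # unpenalized joint -2 log L per lambda
    n_specific: np.ndarray      # N per lambda
    thetas: np.ndarray          # (n_lambda, n_params)
    base_fit: FitResult | None = None
    failures: list = field(default_factory=list)

    def patterns(self) -> list:
        """Distinct specificity patterns in scan order."""
        seen = []
        for row in self.d_matrix:
            pat = tuple(n for n, v in zip(self.d_names, row) if abs(v) > 1e-6)
            if pat not in seen:
                seen.append(pat)
        return seen


def _base_joint_fit(joint: JointProblem, seed=None, n_starts: int = 2,
                    individual_init: bool = True, n_starts_individual: int = 3,
                    ) -> FitResult:
    """Unpenalized full joint fit (all d free, lambda = 0).

    The default strategy mirrors the study design: estimate each cell type
    individually first, combine the estimates (d = difference of log10
    values on testable parameters) as one start, and add random multi-starts
    up to ``n_starts`` joint starts in total.
    """
    rng = np.random.default_rng(seed)
    lb, ub = joint.bounds()
    starts = []
    if individual_init:
        f1 = multistart_fit(joint.p1, n_starts_individual, seed=int(rng.integers(2**31)))
        f2 = multistart_fit(joint.p2, n_starts_individual, seed=int(rng.integers(2**31)))
        theta = joint.default_start()
        names = joint.coord_names()
        for j, n in enumerate(joint.p1.free_names):
            if n in joint.shared:
                theta[names.index(n)] = f1.theta[j]
            else:
                theta[names.index(f"ct1_{n}")] = f1.theta[j]
        for j, n in enumerate(joint.p2.free_names):
            if n in joint.testable:
                theta[names.index(f"d_{n}")] = f2.theta[j] - theta[names.index(n)]
            elif n not in joint.shared:
                theta[names.index(f"ct2_{n}")] = f2.theta[j]
        starts.append(np.clip(theta, lb, ub))
    for _ in range(max(n_starts - len(starts), 0)):
        starts.append(lb + rng.uniform(size=len(lb)) * (ub - lb))
    return multistart_fit(joint, len(starts), seed=seed, starts=starts)


def scan_path(joint: JointProblem, lam_grid=None, base_fit: FitResult | None = None,
              seed=None, n_starts: int = 10) -> RegularizationPath:
    """Scan lambda ascending with warm starts; records the full path.

    A fit that fails (or is beaten by a cold restart from the lambda = 0
    solution by more than re-optimization noise) is retried from the
    unpenalized solution; persistent failures are recorded and the scan
    continues.
    """
    lam_grid = default_lambda_grid() if lam_grid is None else np.asarray(lam_grid, float)
    if np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lambda grid must be sorted ascending")
    if base_fit is None:
        base_fit = _base_joint_fit(joint, seed=seed, n_starts=n_starts)
    theta_warm = base_fit.theta.copy()
    M = joint.M
    nlam = lam_grid.size
    d_mat = np.zeros((nlam, M))
    obj = np.full(nlam, np.nan)
    n2ll = np.full(nlam, np.nan)
    nspec = np.zeros(nlam, dtype=int)
    thetas = np.zeros((nlam, joint.n_params))
    failures = []
    for k, lam in enumerate(lam_grid):
        res = penalized_fit(joint, lam, theta_warm)
        if not np.isfinite(res.objective):
            res = penalized_fit(joint, lam, base_fit.theta)
        if not np.isfinite(res.objective):
            failures.append((k, float(lam)))
            thetas[k] = theta_warm
            continue
        theta_warm = res.theta.copy()
        d = joint.d_values(res.theta)
        d_mat[k] = d
        obj[k] = res.objective
        n2ll[k] = res.neg2loglik
        nspec[k] = count_specific(d)
        thetas[k] = res.theta
    return RegularizationPath(
        lambdas=lam_grid, d_names=list(joint.testable), d_matrix=d_mat,
        objective=obj, neg2loglik=n2ll, n_specific=nspec, thetas=thetas,
        base_fit=base_fit, failures=failures,
    )


@dataclass
class Selection:
    """Parsimonious specificity pattern with its unregularized refit."""

    pattern: tuple
    N: int
    M: int
    D: float
    threshold: float
    alpha: float
    theta: np.ndarray            # full joint vector of the refit
    neg2loglik: float
    full_neg2loglik: float
    fold_changes: dict           # name -> {"d": ..., "fold": ...}
    tested: list = field(default_factory=list)  # (pattern, N, D, threshold, passed)
    full_model_fallback: bool = False
    tie_patterns: list = field(default_factory=list)


def _refit_pattern(joint: JointProblem, pattern, warm_theta,
                   max_iter: int = 1000):
    """Unregularized refit with d free on ``pattern`` only; returns (theta, value)."""
    sub = joint.pattern_problem(pattern)
    start = sub.reduce(warm_theta)
    rec = fit(sub, start, max_iter=max_iter)
    return sub.expand(rec.theta), rec.value


def _selection_from(joint, pattern, theta, value, full_value, alpha, tested,
                    fallback=False, ties=()):
    d = joint.d_values(theta)
    folds = {}
    for name, di in zip(joint.testable, d):
        folds[name] = {"d": float(di), "fold": float(10.0 ** di)}
    N = len(pattern)
    return Selection(
        pattern=tuple(pattern), N=N, M=joint.M,
        D=float(max(value - full_value, 0.0)),
        threshold=lrt_threshold(joint.M - N, alpha), alpha=alpha,
        theta=theta, neg2loglik=float(value), full_neg2loglik=float(full_value),
        fold_changes=folds, tested=tested, full_model_fallback=fallback,
        tie_patterns=list(ties),
    )


def _swap_neighbors(pattern, testable):
    """Same-size patterns differing by one member (collinearity guard)."""
    out = []
    for drop in pattern:
        for add in testable:
            if add not in pattern:
                out.append(tuple(sorted(set(pattern) - {drop} | {add})))
    return out


def select_parsimonious(path: RegularizationPath, joint: JointProblem,
                        alpha: float = 0.05, refine: bool | None = None) -> Selection:
    """Likelihood-ratio selection of the parsimonious specificity pattern.

    Each distinct pattern along the path is refit without regularization
    (non-selected d_i frozen at exactly 0); the chosen pattern is the one
    with the smallest N whose refit satisfies D < chi2_{M-N, 1-alpha}.
    Several same-N candidates are compared by their D and the smallest
    wins.  With ``refine`` (default on for M <= 8) the candidate set at
    each N additionally contains the one-swap neighborhood of the path
    patterns of that size: correlated parameter pairs can trade places on
    an L1 path, and the likelihood-ratio comparison — not the penalized
    objective — is the arbiter the procedure trusts.
    """
    if refine is None:
        refine = joint.M <= 8
    full_value = path.base_fit.value
    cands = path.patterns()
    if tuple(joint.testable) not in cands:
        cands.insert(0, tuple(joint.testable))
    if () not in cands:
        cands.append(())
    by_n = {}
    for pat in cands:
        by_n.setdefault(len(pat), set()).add(tuple(sorted(pat)))
    if refine:
        for pat in cands:
            for nb in _swap_neighbors(pat, joint.testable):
                by_n[len(nb)].add(nb)
    # warm starts: the path point where each pattern first appeared
    warm = {}
    for k in range(path.lambdas.size):
        pat = tuple(sorted(n for n, v in zip(path.d_names, path.d_matrix[k])
                           if abs(v) > 1e-6))
        warm.setdefault(pat, path.thetas[k])
    warm[tuple(sorted(joint.testable))] = path.base_fit.theta
    d_idx = joint.d_indices()

    def refit(pat):
        w = warm.get(pat, path.base_fit.theta).copy()
        for i, name in zip(d_idx, joint.testable):
            if name not in pat:
                w[i] = 0.0
        return _refit_pattern(joint, pat, w)

    tested = []
    results = {}
    for n in sorted(by_n):
        thr = lrt_threshold(joint.M - n, alpha)
        passing = []
        for pat in sorted(by_n[n]):
            theta, value = refit(pat)
            D = max(value - full_value, 0.0)
            passed = D < thr or n == joint.M
            tested.append((pat, n, float(D), float(thr), bool(passed)))
            results[pat] = (theta, value)
            if passed:
                passing.append((D, pat))
        if passing:
            passing.sort(key=lambda t: (t[0], t[1]))
            best_D, best_pat = passing[0]
            ties = [p for _, p in passing] if len(passing) > 1 else ()
            theta, value = results[best_pat]
            return _selection_from(joint, best_pat, theta, value, full_value,
                                   alpha, tested, ties=ties)
    # nothing passed: fall back to the full model, flagged
    pat = tuple(sorted(joint.testable))
    theta, value = results.get(pat) or refit(pat)
    warnings.warn("no reduced pattern passed the LRT; returning the full model")
    return _selection_from(joint, pat, theta, value, full_value, alpha,
                           tested, fallback=True)


def exhaustive_selection_oracle(joint: JointProblem, alpha: float = 0.05,
                                base_fit: FitResult | None = None,
                                max_M: int = 8) -> Selection:
    """Brute-force selection over all 2^M specificity patterns (small M only).

    Fits every pattern unregularized and returns the minimal-N pattern(s)
    passing the LRT against the full model; ties broken by smaller D.
    Serves as the independent oracle for the L1 path procedure.
    """
    if joint.M > max_M:
        raise ValueError(f"exhaustive enumeration refused for M = {joint.M} > {max_M}")
    if base_fit is None:
        base_fit = _base_joint_fit(joint)
    full_value = base_fit.value
    tested = []
    results = {}
    by_n = {}
    for r in range(joint.M + 1):
        for combo in itertools.combinations(joint.testable, r):
            w = base_fit.theta.copy()
            for i, name in zip(joint.d_indices(), joint.testable):
                if name not in combo:
                    w[i] = 0.0
            theta, value = _refit_pattern(joint, combo, w)
            D = max(value - full_value, 0.0)
            thr = lrt_threshold(joint.M - r, alpha)
            passed = D < thr or r == joint.M
            tested.append((combo, r, float(D), float(thr), bool(passed)))
            results[combo] = (theta, value)
            if passed:
                by_n.setdefault(r, []).append((D, combo))
        if r in by_n:
            break
    n_min = min(by_n)
    winners = sorted(by_n[n_min])
    best_D, best_pat = winners[0]
    theta, value = results[best_pat]
    ties = [p for _, p in winners] if len(winners) > 1 else ()
    return _selection_from(joint, best_pat, theta, value, full_value, alpha,
                           tested, ties=ties)
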