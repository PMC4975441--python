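"""Observation mapping, error models, and -2 log-likelihood.

Trajectories are mapped to observations through ``y_hat = scale * expr(x) +
offset`` with optional log transform; intensity-based measurements (immuno-
blot, qRT-PCR) use a log-normal error model realized as additive Gaussian
noise on log-transformed values, degree-of-phosphorylation data a constant
error model.  One noise parameter is assigned per (technique, observable,
cell type); the mass-spectrometry degree-of-phosphorylation sigma is bounded
above by 0.05.

The value contract for the objective is

    -2 log L = sum_records [ (y - y_hat)^2 / sigma_eff^2 + log(2 pi sigma_eff^2) ]

with residuals formed on log values for the log-normal kind (sigma on that
scale).  The data-only constant of the log-normal density is dropped; it
cancels in every likelihood difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp

from .model import LN10, ModelConfigError, simulate

__all__ = [
    "ObservableSpec",
    "ErrorModel",
    "DataSet",
    "DataError",
    "PredictionError",
    "Problem",
    "predict_observations",
    "neg2loglik",
    "residual_vector",
]

DATA_COLUMNS = ["cell_type", "condition", "observable", "time_min", "value", "replicate"]

_LOG_FLOOR = 1e-10  # positivity floor for predictions under log-scale errors


class DataError(ValueError):
    """Invalid observation table or error-model assignment."""


class PredictionError(RuntimeError):
    """Observation evaluation failure (e.g. log of a non-positive prediction)."""

    def __init__(self, message, records=None):
        super().__init__(message)
        self.records = records


@dataclass
class ObservableSpec:
    """Observation function: ``transform(scale * expr(states) + offset)``."""

    name: str
    expr: str
    scale_param: str | None = None
    offset_param: str | None = None
    transform: str = "linear"  # linear | log

    def __post_init__(self):
        if self.transform not in ("linear", "log"):
            raise ModelConfigError(f"unknown transform {self.transform!r}")
        self._cache = {}

    def compiled(self, state_names):
        key = tuple(state_names)
        if key not in self._cache:
            xs = [sp.Symbol(s) for s in state_names]
            e = sp.sympify(self.expr)
            for s in e.free_symbols:
                if str(s) not in state_names:
                    raise ModelConfigError(
                        f"observable {self.name}: unknown state {s}"
                    )
            grad = [sp.diff(e, x) for x in xs]
            self._cache[key] = (
                sp.lambdify([xs], e, modules="numpy"),
                sp.lambdify([xs], grad, modules="numpy"),
            )
        return self._cache[key]


@dataclass
class ErrorModel:
    """Noise model for one observable: constant or log-normal-relative."""

    kind: str  # constant | lognormal_relative
    sigma_param: str

    def __post_init__(self):
        if self.kind not in ("constant", "lognormal_relative"):
            raise ModelConfigError(f"unknown error model kind {self.kind!r}")


class DataSet:
    """Time-course observation records plus per-observable error models.

    Records keep their original order; predictions are always aligned to it.
    """

    def __init__(self, df: pd.DataFrame, error_models: dict):
        missing = [c for c in DATA_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        if df[["time_min", "value"]].isna().any().any():
            raise DataError("missing time/value entries are not allowed")
        self.df = df.reset_index(drop=True)
        self.error_models = dict(error_models)
        for obs in self.df["observable"].unique():
            if obs not in self.error_models:
                raise DataError(f"no error model assigned for observable {obs!r}")

    def __len__(self):
        return len(self.df)

    def for_cell_type(self, cell_type: str) -> "DataSet":
        sub = self.df[self.df["cell_type"] == cell_type]
        if sub.empty:
            raise DataError(f"no records for cell type {cell_type!r}")
        ems = {o: self.error_models[o] for o in sub["observable"].unique()}
        return DataSet(sub, ems)

    def cell_types(self) -> list:
        return list(dict.fromkeys(self.df["cell_type"]))

    def validate_against(self, model) -> None:
        obs_names = {o.name for o in model.observables}
        cond_names = {c.name for c in model.conditions}
        for i, rec in self.df.iterrows():
            if rec["observable"] not in obs_names:
                raise DataError(f"record {i}: unknown observable {rec['observable']!r}")
            if rec["condition"] not in cond_names:
                raise DataError(f"record {i}: unknown condition {rec['condition']!r}")
            em = self.error_models[rec["observable"]]
            if em.kind == "lognormal_relative" and rec["value"] <= 0:
                raise DataError(
                    f"record {i}: non-positive value {rec['value']} for "
                    f"log-normal observable {rec['observable']!r}"
                )


# ---------------------------------------------------------------------------


class Problem:
    """One model + one cell type's data, ready for least-squares estimation.

    The free vector ``theta`` covers all non-fixed parameters except error
    (sigma) parameters, each on its estimation scale; free sigmas are
    updated by their closed-form conditional maximum-likelihood values
    between least-squares passes (profile-sigma scheme).
    """

    def __init__(self, model, dataset: DataSet, rtol: float = 1e-6, atol: float = 1e-6):
        dataset.validate_against(model)
        if len(dataset.cell_types()) > 1:
            raise DataError("Problem handles a single cell type; split the dataset")
        self.model = model
        self.dataset = dataset
        self.rtol, self.atol = rtol, atol
        self.free = [p for p in model.params if not p.fixed and p.role != "error"]
        self.free_names = [p.name for p in self.free]
        self.sigma_free = [p for p in model.params if not p.fixed and p.role == "error"]
        self._p_base = model.default_values()
        self._names = model.param_names()
        self._free_idx = [self._names.index(n) for n in self.free_names]
        # per-condition evaluation blocks and per-observable record masks
        df = dataset.df
        self._blocks = []
        for cond_name in dict.fromkeys(df["condition"]):
            sub = df[df["condition"] == cond_name]
            times = np.unique(sub["time_min"].to_numpy(dtype=float))
            groups = []
            for obs_name in dict.fromkeys(sub["observable"]):
                osub = sub[sub["observable"] == obs_name]
                rec_idx = osub.index.to_numpy()
                t_idx = np.searchsorted(times, osub["time_min"].to_numpy(dtype=float))
                groups.append((model.observable(obs_name), rec_idx, t_idx,
                               osub["value"].to_numpy(dtype=float)))
            self._blocks.append((model.condition(cond_name), times, groups))
        self._y = df["value"].to_numpy(dtype=float)
        self._obs_masks = [
            (obs_name, (df["observable"] == obs_name).to_numpy())
            for obs_name in dict.fromkeys(df["observable"])
        ]

    # -- protocol --------------------------------------------------------
    @property
    def n_residuals(self) -> int:
        return len(self.dataset)

    def coord_names(self) -> list:
        return list(self.free_names)

    def bounds(self):
        lb = np.array([p.lower for p in self.free])
        ub = np.array([p.upper for p in self.free])
        return lb, ub

    def default_start(self) -> np.ndarray:
        return np.array([p.to_scale(p.value) for p in self.free])

    def has_free_sigmas(self) -> bool:
        return bool(self.sigma_free)

    def natural_params(self, theta) -> np.ndarray:
        p = self._p_base.copy()
        for j, (i, spec) in enumerate(zip(self._free_idx, self.free)):
            p[i] = spec.to_natural(theta[j])
        return p

    def _sigma_value(self, em) -> float:
        return self._p_base[self._names.index(em.sigma_param)]

    def set_sigma(self, name: str, value: float) -> None:
        self._p_base[self._names.index(name)] = value

    # -- evaluation ------------------------------------------------------
    def _predict_blocks(self, theta, with_jac):
        p = self.natural_params(theta)
        n = len(self.dataset)
        yhat = np.empty(n)
        raws = np.empty(n)
        jac = np.empty((n, len(self.free))) if with_jac else None
        for cond, times, groups in self._blocks:
            traj = simulate(
                self.model, p, cond, times, rtol=self.rtol, atol=self.atol,
                sens_params=self.free_names if with_jac else None,
            )
            for obs, rec_idx, t_idx, _y in groups:
                fval, fgrad = obs.compiled(self.model.states)
                xs = [traj.states[:, j] for j in range(traj.states.shape[1])]
                raw = np.asarray(fval(xs), dtype=float) * np.ones(times.size)
                scale = (p[self._names.index(obs.scale_param)]
                         if obs.scale_param else 1.0)
                offset = (p[self._names.index(obs.offset_param)]
                          if obs.offset_param else 0.0)
                y = scale * raw + offset
                yhat[rec_idx] = y[t_idx]
                raws[rec_idx] = raw[t_idx]
                if with_jac:
                    g_list = fgrad(xs)
                    G = np.zeros((times.size, len(self.free)))
                    for s_i, g_s in enumerate(g_list):
                        g_s = np.asarray(g_s, dtype=float)
                        if np.all(g_s == 0):
                            continue
                        G += (g_s * np.ones(times.size))[:, None] * traj.sens[:, s_i, :]
                    J = scale * G
                    if obs.scale_param in self.free_names:
                        j = self.free_names.index(obs.scale_param)
                        spec = self.free[j]
                        dscale = LN10 * scale if spec.scale == "log10" else 1.0
                        J[:, j] += dscale * raw
                    if obs.offset_param in self.free_names:
                        j = self.free_names.index(obs.offset_param)
                        spec = self.free[j]
                        doff = (LN10 * offset if spec.scale == "log10" else 1.0)
                        J[:, j] += doff
                    jac[rec_idx] = J[t_idx]
        return yhat, raws, jac

    def predict(self, theta) -> np.ndarray:
        """Predicted observation values aligned to the dataset's record order."""
        yhat, _, _ = self._predict_blocks(theta, with_jac=False)
        out = yhat.copy()
        for i, rec in self.dataset.df.iterrows():
            obs = self.model.observable(rec["observable"])
            if obs.transform == "log":
                if yhat[i] <= 0:
                    raise PredictionError(
                        f"log transform of non-positive prediction", records=[i]
                    )
                out[i] = math.log(yhat[i])
        return out

    def residuals_jac(self, theta, with_jac=True):
        """Weighted residuals (and their Jacobian w.r.t. the free vector)."""
        yhat, raws, jac = self._predict_blocks(theta, with_jac)
        y = self._y
        r = np.empty(y.size)
        J = np.empty_like(jac) if with_jac else None
        for obs_name, m in self._obs_masks:
            em = self.dataset.error_models[obs_name]
            sigma = self._sigma_value(em)
            spec = self.model.observable(obs_name)
            if em.kind == "constant" and spec.transform == "linear":
                r[m] = (y[m] - yhat[m]) / sigma
                if with_jac:
                    J[m] = -jac[m] / sigma
            else:
                # residuals on log values (log-normal kind, or log transform);
                # predictions are floored at a tiny positive value so that
                # hopeless trial points keep a finite objective instead of
                # aborting the optimizer (the floored region has zero
                # prediction gradient, which is the honest subderivative)
                yh = np.maximum(yhat[m], _LOG_FLOOR)
                r[m] = (np.log(y[m]) - np.log(yh)) / sigma
                if with_jac:
                    Jm = -jac[m] / (yh[:, None] * sigma)
                    Jm[yhat[m] <= _LOG_FLOOR] = 0.0
                    J[m] = Jm
        return (r, J) if with_jac else (r, None)

    def norm_constant(self) -> float:
        """The sigma-dependent normalization term of -2 log L."""
        df = self.dataset.df
        total = 0.0
        for obs_name, cnt in df["observable"].value_counts().items():
            em = self.dataset.error_models[obs_name]
            sigma = self._sigma_value(em)
            total += cnt * math.log(2.0 * math.pi * sigma * sigma)
        return total

    def neg2loglik(self, theta) -> float:
        r, _ = self.residuals_jac(theta, with_jac=False)
        return float(r @ r) + self.norm_constant()

    def update_sigmas(self, theta) -> float:
        """Closed-form conditional ML update of free sigma parameters.

        Returns the largest relative sigma change (0 when none are free).
        """
        if not self.sigma_free:
            return 0.0
        yhat, _, _ = self._predict_blocks(theta, with_jac=False)
        y = self._y
        max_change = 0.0
        for spec in self.sigma_free:
            res2 = []
            for obs_name, m in self._obs_masks:
                em = self.dataset.error_models[obs_name]
                if em.sigma_param != spec.name:
                    continue
                if em.kind == "constant" and self.model.observable(obs_name).transform == "linear":
                    res2.append((y[m] - yhat[m]) ** 2)
                else:
                    res2.append((np.log(y[m]) - np.log(np.maximum(yhat[m], _LOG_FLOOR))) ** 2)
            if not res2:
                continue
            res2 = np.concatenate(res2)
            new = math.sqrt(max(float(np.mean(res2)), 1e-300))
            new = min(max(new, spec.to_natural(spec.lower)), spec.to_natural(spec.upper))
            old = self._sigma_value(ErrorModel("constant", spec.name))
            self.set_sigma(spec.name, new)
            if old > 0:
                max_change = max(max_change, abs(new - old) / old)
        return max_change


# ---------------------------------------------------------------------------
# spec-level convenience functions
# ---------------------------------------------------------------------------


def predict_observations(trajectories, observables, observation_params, dataset: DataSet,
                         state_names=None) -> np.ndarray:
    """Evaluate observables on given trajectories, aligned to ``dataset``.

    ``observation_params`` maps scale/offset parameter names to natural
    values.  Record order is preserved.
    """
    names = state_names or trajectories.state_names
    df = dataset.df
    out = np.empty(len(df))
    by_name = {o.name: o for o in observables}
    for i, rec in df.iterrows():
        obs = by_name[rec["observable"]]
        fval, _ = obs.compiled(names)
        ti = int(np.argmin(np.abs(trajectories.times - rec["time_min"])))
        if abs(trajectories.times[ti] - rec["time_min"]) > 1e-9:
            raise PredictionError(f"record {i}: time {rec['time_min']} not simulated")
        xs = [trajectories.states[ti, j] for j in range(len(names))]
        raw = float(fval(xs))
        scale = observation_params.get(obs.scale_param, 1.0) if obs.scale_param else 1.0
        offset = observation_params.get(obs.offset_param, 0.0) if obs.offset_param else 0.0
        v = scale * raw + offset
        if obs.transform == "log":
            if v <= 0:
                raise PredictionError("log of non-positive prediction", records=[i])
            v = math.log(v)
        out[i] = v
    return out


def neg2loglik(model, dataset: DataSet, params) -> float:
    """-2 log-likelihood at a full natural-scale parameter vector (or dict)."""
    prob = Problem(model, dataset)
    p = model.natural_vector(params)
    theta = np.array([spec.to_scale(p[model.param_names().index(spec.name)])
                      for spec in prob.free])
    for spec in prob.sigma_free:
        prob.set_sigma(spec.name, p[model.param_names().index(spec.name)])
    return prob.neg2loglik(theta)


def residual_vector(model, dataset: DataSet, params):
    """Weighted residuals and Jacobian w.r.t. free (non-sigma) parameters."""
    prob = Problem(model, dataset)
    p = model.natural_vector(params)
    theta = np.array([spec.to_scale(p[model.param_names().index(spec.name)])
                      for spec in prob.free])
    for spec in prob.sigma_free:
        prob.set_sigma(spec.name, p[model.param_names().index(spec.name)])
    return prob.residuals_jac(theta, with_jac=True)
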