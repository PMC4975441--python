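"""Observation mapping, error models and the -2 log L value contract."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odefold.estimation import fit
from odefold.likelihood import (DataSet, ErrorModel, ObservableSpec, Problem,
                                neg2loglik, predict_observations,
                                residual_vector)
from odefold.model import Condition, OdeModel, ParamSpec, simulate


def make_dataset(model, params, obs_times, noise=None, rng=None,
                 error_models=None, cell_type="cell_type_1"):
    rows = []
    for obs, times in obs_times.items():
        traj = simulate(model, params, model.condition("base"),
                        np.asarray(times, float))
        vals = traj.state(obs) if obs in model.states else None
        if vals is None:  # observable expression
            spec = model.observable(obs)
            f, _ = spec.compiled(model.states)
            vals = np.asarray(f([traj.states[:, j]
                                 for j in range(len(model.states))]))
        if noise is not None:
            vals = vals + rng.normal(0.0, noise, size=len(times))
        for t, v in zip(times, vals):
            rows.append(dict(cell_type=cell_type, condition="base",
                             observable=obs, time_min=float(t),
                             value=float(v), replicate=1))
    return DataSet(pd.DataFrame(rows), error_models or model.error_models)


def decay_model(sigma_fixed=True, lognormal=False, scale_free=False):
    """One-state exponential decay with a scaled observable."""
    return OdeModel(
        name="decay",
        states=["X"],
        params=[
            ParamSpec("k", 0.2),
            ParamSpec("X0", 1.0, role="initial_concentration", fixed=True),
            ParamSpec("s", 1.0, role="observation", fixed=not scale_free),
            ParamSpec("sigma", 0.1, role="error", fixed=sigma_fixed,
                      lower=-3.0, upper=0.0),
        ],
        odes={"X": "-k * X"},
        x0={"X": "X0"},
        observables=[ObservableSpec("Xobs", "X", scale_param="s")],
        conditions=[Condition("base")],
        error_models={"Xobs": ErrorModel(
            "lognormal_relative" if lognormal else "constant", "sigma")},
    )


def test_perfect_fit_residuals_and_norm_constant(toy_model, toy_truth):
    """Data equal to the prediction: zero residuals, -2logL = sum log(2 pi s^2)."""
    ds = make_dataset(toy_model, toy_truth.params_for(1),
                      {"Protein": [0.0, 1.0, 5.0], "ppProtein": [2.0, 8.0]})
    params = dict(toy_truth.params_for(1), sigma_obs=0.1)
    r, J = residual_vector(toy_model, ds, params)
    # the generator and the likelihood evaluate on different time grids, so
    # agreement is bounded by solver error (1e-6 tolerances), not exact
    assert np.max(np.abs(r)) < 1e-4
    val = neg2loglik(toy_model, ds, params)
    assert val == pytest.approx(5 * math.log(2 * math.pi * 0.01), abs=1e-6)
    assert J.shape == (5, 4)  # fixed sigma has no Jacobian column


def test_single_record_unit_z_score(toy_model):
    """|y - yhat| = sigma contributes exactly 1 to the residual term."""
    df = pd.DataFrame([dict(cell_type="ct", condition="base",
                            observable="Protein", time_min=0.0,
                            value=1.1, replicate=1)])
    ds = DataSet(df, {"Protein": ErrorModel("constant", "sigma_obs")})
    params = {"k1": 1.0, "k2": 0.3, "k3": 0.5, "Protein0": 1.0,
              "sigma_obs": 0.1}
    val = neg2loglik(toy_model, ds, params)
    assert val - math.log(2 * math.pi * 0.01) == pytest.approx(1.0, abs=1e-9)


def test_brute_force_summation_oracle(toy_model, toy_truth):
    """-2 log L equals an independent per-record summation.

    The oracle simulates each record's time point in its own solver run;
    both paths integrate at verification tolerances so the comparison is
    limited by the 1e-9 bound, not by solver noise.
    """
    rng = np.random.default_rng(7)
    ds = make_dataset(toy_model, toy_truth.params_for(1),
                      {"Protein": np.linspace(0, 20, 9),
                       "ppProtein": np.linspace(1, 21, 6)},
                      noise=0.1, rng=rng)
    params = {"k1": 0.8, "k2": 0.35, "k3": 0.4, "Protein0": 1.1,
              "sigma_obs": 0.1}
    prob = Problem(toy_model, ds, rtol=1e-12, atol=1e-13)
    theta = np.log10([params["k1"], params["k2"], params["k3"],
                      params["Protein0"]])
    got = prob.neg2loglik(theta)
    # independent oracle: simulate per record, sum the density terms directly
    expected = 0.0
    for _, rec in ds.df.iterrows():
        traj = simulate(toy_model, params, toy_model.condition("base"),
                        [rec["time_min"]], rtol=1e-12, atol=1e-13)
        yhat = traj.state(rec["observable"])[-1]
        expected += ((rec["value"] - yhat) / 0.1) ** 2 + math.log(2 * math.pi * 0.01)
    assert got == pytest.approx(expected, abs=1e-9)


def test_residuals_consistent_with_neg2loglik(toy_model, toy_truth):
    """Sum of squared weighted residuals + normalization == -2 log L."""
    rng = np.random.default_rng(3)
    ds = make_dataset(toy_model, toy_truth.params_for(1),
                      {"Protein": np.linspace(0, 20, 9)}, noise=0.1, rng=rng)
    prob = Problem(toy_model, ds)
    for trial in range(3):
        theta = np.array([rng.uniform(-1, 0.3), np.log10(0.3), np.log10(0.5),
                          rng.uniform(-0.2, 0.4)])
        r, _ = prob.residuals_jac(theta, with_jac=False)
        n2ll = prob.neg2loglik(theta)
        assert float(r @ r) == pytest.approx(
            n2ll - 9 * math.log(2 * math.pi * 0.01), abs=1e-10)
    # the sensitivity-augmented evaluation agrees within solver noise
    r_jac, _ = prob.residuals_jac(theta, with_jac=True)
    assert r_jac == pytest.approx(r, abs=1e-4)


def test_residual_jacobian_matches_finite_differences(toy_model, toy_truth):
    rng = np.random.default_rng(11)
    ds = make_dataset(toy_model, toy_truth.params_for(1),
                      {"Protein": np.linspace(0, 20, 7),
                       "ppProtein": np.linspace(1, 21, 5)},
                      noise=0.1, rng=rng)
    prob = Problem(toy_model, ds, rtol=1e-10, atol=1e-12)
    theta = np.log10([0.9, 0.33, 0.45, 1.05])
    _, J = prob.residuals_jac(theta)
    h = 1e-5
    for j in range(len(theta)):
        up = theta.copy(); up[j] += h
        dn = theta.copy(); dn[j] -= h
        fd = (prob.residuals_jac(up, with_jac=False)[0]
              - prob.residuals_jac(dn, with_jac=False)[0]) / (2 * h)
        denom = np.maximum(np.abs(fd), 1e-2)
        assert np.max(np.abs(J[:, j] - fd) / denom) < 1e-4


def test_predict_observations_identity_and_linearity(toy_model, toy_truth):
    ds = make_dataset(toy_model, toy_truth.params_for(1),
                      {"Protein": [0.0, 1.0, 4.0]})
    traj = simulate(toy_model, toy_truth.params_for(1),
                    toy_model.condition("base"), [0.0, 1.0, 4.0])
    obs = [ObservableSpec("Protein", "Protein", scale_param="s")]
    base = predict_observations(traj, obs, {"s": 1.0}, ds)
    assert base[0] == pytest.approx(toy_truth.protein0_ct1, abs=1e-9)
    doubled = predict_observations(traj, obs, {"s": 2.0}, ds)
    assert doubled == pytest.approx(2.0 * base, rel=1e-12)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(c=st.floats(min_value=0.1, max_value=50.0))
def test_lognormal_scale_equivariance(c):
    """Scaling data and scale parameter together leaves residuals unchanged."""
    model = decay_model(lognormal=True, scale_free=True)
    rng = np.random.default_rng(5)
    times = np.linspace(1.0, 20.0, 8)
    traj = simulate(model, model.default_values(), model.condition("base"), times)
    vals = traj.state("X") * np.exp(rng.normal(0, 0.1, times.size))
    def build(mult):
        df = pd.DataFrame([dict(cell_type="ct", condition="base",
                                observable="Xobs", time_min=float(t),
                                value=float(v * mult), replicate=1)
                           for t, v in zip(times, vals)])
        return DataSet(df, model.error_models)
    prob1 = Problem(model, build(1.0))
    prob2 = Problem(model, build(c))
    theta1 = prob1.default_start()
    theta2 = theta1.copy()
    theta2[prob2.free_names.index("s")] += np.log10(c)
    r1, _ = prob1.residuals_jac(theta1, with_jac=False)
    r2, _ = prob2.residuals_jac(theta2, with_jac=False)
    assert r1 == pytest.approx(r2, abs=1e-9)


def test_estimated_sigma_hits_lower_bound_on_perfect_data():
    """No unexplained variance: the ML noise estimate collapses to its bound."""
    model = decay_model(sigma_fixed=False)
    times = np.linspace(0.0, 20.0, 9)
    traj = simulate(model, model.default_values(), model.condition("base"), times)
    df = pd.DataFrame([dict(cell_type="ct", condition="base", observable="Xobs",
                            time_min=float(t), value=float(v), replicate=1)
                       for t, v in zip(times, traj.state("X"))])
    ds = DataSet(df, model.error_models)
    prob = Problem(model, ds)
    rec = fit(prob, prob.default_start())
    sigma_hat = prob._p_base[model.param_names().index("sigma")]
    assert sigma_hat == pytest.approx(10.0 ** -3.0, rel=1e-6)  # lower bound
    assert rec.value < 9 * math.log(2 * math.pi * 1e-6) + 1e-3


def test_dataset_validation():
    df = pd.DataFrame([dict(cell_type="ct", condition="base", observable="Xobs",
                            time_min=0.0, value=-0.5, replicate=1)])
    model = decay_model(lognormal=True)
    ds = DataSet(df, model.error_models)
    from odefold.likelihood import DataError
    with pytest.raises(DataError):
        ds.validate_against(model)  # negative value under log-normal errors
    with pytest.raises(DataError):
        DataSet(df.drop(columns=["value"]), model.error_models)
    with pytest.raises(DataError):
        DataSet(df, {})  # missing error model
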