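"""ODE core: simulation against closed forms, sensitivities, events."""

import numpy as np
import pytest
from scipy.linalg import expm

from odefold.model import (Condition, Event, ModelConfigError, OdeModel,
                           ParamSpec, simulate, simulate_with_sensitivities,
                           steady_state_init)

LN10 = np.log(10.0)


def cascade_matrix(k1, k2, k3):
    """Generator of the linear three-state cascade (closed-form oracle)."""
    return np.array([[-k1, 0.0, 0.0],
                     [k1, -k2, k3],
                     [0.0, k2, -k3]])


def closed_form(k1, k2, k3, P0, times):
    A = cascade_matrix(k1, k2, k3)
    x0 = np.array([P0, 0.0, 0.0])
    return np.array([expm(A * t) @ x0 for t in times])


def test_initial_state_and_protein_decay(toy_model):
    """Phosphorylated species start at zero; Protein decays as e^(-k1 t)."""
    times = np.array([0.0, 0.5, 1.0, 2.0, 5.0])
    traj = simulate(toy_model, {"k1": 0.3, "k2": 0.7, "k3": 0.5, "Protein0": 1.0},
                    toy_model.condition("base"), times)
    assert traj.states[0] == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)
    assert traj.state("Protein")[2] == pytest.approx(np.exp(-0.3), abs=1e-6)
    assert traj.state("Protein") == pytest.approx(np.exp(-0.3 * times), abs=1e-6)


@pytest.mark.parametrize("seed", range(4))
def test_mass_conservation(toy_model, seed):
    """The closed cascade conserves total protein for any parameterization."""
    rng = np.random.default_rng(seed)
    k1, k2, k3 = 10.0 ** rng.uniform(-1.5, 0.8, size=3)
    P0 = 10.0 ** rng.uniform(-0.5, 0.7)
    times = np.linspace(0.0, 25.0, 26)
    traj = simulate(toy_model, {"k1": k1, "k2": k2, "k3": k3, "Protein0": P0},
                    toy_model.condition("base"), times)
    total = traj.states.sum(axis=1)
    assert total == pytest.approx(np.full(times.size, P0), abs=1e-6)


def test_matches_closed_form_100_draws(toy_model):
    """Numerical solution equals the matrix-exponential solution to 1e-6.

    The solver runs at verification tolerances (1e-9) so that its global
    error budget sits below the 1e-6 agreement bound being asserted.
    """
    rng = np.random.default_rng(12345)
    times = np.linspace(0.0, 25.0, 11)
    for _ in range(100):
        k1, k2, k3 = 10.0 ** rng.uniform(-1.5, 0.7, size=3)
        P0 = 10.0 ** rng.uniform(-0.3, 0.5)
        traj = simulate(toy_model, {"k1": k1, "k2": k2, "k3": k3, "Protein0": P0},
                        toy_model.condition("base"), times, rtol=1e-9, atol=1e-9)
        expected = closed_form(k1, k2, k3, P0, times)
        assert np.max(np.abs(traj.states - expected)) < 1e-6


def test_sensitivity_matches_analytic_form(toy_model):
    """d Protein / d log10 k1 = -k1 ln10 t e^(-k1 t) P0."""
    k1 = 0.3
    times = np.linspace(0.0, 20.0, 21)
    traj = simulate_with_sensitivities(
        toy_model, {"k1": k1, "k2": 0.7, "k3": 0.5, "Protein0": 1.0},
        toy_model.condition("base"), times)
    got = traj.state_sens("Protein")[:, traj.sens_params.index("k1")]
    expected = -k1 * LN10 * times * np.exp(-k1 * times)
    assert got == pytest.approx(expected, abs=1e-5)


def test_sensitivity_structural_zero(toy_model):
    """Protein is fed by no rate containing k2/k3: its sensitivity is 0."""
    traj = simulate_with_sensitivities(
        toy_model, {"k1": 0.3, "k2": 0.7, "k3": 0.5, "Protein0": 1.0},
        toy_model.condition("base"), np.linspace(0.0, 25.0, 11))
    for p in ("k2", "k3"):
        col = traj.state_sens("Protein")[:, traj.sens_params.index(p)]
        assert np.max(np.abs(col)) < 1e-8


def test_sensitivity_matches_finite_differences(toy_model):
    """Forward sensitivities agree with central differences in log10 space."""
    params = {"k1": 1.0, "k2": 0.3, "k3": 0.5, "Protein0": 1.0}
    times = np.linspace(0.0, 25.0, 6)
    tol = dict(rtol=1e-9, atol=1e-11)  # solver noise below the FD budget
    traj = simulate_with_sensitivities(toy_model, params,
                                       toy_model.condition("base"), times, **tol)
    h = 1e-4
    for j, name in enumerate(traj.sens_params):
        up = dict(params); up[name] = params[name] * 10.0 ** h
        dn = dict(params); dn[name] = params[name] * 10.0 ** -h
        fd = (simulate(toy_model, up, toy_model.condition("base"), times,
                       **tol).states
              - simulate(toy_model, dn, toy_model.condition("base"), times,
                         **tol).states) / (2.0 * h)
        scale = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(traj.sens[:, :, j] - fd) / scale) < 1e-4


def test_event_zeroes_targeted_rate(toy_model):
    """Efficiency-1 event on the first phosphorylation freezes Protein."""
    cond = Condition("blocked", events=[Event(5.0, "phos1", 1.0)])
    times = np.array([0.0, 2.0, 5.0, 6.0, 10.0, 25.0])
    traj = simulate(toy_model, {"k1": 0.3, "k2": 0.7, "k3": 0.5, "Protein0": 1.0},
                    cond, times)
    protein = traj.state("Protein")
    assert protein[3:] == pytest.approx(np.full(3, protein[2]), abs=1e-8)
    # downstream species keep equilibrating after the block
    assert abs(traj.state("ppProtein")[5] - traj.state("ppProtein")[2]) > 1e-3


def test_partial_efficiency_event(toy_model):
    """Efficiency e multiplies the targeted rate by (1 - e)."""
    cond = Condition("half", events=[Event(1.0, "phos1", 0.5)])
    traj = simulate(toy_model, {"k1": 0.4, "k2": 0.7, "k3": 0.5, "Protein0": 1.0},
                    cond, np.array([0.0, 1.0, 3.0]))
    # after the event Protein decays at rate k1/2
    expected = traj.state("Protein")[1] * np.exp(-0.2 * 2.0)
    assert traj.state("Protein")[2] == pytest.approx(expected, rel=1e-6)


def test_tolerance_halving_invariance(toy_model):
    params = {"k1": 1.0, "k2": 0.3, "k3": 0.5, "Protein0": 1.0}
    times = np.linspace(0.0, 25.0, 26)
    a = simulate(toy_model, params, toy_model.condition("base"), times)
    b = simulate(toy_model, params, toy_model.condition("base"), times,
                 rtol=5e-7, atol=5e-7)
    # relative to each state's trajectory amplitude: states decaying to ~0
    # have no meaningful pointwise relative error
    amplitude = np.abs(a.states).max(axis=0)
    assert np.max(np.abs(a.states - b.states) / amplitude) < 1e-5


def test_toy_steady_state_is_initial_condition(toy_model):
    """Unstimulated cascade has no basal dynamics beyond full conversion."""
    x = steady_state_init(toy_model, {"k1": 1.0, "k2": 0.3, "k3": 0.5,
                                      "Protein0": 1.0})
    assert np.max(np.abs(toy_model.rhs(x, toy_model.default_values()))) < 1e-8


def test_steady_state_residual_check(jakstat_model):
    """Pre-equilibration result satisfies the direct rhs residual bound."""
    x = steady_state_init(jakstat_model, jakstat_model.default_values())
    resid = jakstat_model.rhs(x, jakstat_model.default_values())
    assert np.max(np.abs(resid)) < 1e-8


def test_unknown_event_target_rejected(toy_model):
    cond = Condition("bad", events=[Event(1.0, "no_such_rate", 1.0)])
    with pytest.raises(ModelConfigError):
        simulate(toy_model, toy_model.default_values(), cond, [0.0, 1.0, 2.0])


def test_model_validation_errors():
    with pytest.raises(ModelConfigError):
        OdeModel(name="bad", states=["A"], params=[ParamSpec("k", 1.0)],
                 odes={"A": "-k * B"})  # undeclared symbol
    with pytest.raises(ModelConfigError):
        OdeModel(name="bad2", states=["A", "B"], params=[ParamSpec("k", 1.0)],
                 odes={"A": "-k * A"})  # missing rhs
    with pytest.raises(ModelConfigError):
        ParamSpec("p", 1.0, lower=2.0, upper=1.0)
    with pytest.raises(ModelConfigError):
        Event(-1.0, "r", 0.5)
    with pytest.raises(ModelConfigError):
        Event(1.0, "r", 1.5)
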