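import numpy as np
import pytest

np.seterr(all="ignore")

from odefold import examples
from odefold.l1 import JointProblem
from odefold.workflow import TOY_TESTABLE, run_toy_study


@pytest.fixture(scope="session")
def toy_model():
    return examples.build_toy_model()


@pytest.fixture(scope="session")
def toy_truth():
    return examples.ToyTruth()


@pytest.fixture(scope="session")
def toy_data0():
    return examples.generate_toy_data(seed=0)


@pytest.fixture(scope="session")
def toy_joint0(toy_model, toy_data0):
    return JointProblem(
        toy_model,
        toy_data0.for_cell_type("cell_type_1"),
        toy_data0.for_cell_type("cell_type_2"),
        testable=TOY_TESTABLE,
    )


@pytest.fixture(scope="session")
def toy_study0(toy_model):
    """Full workflow run at the default study seed, objects retained."""
    return run_toy_study(0, model=toy_model, keep_objects=True)


@pytest.fixture(scope="session")
def toy_study_50(toy_model):
    """The 50-replicate selection/recovery study (shared across tests)."""
    return [run_toy_study(seed, model=toy_model) for seed in range(50)]


@pytest.fixture(scope="session")
def jakstat_model():
    return examples.build_jakstat_model()


@pytest.fixture(scope="session")
def gaussian_offset_problem():
    """Constant state observed with a free linear offset plus the data.

    The exact linear-Gaussian case: the offset's profile likelihood is an
    analytic parabola and its standard error is sigma/sqrt(n).
    """
    import pandas as pd

    from odefold.likelihood import DataSet, ErrorModel, ObservableSpec, Problem
    from odefold.model import Condition, OdeModel, ParamSpec

    n, mu, sigma = 25, 0.5, 0.1
    model = OdeModel(
        name="offset",
        states=["X"],
        params=[
            ParamSpec("o", 0.0, scale="linear", lower=-5.0, upper=5.0,
                      role="observation"),
            ParamSpec("sigma", sigma, role="error", fixed=True),
        ],
        odes={"X": "0"},
        x0={"X": "0"},
        observables=[ObservableSpec("Xobs", "X", offset_param="o")],
        conditions=[Condition("base")],
        error_models={"Xobs": ErrorModel("constant", "sigma")},
    )
    rng = np.random.default_rng(3)
    y = rng.normal(mu, sigma, size=n)
    df = pd.DataFrame([dict(cell_type="ct", condition="base", observable="Xobs",
                            time_min=float(i), value=float(v), replicate=1)
                       for i, v in enumerate(y)])
    return Problem(model, DataSet(df, model.error_models)), y, n, sigma
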