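"""Control-coefficient sensitivity analysis for target prioritization.

The readout K is the area under the curve of a chosen state up to a time
horizon (for the JAK2/STAT5 model: nuclear phosphorylated STAT5 over 60
minutes, a survival-associated quantity).  For each parameter the
dimensionless control coefficient

    S_i = (p_i / K) * dK/dp_i  =  d log K / d log p_i

is evaluated at the fitted parameters by sensitivity-augmented integration:
the ODE system is extended with a quadrature state for the readout, so K
and dK/dp come from the forward sensitivity system rather than from
quadrature of sampled output.  A positive coefficient means that lowering
the parameter lowers the readout; the larger |S|, the more control the
parameter exerts.  Comparing coefficients between two cell types flags
parameters with more control in cell type 2 (preferential targets there).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LN10, Condition, ModelConfigError, OdeModel, simulate

__all__ = ["ReadoutSpec", "ControlTable", "auc_readout", "control_coefficients",
           "compare_cell_types"]


@dataclass
class ReadoutSpec:
    """K = integral of ``state`` over [0, horizon] minutes."""

    state: str
    horizon: float = 60.0

    def __post_init__(self):
        if self.horizon <= 0:
            raise ModelConfigError("readout horizon must be positive")


@dataclass
class ControlTable:
    """Per-parameter control coefficients at one evaluation point."""

    table: pd.DataFrame  # columns: parameter, S, rank
    readout: ReadoutSpec
    condition: str
    K: float
    cell_type: str | None = None

    def coefficient(self, name: str) -> float:
        row = self.table[self.table["parameter"] == name]
        return float(row["S"].iloc[0])


def _augmented(model: OdeModel, readout: ReadoutSpec) -> tuple[OdeModel, str]:
    if readout.state not in model.states:
        raise ModelConfigError(f"readout state {readout.state!r} not in model")
    qname = f"int_{readout.state}"
    return model.with_integral(readout.state, qname), qname


def auc_readout(model: OdeModel, params, condition: Condition,
                readout: ReadoutSpec, rtol: float = 1e-6,
                atol: float = 1e-6) -> float:
    """K computed by augmenting the ODE with an integral state."""
    aug, qname = _augmented(model, readout)
    traj = simulate(aug, params, condition, [0.0, readout.horizon],
                    rtol=rtol, atol=atol)
    return float(traj.state(qname)[-1])


def control_coefficients(model: OdeModel, params, condition: Condition,
                         readout: ReadoutSpec, parameters: list | None = None,
                         cell_type: str | None = None, rtol: float = 1e-6,
                         atol: float = 1e-6) -> ControlTable:
    """Control coefficients S_i = (p_i/K) dK/dp_i for the selected parameters.

    Defaults to all non-fixed parameters with kinetic or initial-
    concentration roles.  K = 0 leaves the coefficients undefined (NaN,
    with a warning).
    """
    if parameters is None:
        parameters = [p.name for p in model.params if not p.fixed
                      and p.role in ("kinetic", "initial_concentration")]
    aug, qname = _augmented(model, readout)
    p_nat = model.natural_vector(params)
    traj = simulate(aug, p_nat, condition, [0.0, readout.horizon],
                    sens_params=parameters, rtol=rtol, atol=atol)
    K = float(traj.state(qname)[-1])
    dK = traj.state_sens(qname)[-1]  # on each parameter's estimation scale
    if K == 0.0:
        warnings.warn("readout K = 0: control coefficients undefined")
        S = np.full(len(parameters), np.nan)
    else:
        S = np.empty(len(parameters))
        for j, name in enumerate(parameters):
            spec = model.param(name)
            if spec.scale == "log10":
                # dK/dlog10 p = ln10 * p * dK/dp  =>  S = dK/dlog10 p / (K ln10)
                S[j] = dK[j] / (K * LN10)
            else:
                value = p_nat[model.param_names().index(name)]
                S[j] = value * dK[j] / K
    order = np.argsort(-np.abs(S))
    rank = np.empty(len(S), dtype=int)
    rank[order] = np.arange(1, len(S) + 1)
    df = pd.DataFrame({"parameter": parameters, "S": S, "rank": rank})
    return ControlTable(table=df, readout=readout,
                        condition=condition.name if condition else "",
                        K=K, cell_type=cell_type)


def compare_cell_types(ct1: ControlTable, ct2: ControlTable,
                       labels=("cell_type_1", "cell_type_2")) -> pd.DataFrame:
    """Side-by-side control coefficients with a preferential-target flag.

    ``more_control_ct2`` marks parameters with |S| larger in cell type 2:
    interventions on them hit cell type 2 harder than cell type 1.
    """
    a = ct1.table.set_index("parameter")["S"]
    b = ct2.table.set_index("parameter")["S"]
    params = [p for p in a.index if p in b.index]
    df = pd.DataFrame({
        "parameter": params,
        f"S_{labels[0]}": [a[p] for p in params],
        f"S_{labels[1]}": [b[p] for p in params],
    })
    df["more_control_ct2"] = np.abs(df[f"S_{labels[1]}"]) > np.abs(df[f"S_{labels[0]}"])
    return df
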