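"""Plain-text persistence: model descriptions, data tables, reports.

Models are stored as structured YAML (states, parameters with bounds and
fixed values, rates, ODEs, observables, conditions with events, error-model
assignments); loading a dumped model reproduces it exactly.  Observation
tables are tab-separated text with the header
``cell_type  condition  observable  time_min  value  replicate``.
Reports are JSON with all floats carried at full precision (17 significant
digits), so a workflow re-run with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Condition, Event, ModelConfigError, OdeModel, ParamSpec
from .likelihood import DATA_COLUMNS, DataError, DataSet, ErrorModel, ObservableSpec

__all__ = [
    "model_to_dict", "model_from_dict", "save_model", "load_model",
    "load_data_table", "save_data_table", "write_report", "validate_report",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------


def _plain(obj):
    """Coerce numpy scalars to builtins for clean YAML/JSON output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def model_to_dict(model: OdeModel) -> dict:
    return _plain({
        "name": model.name,
        "states": list(model.states),
        "inputs": list(model.inputs),
        "parameters": [dataclasses.asdict(p) for p in model.params],
        "rates": dict(model.rates),
        "odes": dict(model.odes),
        "x0": {k: str(v) for k, v in model.x0.items()},
        "observables": [
            {"name": o.name, "expr": o.expr, "scale_param": o.scale_param,
             "offset_param": o.offset_param, "transform": o.transform}
            for o in model.observables
        ],
        "conditions": [
            {"name": c.name, "inputs": dict(c.inputs),
             "steady_state": c.steady_state,
             "init_overrides": dict(c.init_overrides),
             "events": [dataclasses.asdict(e) for e in c.events]}
            for c in model.conditions
        ],
        "error_models": {
            obs: {"kind": em.kind, "sigma_param": em.sigma_param}
            for obs, em in model.error_models.items()
        },
    })


def model_from_dict(d: dict) -> OdeModel:
    try:
        params = [ParamSpec(**p) for p in d["parameters"]]
        observables = [ObservableSpec(**o) for o in d.get("observables", [])]
        conditions = [
            Condition(
                name=c["name"], inputs=dict(c.get("inputs", {})),
                steady_state=bool(c.get("steady_state", False)),
                init_overrides=dict(c.get("init_overrides", {})),
                events=[Event(**e) for e in c.get("events", [])],
            )
            for c in d.get("conditions", [])
        ]
        error_models = {obs: ErrorModel(**em)
                        for obs, em in d.get("error_models", {}).items()}
        return OdeModel(
            name=d["name"], states=list(d["states"]), params=params,
            odes=dict(d["odes"]), rates=dict(d.get("rates", {})),
            x0=dict(d.get("x0", {})), inputs=list(d.get("inputs", [])),
            observables=observables, conditions=conditions,
            error_models=error_models,
        )
    except KeyError as e:
        raise ModelConfigError(f"model description missing section {e}") from e


def save_model(model: OdeModel, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(model_to_dict(model), sort_keys=False, width=100))


def load_model(path) -> OdeModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# data tables
# ---------------------------------------------------------------------------


def load_data_table(path, error_models: dict) -> DataSet:
    """Load a TSV observation table; errors carry the offending line.

    ``error_models`` maps observables to ErrorModel (typically from the
    model description's ``error_models`` section).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as e:
        raise DataError(f"{path}: unparseable table: {e}") from e
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in ("time_min", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
            raise DataError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[DATA_COLUMNS].duplicated().any():
        lines = [int(i) + 2 for i in df.index[df[DATA_COLUMNS].duplicated()]]
        raise DataError(f"{path}: duplicate exact records at line(s) {lines}")
    return DataSet(df, error_models)


def save_data_table(dataset: DataSet, path) -> None:
    dataset.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "type": "object",
    "required": ["selection", "meta"],
    "properties": {
        "meta": {
            "type": "object",
            "required": ["package", "version", "seed", "alpha", "tolerances"],
        },
        "selection": {
            "type": "object",
            "required": ["pattern", "N", "M", "D", "threshold",
                         "fold_changes", "full_model_fallback"],
        },
        "profiles": {"type": "object"},
        "control_coefficients": {"type": "array"},
        "path": {"type": "object"},
    },
}


def validate_report(report: dict) -> None:
    """Structural validation against the shipped report schema."""
    def check(obj, schema, where):
        if schema.get("type") == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{where}: expected object")
            for req in schema.get("required", []):
                if req not in obj:
                    raise ValueError(f"{where}: missing required key {req!r}")
            for key, sub in schema.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{where}.{key}")
        elif schema.get("type") == "array" and not isinstance(obj, list):
            raise ValueError(f"{where}: expected array")
    check(report, REPORT_SCHEMA, "report")


def _fmt(x):
    if isinstance(x, (np.floating, float)):
        return float(f"{float(x):.17g}")
    return x


def format_fold_entry(fold: float, sigma_log10: float | None,
                      open_interval: bool = False) -> str:
    """Catalogue-style entry: 'value +/- sigma' or '>= bound'."""
    if sigma_log10 is None:
        return f"{fold:.2g} (unbounded)"
    if open_interval:
        return f">= {10.0 ** (np.log10(fold) - sigma_log10):.2g}"
    return f"{fold:.2g} +/- {fold * np.log(10.0) * sigma_log10:.2g}"


def write_report(outdir, selection=None, profiles=None, control_table=None,
                 path=None, seed=None, alpha=0.05,
                 tolerances=(1e-6, 1e-6)) -> dict:
    """Write the machine-readable JSON report plus delimited tables.

    ``profiles`` maps fold-change parameter names to ProfileCI objects.
    Returns the report dictionary (also written to ``report.json``).
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "meta": {
            "package": "odefold", "version": __version__,
            "seed": seed, "alpha": alpha,
            "tolerances": {"rtol": _fmt(tolerances[0]), "atol": _fmt(tolerances[1])},
        },
    }
    if selection is not None:
        folds = {}
        rows = []
        for name, entry in selection.fold_changes.items():
            ci = (profiles or {}).get(name)
            sigma = None if ci is None else ci.sigma
            is_open = bool(ci is not None and ci.sigma_is_lower_bound)
            selected = name in selection.pattern
            if selected:
                # catalogue style: factor > 1 plus the cell type it favors
                disp = entry["fold"] if entry["fold"] >= 1.0 else 1.0 / entry["fold"]
                side = "cell type 2" if entry["fold"] >= 1.0 else "cell type 1"
                formatted = (f"{format_fold_entry(disp, sigma, is_open)}"
                             f" (higher in {side})")
            else:
                formatted = "1 (cell type-independent)"
            folds[name] = {
                "selected": selected, "d_log10": _fmt(entry["d"]),
                "fold": _fmt(entry["fold"]),
                "sigma_log10": None if sigma is None else _fmt(sigma),
                "open_interval": is_open, "formatted": formatted,
            }
            rows.append({"parameter": name, "selected": selected,
                         "fold_change": formatted})
        report["selection"] = {
            "pattern": sorted(selection.pattern), "N": selection.N,
            "M": selection.M, "D": _fmt(selection.D),
            "threshold": _fmt(selection.threshold),
            "full_model_fallback": bool(selection.full_model_fallback),
            "tie_patterns": [sorted(p) for p in selection.tie_patterns],
            "fold_changes": folds,
            "tested_patterns": [
                {"pattern": sorted(p), "N": n, "D": _fmt(D),
                 "threshold": _fmt(thr), "passed": ok}
                for p, n, D, thr, ok in selection.tested
            ],
        }
        pd.DataFrame(rows).to_csv(outdir / "fold_changes.tsv", sep="\t",
                                  index=False)
    if path is not None:
        ptab = pd.DataFrame(path.d_matrix,
                            columns=[f"d_{n}" for n in path.d_names])
        ptab.insert(0, "lambda", path.lambdas)
        ptab["N"] = path.n_specific
        ptab["C"] = path.objective
        ptab["neg2loglik"] = path.neg2loglik
        ptab.to_csv(outdir / "path.tsv", sep="\t", index=False,
                    float_format="%.17g")
        report["path"] = {
            "n_lambda": int(path.lambdas.size),
            "lambda_min": _fmt(path.lambdas[0]),
            "lambda_max": _fmt(path.lambdas[-1]),
            "failures": [[int(k), _fmt(l)] for k, l in path.failures],
        }
    if control_table is not None:
        control_table.to_csv(outdir / "control_coefficients.tsv", sep="\t",
                             index=False, float_format="%.17g")
        report["control_coefficients"] = [
            {k: _fmt(v) for k, v in row.items()}
            for row in control_table.to_dict(orient="records")
        ]
    if profiles:
        report["profiles"] = {
            name: {"lower": _fmt(ci.lower) if ci.lower is not None else None,
                   "upper": _fmt(ci.upper) if ci.upper is not None else None,
                   "sigma_log10": _fmt(ci.sigma) if ci.sigma is not None else None,
                   "open": bool(ci.sigma_is_lower_bound), "delta": _fmt(ci.delta)}
            for name, ci in profiles.items()
        }
    validate_report(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


@dataclasses.dataclass
class RunConfig:
    """Serializable description of a full analysis run."""

    model: str
    data: dict                  # cell type label -> data table path
    testable: list
    lambda_min: float = 1e-4
    lambda_max: float = 1e4
    lambda_points: int = 49
    alpha: float = 0.05
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-6
    outdir: str = "odefold_run"

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
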