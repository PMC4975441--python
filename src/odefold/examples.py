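"""Example models and seeded synthetic-data generators.

Two workflows ship with the package:

* a two-step phosphorylation cascade (Protein -> pProtein <-> ppProtein)
  simulated for two cell types that differ in the dephosphorylation rate k3
  (0.5 vs 0.1 /min) and the initial protein concentration (1 vs 2 nM), with
  additive Gaussian noise sigma = 0.1 on 21 Protein and 10 ppProtein
  sampling times per cell type — the benchmark for fold-change recovery;

* a reconstructed EPO-induced JAK2/STAT5 signaling model (23 states, the
  26-parameter catalogue including [PTP]_t=0) with basal transcription,
  nuclear pSTAT5 dephosphorylation, Hill-type SOCS3 promoter regulation,
  SOCS3/CIS negative feedback at the receptor/kinase level and delay chains
  for both mRNAs, plus a generator emulating immunoblot/qRT-PCR-like
  (log-normal relative noise) and mass-spec-like degree-of-phosphorylation
  (constant noise, sigma <= 0.05) measurements and transcription-inhibitor
  event designs.

The generator defaults are the study conditions; sampling schedules and the
unpublished toy truths k1 = 0.3, k2 = 0.7 /min are package choices shipped
as editable defaults (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Condition, Event, OdeModel, ParamSpec, simulate
from .likelihood import DataSet, ErrorModel, ObservableSpec

__all__ = [
    "ToyTruth",
    "build_toy_model",
    "generate_toy_data",
    "build_jakstat_model",
    "generate_jakstat_data",
    "default_jakstat_design",
    "TOY_PROTEIN_TIMES",
    "TOY_PPPROTEIN_TIMES",
    "JAKSTAT_PARAM_NAMES",
    "JAKSTAT_FIXED_SPECIFIC",
]

# quasi-log-spaced sampling on [0, 25] min; Protein and ppProtein schedules
# deliberately do not coincide
TOY_PROTEIN_TIMES = np.array([
    0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0,
    6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.5, 25.0,
])
TOY_PPPROTEIN_TIMES = np.array([
    0.5, 1.5, 3.0, 5.0, 7.5, 10.0, 13.0, 17.0, 21.0, 25.0,
])


@dataclass
class ToyTruth:
    """Generating parameter values of the two-cell-type cascade simulation.

    The shared rates default to k1 = 1.0 and k2 = 0.3 /min: the stimulus
    conversion is fast and the downstream phosphorylation equilibration
    slower, so the ppProtein relaxation rate (k2 + k3) is resolved by the
    sampling schedule in both cell types.  With the cell type-specific
    truths k3 = 0.5/0.1 /min and [Protein]0 = 1/2 nM and additive noise
    sigma = 0.1 nM on 21 + 10 points per cell type, the parsimonious-model
    profile standard deviations of the log10 fold-changes are about 0.12
    (k3) and 0.03 ([Protein]0) — the identifiability regime in which the
    fold-change recovery benchmark operates (see docs/methods.md).
    """

    k1: float = 1.0            # /min, shared
    k2: float = 0.3            # /min, shared
    k3_ct1: float = 0.5        # /min
    k3_ct2: float = 0.1        # /min
    protein0_ct1: float = 1.0  # nM
    protein0_ct2: float = 2.0  # nM
    sigma: float = 0.1         # additive Gaussian noise (nM)
    protein_times: np.ndarray = field(
        default_factory=lambda: TOY_PROTEIN_TIMES.copy())
    ppprotein_times: np.ndarray = field(
        default_factory=lambda: TOY_PPPROTEIN_TIMES.copy())

    def params_for(self, cell_type: int) -> dict:
        return {
            "k1": self.k1, "k2": self.k2,
            "k3": self.k3_ct1 if cell_type == 1 else self.k3_ct2,
            "Protein0": self.protein0_ct1 if cell_type == 1 else self.protein0_ct2,
        }


def build_toy_model(sigma: float = 0.1) -> OdeModel:
    """Two-step phosphorylation cascade with reversible second step.

    The first phosphorylation (rate k1) is irreversible; pProtein and
    ppProtein equilibrate through forward rate k2 and back rate k3.  Both
    phosphorylated species start at zero; the pool is closed, so total
    protein is conserved.  The measurement noise sigma is a fixed, known
    constant in this workflow.
    """
    return OdeModel(
        name="two_step_cascade",
        states=["Protein", "pProtein", "ppProtein"],
        params=[
            ParamSpec("k1", 1.0),
            ParamSpec("k2", 0.3),
            ParamSpec("k3", 0.5),
            ParamSpec("Protein0", 1.0, role="initial_concentration"),
            ParamSpec("sigma_obs", sigma, role="error", fixed=True),
        ],
        rates={
            "phos1": "k1 * Protein",
            "phos2": "k2 * pProtein",
            "dephos": "k3 * ppProtein",
        },
        odes={
            "Protein": "-phos1",
            "pProtein": "phos1 - phos2 + dephos",
            "ppProtein": "phos2 - dephos",
        },
        x0={"Protein": "Protein0"},
        observables=[
            ObservableSpec("Protein", "Protein"),
            ObservableSpec("ppProtein", "ppProtein"),
        ],
        conditions=[Condition("base")],
        error_models=toy_error_models(),
    )


def toy_error_models() -> dict:
    return {
        "Protein": ErrorModel("constant", "sigma_obs"),
        "ppProtein": ErrorModel("constant", "sigma_obs"),
    }


def generate_toy_data(truth: ToyTruth | None = None, seed: int = 0,
                      noiseless: bool = False) -> DataSet:
    """Simulate both cell types and add i.i.d. N(0, sigma^2) noise.

    Returns 21 Protein + 10 ppProtein records per cell type (62 records in
    total).  Negative noisy values are permitted: the error model is
    additive Gaussian.  Deterministic given the seed.  ``noiseless=True``
    returns the exact model output at the same schedules (oracle runs).
    """
    truth = truth or ToyTruth()
    model = build_toy_model(sigma=truth.sigma)
    rng = np.random.default_rng(seed)
    cond = model.condition("base")
    rows = []
    for ct in (1, 2):
        params = truth.params_for(ct)
        for obs, times in (("Protein", truth.protein_times),
                           ("ppProtein", truth.ppprotein_times)):
            traj = simulate(model, params, cond, np.asarray(times, float))
            clean = traj.state(obs)
            noisy = (clean if noiseless
                     else clean + rng.normal(0.0, truth.sigma, size=clean.size))
            for t, v in zip(times, noisy):
                rows.append({
                    "cell_type": f"cell_type_{ct}", "condition": "base",
                    "observable": obs, "time_min": float(t),
                    "value": float(v), "replicate": 1,
                })
    return DataSet(pd.DataFrame(rows), toy_error_models())


# ---------------------------------------------------------------------------
# JAK2/STAT5 example model (reconstruction)
# ---------------------------------------------------------------------------

JAKSTAT_PARAM_NAMES = [
    "CISHRNAbasal", "CISHRNAdelay", "CISHRNAeqm", "CISHRNAturn",
    "CISeqm", "CISinh", "CISturn",
    "EPORactJAK2", "JAK2EPORdeactPTP", "JAK2actEPO",
    "PTPactEPOR", "PTPdeact",
    "SOCS3RNAbasal", "SOCS3RNAdelay", "SOCS3RNAeqm", "SOCS3RNAturn",
    "SOCS3eqm", "SOCS3inh", "SOCS3prom", "SOCS3turn",
    "STAT5actEPOR", "STAT5actJAK2", "STAT5exp", "STAT5imp",
    "PTP0", "nSTAT5deact",
]

# nominal natural-scale values giving a transient pSTAT5 peak within ~30 min
# and delayed mRNA peaks, resolved over a 0-300 min window
_JAKSTAT_DEFAULTS = {
    "CISHRNAbasal": 0.05, "CISHRNAdelay": 0.1, "CISHRNAeqm": 2.0,
    "CISHRNAturn": 0.05, "CISeqm": 1.5, "CISinh": 2.0, "CISturn": 0.02,
    "EPORactJAK2": 0.3, "JAK2EPORdeactPTP": 0.3, "JAK2actEPO": 0.04,
    "PTPactEPOR": 0.5, "PTPdeact": 0.1,
    "SOCS3RNAbasal": 0.05, "SOCS3RNAdelay": 0.08, "SOCS3RNAeqm": 2.0,
    "SOCS3RNAturn": 0.06, "SOCS3eqm": 1.2, "SOCS3inh": 3.0,
    "SOCS3prom": 1.0, "SOCS3turn": 0.03,
    "STAT5actEPOR": 0.1, "STAT5actJAK2": 0.05, "STAT5exp": 0.03,
    "STAT5imp": 0.06, "PTP0": 1.0, "nSTAT5deact": 0.04,
}

# cell-type-specific fixed quantities (measured externally in a real study:
# EPOR-JAK2 complex and STAT5 initial concentrations).  These are synthetic
# representative values, not measured ones.
JAKSTAT_FIXED_SPECIFIC = {
    "EPORJAK2_init": (1.0, 0.3),
    "STAT5_init": (1.0, 0.8),
}

N_DELAY = 4   # delay-chain intermediates per mRNA (23-state accounting)
HILL = 2.0    # fixed SOCS3 promoter Hill coefficient


def build_jakstat_model(n_delay: int = N_DELAY, hill: float = HILL) -> OdeModel:
    """Reconstructed generalized EPO-induced JAK2/STAT5 pathway model.

    Ligand EPO activates JAK2 in the EPOR-JAK2 complex, then the receptor
    is phosphorylated by active JAK2; the phosphatase PTP (activated by
    phosphorylated receptor complexes) deactivates both sites.  Activated
    STAT5 shuttles into the nucleus, is dephosphorylated there and exported
    back.  Nuclear pSTAT5 drives CISH transcription linearly and SOCS3
    transcription through a Hill function (fixed Hill coefficient); both
    genes have basal transcription, delay chains, first-order mRNA and
    protein turnover, and the proteins inhibit receptor/JAK2-level
    activation.  With the default chain length of 4 intermediates per mRNA
    the model has 23 states; 25 kinetic parameters plus the initial PTP
    concentration form the testable catalogue, while the EPOR-JAK2 and
    STAT5 initial concentrations are fixed per cell type.
    """
    chain = lambda g, i: f"{g}n{i}"
    states = [
        "EPO", "EPORJAK2", "EPORpJAK2", "pEPORpJAK2", "pEPORJAK2",
        "PTP", "actPTP", "STAT5", "pSTAT5", "npSTAT5", "nSTAT5",
        *[chain("CISH", i) for i in range(1, n_delay + 1)], "CISHRNA", "CIS",
        *[chain("SOCS3", i) for i in range(1, n_delay + 1)], "SOCS3RNA", "SOCS3",
    ]

    params = [ParamSpec(n, _JAKSTAT_DEFAULTS[n],
                        role="initial_concentration" if n == "PTP0" else "kinetic")
              for n in JAKSTAT_PARAM_NAMES]
    params += [
        ParamSpec("EPORJAK2_init", 1.0, role="initial_concentration", fixed=True),
        ParamSpec("STAT5_init", 1.0, role="initial_concentration", fixed=True),
        ParamSpec("SOCS3promKA", 0.2, fixed=True),  # Hill half-max (fixed, nM)
        # observation scales (relative measurements) and noise parameters
        ParamSpec("scale_pEPOR", 1.0, role="observation", fixed=True),
        ParamSpec("scale_pJAK2", 1.0, role="observation", fixed=True),
        ParamSpec("scale_pSTAT5", 1.0, role="observation", fixed=True),
        ParamSpec("scale_tSTAT5", 1.0, role="observation", fixed=True),
        ParamSpec("scale_CISHRNA", 1.0, role="observation", fixed=True),
        ParamSpec("scale_SOCS3RNA", 1.0, role="observation", fixed=True),
        ParamSpec("sigma_rel", 0.15, role="error", fixed=True),
        ParamSpec("sigma_dop", 0.04, lower=-5.0, upper=np.log10(0.05),
                  role="error", fixed=True),
    ]

    # inhibition acts on the absolute feedback-protein concentration
    # (per-nM strength), so the equilibrium-concentration parameters
    # remain observable through the feedback loop
    socs3_inhib = "(1 + SOCS3inh * SOCS3)"
    cis_inhib = "(1 + CISinh * CIS)"
    rates = {
        # receptor / kinase module
        "actJAK2": f"JAK2actEPO * EPO * EPORJAK2 / {socs3_inhib}",
        "actJAK2b": f"JAK2actEPO * EPO * pEPORJAK2 / {socs3_inhib}",
        "actEPOR": f"EPORactJAK2 * EPORpJAK2 / {cis_inhib}",
        "deactJAK2": "JAK2EPORdeactPTP * actPTP * EPORpJAK2",
        "deactJAK2b": "JAK2EPORdeactPTP * actPTP * pEPORpJAK2",
        "deactEPOR": "JAK2EPORdeactPTP * actPTP * pEPORJAK2",
        # phosphatase module
        "actPTPr": "PTPactEPOR * PTP * (pEPORpJAK2 + pEPORJAK2)",
        "deactPTPr": "PTPdeact * actPTP",
        # STAT5 module
        "actSTAT5": ("(STAT5actJAK2 * (EPORpJAK2 + pEPORpJAK2)"
                     " + STAT5actEPOR * (pEPORpJAK2 + pEPORJAK2)) * STAT5"),
        "impSTAT5": "STAT5imp * pSTAT5",
        "deactnSTAT5": "nSTAT5deact * npSTAT5",
        "expSTAT5": "STAT5exp * nSTAT5",
        # transcription inputs (actinomycin-D events target these rates)
        "CISH_transcription":
            "CISHRNAdelay * (CISHRNAbasal + npSTAT5 / STAT5_init)",
        # the Hill exponent is inlined as an integer so the symbolic
        # derivative stays polynomial (finite at npSTAT5 = 0)
        "SOCS3_transcription":
            (f"SOCS3RNAdelay * (SOCS3RNAbasal + SOCS3prom * npSTAT5**{int(hill)}"
             f" / (npSTAT5**{int(hill)} + SOCS3promKA**{int(hill)}))"),
    }
    odes = {
        "EPO": "0",
        "EPORJAK2": "-actJAK2 + deactJAK2 + deactEPOR",
        "EPORpJAK2": "actJAK2 - deactJAK2 - actEPOR",
        "pEPORpJAK2": "actEPOR + actJAK2b - deactJAK2b",
        "pEPORJAK2": "deactJAK2b - deactEPOR - actJAK2b",
        "PTP": "-actPTPr + deactPTPr",
        "actPTP": "actPTPr - deactPTPr",
        "STAT5": "-actSTAT5 + expSTAT5",
        "pSTAT5": "actSTAT5 - impSTAT5",
        "npSTAT5": "impSTAT5 - deactnSTAT5",
        "nSTAT5": "deactnSTAT5 - expSTAT5",
    }
    for g in ("CISH", "SOCS3"):
        odes[chain(g, 1)] = f"{g}_transcription - {g}RNAdelay * {chain(g, 1)}"
        for i in range(2, n_delay + 1):
            odes[chain(g, i)] = (f"{g}RNAdelay * ({chain(g, i - 1)}"
                                 f" - {chain(g, i)})")
        odes[f"{g}RNA"] = (f"{g}RNAturn * ({g}RNAeqm * {chain(g, n_delay)}"
                           f" - {g}RNA)")
    odes["CIS"] = "CISturn * (CISeqm * CISHRNA / CISHRNAeqm - CIS)"
    odes["SOCS3"] = "SOCS3turn * (SOCS3eqm * SOCS3RNA / SOCS3RNAeqm - SOCS3)"

    observables = [
        ObservableSpec("pEPOR", "pEPORpJAK2 + pEPORJAK2", "scale_pEPOR"),
        ObservableSpec("pJAK2", "EPORpJAK2 + pEPORpJAK2", "scale_pJAK2"),
        ObservableSpec("pSTAT5", "pSTAT5", "scale_pSTAT5"),
        ObservableSpec("tSTAT5", "STAT5 + pSTAT5", "scale_tSTAT5"),
        ObservableSpec("STAT5_dop",
                       "(pSTAT5 + npSTAT5) / (STAT5 + pSTAT5 + npSTAT5 + nSTAT5)"),
        ObservableSpec("CISHRNA", "CISHRNA", "scale_CISHRNA"),
        ObservableSpec("SOCS3RNA", "SOCS3RNA", "scale_SOCS3RNA"),
    ]
    conditions = [
        Condition("epo_stim", inputs={"EPO0": 5.0}, steady_state=True),
        Condition("epo_actd_30", inputs={"EPO0": 5.0}, steady_state=True,
                  events=[Event(30.0, "CISH_transcription", 1.0),
                          Event(30.0, "SOCS3_transcription", 1.0)]),
        Condition("epo_actd_60", inputs={"EPO0": 5.0}, steady_state=True,
                  events=[Event(60.0, "CISH_transcription", 1.0),
                          Event(60.0, "SOCS3_transcription", 1.0)]),
        Condition("unstimulated", inputs={"EPO0": 0.0}, steady_state=True),
    ]
    return OdeModel(
        name="jakstat",
        states=states,
        params=params,
        rates=rates,
        odes=odes,
        x0={"EPO": "EPO0", "EPORJAK2": "EPORJAK2_init", "PTP": "PTP0",
            "STAT5": "STAT5_init"},
        inputs=["EPO0"],
        observables=observables,
        conditions=conditions,
        error_models=jakstat_error_models(),
    )


def jakstat_error_models() -> dict:
    rel = ErrorModel("lognormal_relative", "sigma_rel")
    return {
        "pEPOR": rel, "pJAK2": rel, "pSTAT5": rel, "tSTAT5": rel,
        "CISHRNA": rel, "SOCS3RNA": rel,
        "STAT5_dop": ErrorModel("constant", "sigma_dop"),
    }


def default_jakstat_design(cell_type: str = "cell_type_1") -> list:
    """Measurement design emulating the study's observation structure.

    Immunoblot/qRT-PCR-like observables on dense early/late schedules and a
    mass-spec-like degree-of-phosphorylation observable, plus an mRNA time
    course under transcription inhibition (30 min for the H838-like design,
    60 min for the CFU-E-like design).
    """
    # intensity-based observables start at 5 min: unstimulated phospho-signals
    # are zero and the log-normal error model needs positive values
    blot_times = [5, 10, 15, 20, 30, 40, 60, 90, 120]
    rna_times = [0, 20, 40, 60, 90, 120, 180, 240, 300]
    actd = "epo_actd_60" if cell_type.endswith("_1") else "epo_actd_30"
    return [
        {"cell_type": cell_type, "condition": "epo_stim", "observable": "pEPOR",
         "technique": "immunoblot", "times": blot_times},
        {"cell_type": cell_type, "condition": "epo_stim", "observable": "pJAK2",
         "technique": "immunoblot", "times": blot_times},
        {"cell_type": cell_type, "condition": "epo_stim", "observable": "pSTAT5",
         "technique": "immunoblot", "times": blot_times},
        {"cell_type": cell_type, "condition": "epo_stim",
         "observable": "STAT5_dop", "technique": "mass_spec",
         "times": [0, 10, 20, 30, 60, 120]},
        {"cell_type": cell_type, "condition": "epo_stim", "observable": "CISHRNA",
         "technique": "qRT-PCR", "times": rna_times},
        {"cell_type": cell_type, "condition": "epo_stim", "observable": "SOCS3RNA",
         "technique": "qRT-PCR", "times": rna_times},
        {"cell_type": cell_type, "condition": actd, "observable": "CISHRNA",
         "technique": "qRT-PCR", "times": rna_times},
        {"cell_type": cell_type, "condition": actd, "observable": "SOCS3RNA",
         "technique": "qRT-PCR", "times": rna_times},
    ]


def build_jakstat_smoke(seed: int = 0, fold_STAT5imp: float = 3.0,
                        testable=("JAK2actEPO", "STAT5imp", "CISHRNAturn")):
    """Reduced two-cell-type JAK2/STAT5 problem for a desk-scale joint fit.

    All parameters except the testable subset (plus one shared free rate)
    are fixed at their generating values; cell type 2 differs from cell
    type 1 in the STAT5 nuclear import rate by ``fold_STAT5imp`` and in the
    fixed EPOR-JAK2/STAT5 initial concentrations.  Returns
    ``(model, ds1, ds2, truth_folds)`` ready for ``build_joint_problem``.
    """
    import dataclasses as _dc

    base = build_jakstat_model()
    free = set(testable) | {"nSTAT5deact"}
    params = [
        _dc.replace(p, fixed=(p.fixed or (p.name in JAKSTAT_PARAM_NAMES
                                          and p.name not in free)))
        for p in base.params
    ]
    model = OdeModel(
        name="jakstat_smoke", states=list(base.states), params=params,
        odes=dict(base.odes), rates=dict(base.rates), x0=dict(base.x0),
        inputs=list(base.inputs), observables=list(base.observables),
        conditions=list(base.conditions),
    )
    truth_folds = {t: 1.0 for t in testable}
    truth_folds["STAT5imp"] = fold_STAT5imp
    p1 = model.default_values()
    names = model.param_names()
    p2 = p1.copy()
    p2[names.index("STAT5imp")] *= fold_STAT5imp
    for pname, (v1, v2) in JAKSTAT_FIXED_SPECIFIC.items():
        p1[names.index(pname)] = v1
        p2[names.index(pname)] = v2
    rng = np.random.default_rng(seed)
    # single-condition design: the joint fit stays desk-scale
    def stim_only(ct):
        return [e for e in default_jakstat_design(ct)
                if e["condition"] == "epo_stim"]
    ds1 = generate_jakstat_data(model, stim_only("cell_type_1"),
                                seed=int(rng.integers(2**31)), params=p1)
    ds2 = generate_jakstat_data(model, stim_only("cell_type_2"),
                                seed=int(rng.integers(2**31)), params=p2)
    return model, ds1, ds2, truth_folds


def generate_jakstat_data(model: OdeModel, design: list | None = None,
                          seed: int = 0, params=None,
                          sigma_rel: float = 0.15,
                          sigma_dop: float = 0.04) -> DataSet:
    """Seeded synthetic measurements for the JAK2/STAT5 example model.

    Relative (scaled) observables receive log-normal noise (multiplicative
    ``exp(sigma_rel * eps)``); degree-of-phosphorylation observables receive
    additive constant noise and are clipped back to [0, 1] (clipping is
    recorded in the DataSet attribute ``n_clipped``).
    """
    design = design if design is not None else default_jakstat_design()
    if params is None:
        params = model.default_values()
    ems = jakstat_error_models()
    rng = np.random.default_rng(seed)
    rows = []
    n_clipped = 0
    obs_names = {o.name for o in model.observables}
    for entry in design:
        if entry["observable"] not in obs_names:
            raise KeyError(f"design references unknown observable "
                           f"{entry['observable']!r}")
        cond = model.condition(entry["condition"])
        times = np.asarray(entry["times"], dtype=float)
        traj = simulate(model, params, cond, times)
        obs = model.observable(entry["observable"])
        fval, _ = obs.compiled(model.states)
        xs = [traj.states[:, j] for j in range(len(model.states))]
        raw = np.asarray(fval(xs), dtype=float) * np.ones(times.size)
        scale = 1.0
        if obs.scale_param:
            scale = model.natural_vector(params)[
                model.param_names().index(obs.scale_param)]
        clean = scale * raw
        em = ems[entry["observable"]]
        if em.kind == "lognormal_relative":
            noisy = clean * np.exp(rng.normal(0.0, sigma_rel, size=clean.size))
        else:
            noisy = clean + rng.normal(0.0, sigma_dop, size=clean.size)
            clipped = np.clip(noisy, 0.0, 1.0)
            n_clipped += int(np.sum(clipped != noisy))
            noisy = clipped
        for t, v in zip(times, noisy):
            rows.append({
                "cell_type": entry["cell_type"], "condition": entry["condition"],
                "observable": entry["observable"], "time_min": float(t),
                "value": float(v), "replicate": 1,
                "technique": entry.get("technique", ""),
            })
    ds = DataSet(pd.DataFrame(rows), ems)
    ds.n_clipped = n_clipped
    return ds
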