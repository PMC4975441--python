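# Methods

`odefold` detects cell type-specific parameters in ODE models of signaling
pathways. Two cell types share one model structure; cell type 1 carries
parameters `p_i` and cell type 2 carries `r_i · p_i`, with fold-changes
`r_i` estimated on the log10 scale (`d_i = log10 r_i`). The questions the
package answers are: which `d_i` are non-zero (which parameters differ
between the cell types), by how much, with what uncertainty, and which
parameters would an intervention hit hardest in each cell type.

## Model core

Models are declared symbolically: states, parameters, named rate
expressions, and per-state right-hand sides that may reference rate names.
sympy compiles the right-hand side, its state Jacobian, and its parameter
derivatives once per model; integration uses LSODA at relative/absolute
tolerance 1e-6 with the analytic Jacobian. Units are minutes and nM
throughout; nothing converts units.

Interventions (e.g. a transcription inhibitor) are events: from a stated
time onward the targeted rate (or input) is multiplied by `1 - efficiency`,
with efficiency bounded by 1. Since event times are known a priori, events
are realized by restarting the integration at each event time — no
root-finding is involved.

Forward sensitivities come from the augmented system
`dS/dt = (∂f/∂x) S + ∂f/∂p` with `S(0) = ∂x0/∂p`, integrated together with
the states. The Newton iteration matrix for the augmented system uses the
exact state block and the block-diagonal `I ⊗ (∂f/∂x)` sensitivity block;
the omitted second-derivative cross terms only affect corrector
convergence speed, never solution accuracy, because the error test is
unchanged. Sensitivities are reported on each parameter's estimation scale
(log10 for nearly all parameters), matching log-space estimation.

Steady-state initialization integrates the unstimulated system (all inputs
zero) over growing horizons until `‖f(x*)‖∞ < 1e-8`, re-checked by a
direct right-hand-side evaluation; sensitivities ride along, which handles
conservation laws correctly where an algebraic solve would face a singular
Jacobian. Equilibria are memoized per parameter vector, since all
stimulated conditions of a model share the same resting state.

A hard integration step budget (3000 steps per segment) makes hopeless
trial points — absurdly stiff corners of the log-uniform search box — fail
fast; the failure is surfaced to the optimizer as an infinite objective
rather than an error.

## Likelihood

Observations are `transform(scale · expr(states) + offset)`. Intensity-
based measurements (immunoblot, qRT-PCR) use a log-normal error model,
implemented as additive Gaussian noise on log-transformed values with σ on
that scale; degree-of-phosphorylation measurements use a constant error
model with σ capped at 0.05. One noise parameter is assigned per
(technique, observable, cell type). The objective is

    -2 log L = Σ_records [ (y − ŷ)² / σ_eff² + log(2π σ_eff²) ]

with residuals formed on log values for the log-normal kind. The
σ-dependent normalization term is included so noise parameters are
estimable by maximum likelihood; the data-only constant of the log-normal
density is dropped (it cancels in every likelihood-ratio difference).
Free σ parameters are updated by their closed-form conditional ML values
between least-squares passes (profile-σ scheme) rather than entering the
residual vector.

Under log-scale error models, predictions are floored at 1e-10 during
optimization; the floored region has zero prediction gradient. This keeps
the objective finite at trial points where a phospho-signal is numerically
zero instead of aborting the fit.

## Estimation

Each local fit is a bound-constrained trust-region-reflective least-squares
minimization in log10 parameter space (default bounds 1e-5 to 1e3),
terminated by the step-size criterion 1e-6 with the objective-change
criterion disabled (flat likelihood regions would otherwise stop runs
prematurely); an iteration cap of 1000 bounds runtime. Multi-starts draw
uniformly in log10 space within the bounds from a seeded generator, so
every result is reproducible from its seed. An estimate resting on a bound
is flagged; optionally the affected bounds are widened by one decade and
the fit repeated.

The full joint fit (all fold-changes free) is initialized the way the
two-cell-type design suggests: each cell type is estimated individually,
the combined vector (with `d_i` set to the difference of the individual
log10 estimates) seeds the joint optimization, plus optional random
multi-starts.

## L1 fold-change selection

The constrained objective is `C = L1 + L2 + λ Σ|d_i|` (L denoting
−2 log L). The penalized optimizer is a purpose-built orthant-aware
Levenberg–Marquardt loop: within one step each active `d_i` keeps its
sign — a step that would cross zero is truncated so the coordinate lands
exactly at 0 — and a coordinate resting at zero is released only when the
magnitude of its unpenalized likelihood gradient exceeds the penalty slope
λ (the subgradient optimality condition). Inactive fold-changes are
therefore stored as exact zeros, i.e. `r_i = 1` exactly.

λ is scanned ascending over a log-uniform grid (default 49 points on
[1e-4, 1e4]) with warm starts from the previous λ; a failed fit is retried
from the unpenalized solution and recorded. The path records per λ the
fold-change vector, the constrained objective, the unpenalized joint
−2 log L, and the number N of cell type-specific parameters.

Selection refits every distinct specificity pattern along the path
*without* regularization (non-selected `d_i` frozen at exactly zero — the
penalty is used only to propose patterns, never to bias estimates) and
applies the likelihood-ratio test `D = L_pattern − L_full` against
`χ²(M−N, 1−α)` with α = 0.05; the parsimonious model is the smallest-N
pattern that cannot be rejected, with ties at equal N broken by the
smaller D.

One robustness extension beyond the plain path procedure: the candidate
set at each N also contains the one-swap neighborhood of the path patterns
of that size (enabled by default for M ≤ 8). Strongly correlated
fold-change pairs can trade places on an L1 path — in the shipped cascade
example the k2 and k3 fold-changes are nearly collinear because pProtein
is unobserved — and the likelihood-ratio comparison, not the penalized
objective, is the arbiter the procedure trusts. Without this refinement
the path occasionally proposes the statistically inferior member of the
pair and the better same-N pattern is never examined.

An exhaustive oracle (`exhaustive_selection_oracle`) fits all 2^M patterns
for M ≤ 8 and serves as the independent reference the path procedure is
tested against.

## Profile-likelihood uncertainty

A profile fixes one coordinate on an adaptive grid around the MLE and
re-optimizes everything else, stepping until the objective rises Δ above
the optimum on each side (target rise 0.1 per step, steps clamped to
[1e-4, 0.5] log10 units). Crossings located by linear interpolation give
the interval; σ is approximated conservatively as the larger of the two
log10 distances between estimate and interval limit. Reported "factor ±
σ" values use Δ = 1 (pointwise 1σ), because the reported quantities are
standard deviations; 95% intervals use Δ = 3.841. A profile that never
crosses the threshold marks the parameter as non-identifiable: the
interval is open and σ is reported as a lower bound ("≥"), not an error.

Fold-change uncertainties are profiled in the *refit parsimonious model*
(non-selected fold-changes held at zero), which is also where the point
estimates come from.

## Control-coefficient sensitivity analysis

The readout K is the area under the curve of a chosen state up to a
horizon (default: nuclear phosphorylated STAT5 over 60 min, a
survival-associated quantity). K is computed by augmenting the ODE with a
quadrature state, and `S_i = (p_i/K) ∂K/∂p_i` comes from the forward
sensitivity of that state — no quadrature of sampled output is involved.
Derivatives enter on the natural parameter scale (converted from the
log10-scale sensitivities by the chain rule), making S dimensionless and
scale-free. Positive S means lowering the parameter lowers the readout.
Comparing |S| between two cell types flags parameters whose inhibition
hits cell type 2 harder — candidate selective intervention points.

## The synthetic cascade benchmark

The two-step phosphorylation cascade (Protein → pProtein ⇌ ppProtein) is
simulated for two cell types differing in the dephosphorylation rate k3
(0.5 vs 0.1 /min, a true factor of 5) and the initial protein
concentration (1 vs 2 nM, a true factor of 2), with additive Gaussian
noise σ = 0.1 nM on 21 Protein and 10 ppProtein samples per cell type;
pProtein is unobserved. k1, k2 and the sampling schedules are free design
choices of the benchmark (editable defaults):

* Schedules are quasi-log-spaced on [0, 25] min, denser early; the Protein
  and ppProtein schedules deliberately do not coincide.
* k1 = 1.0, k2 = 0.3 /min. This choice was made on an identifiability
  argument: the ppProtein relaxation rate is k2 + k3, and if that is much
  faster than the k1-limited influx the cascade stays in quasi-equilibrium
  and only the ratio k2/k3 is visible — the k2 and k3 fold-changes then
  become collinear and the whole detection task degenerates. With fast
  conversion (k1 = 1.0) and slow equilibration (k2 = 0.3) the relaxation
  is resolved by the schedule, and the profile standard deviations of the
  selected log10 fold-changes in the parsimonious refit are ≈ 0.12 (k3)
  and ≈ 0.03 ([Protein]0) — i.e. "factor ± σ" reports like 5.3 ± 1.4 and
  1.96 ± 0.14 at the default seed.

A structural caveat the benchmark makes explicit: because pProtein is
unobserved, a k3 decrease in cell type 2 can be mimicked by a k2 increase.
The noiseless deviance of the best such "imposter" fit is ≈ 5.2, *below*
the χ²₂ rejection threshold of 5.99 — the two explanations are not
statistically separable at α = 0.05 even with noise-free data at this
design. Across noise realizations the likelihood therefore genuinely
prefers the k2 parameterization in a minority (~10-15%) of runs, which
bounds any selector's exact-pattern recovery rate at roughly 85-90% under
these study conditions. The shipped tests measure and document exactly
this.

What the generator does not emulate: replicate structure beyond i.i.d.
noise, scale/offset nuisance parameters (the toy observes absolute
concentrations), missing values, or systematic (batch) effects. Passing
the benchmark shows the selection-and-refit machinery recovers known
differences at realistic noise; it does not certify performance on
relative, heteroscedastic real data.

## The JAK2/STAT5 example model

The generalized EPO-induced JAK2/STAT5 model is a runnable reconstruction:
23 states (EPO; four receptor-complex phospho-states; PTP and active PTP;
cytoplasmic/nuclear STAT5 species; per gene, four transcriptional delay
intermediates, mRNA, and feedback protein) and the 26-parameter catalogue
(25 kinetic parameters plus the initial PTP concentration). EPO activates
JAK2 in the EPOR–JAK2 complex, active JAK2 phosphorylates the receptor,
and PTP — activated by phosphorylated receptor complexes — reverses both
steps. Activated STAT5 is imported into the nucleus, dephosphorylated
there, and exported. CISH transcription is linear in nuclear pSTAT5; SOCS3
transcription follows a Hill function (coefficient fixed at 2, half-max
fixed at 0.2 nM — the nonlinearity is structural, its shape parameters are
not estimated); both genes have basal transcription, so a transcription
block also depletes resting mRNA. SOCS3 inhibits JAK2 activation and CIS
inhibits receptor phosphorylation, each through `1/(1 + strength ·
concentration)`. Turnover (`*turn`), equilibrium-concentration (`*eqm`),
delay (`*delay`), inhibition-strength (`*inh`) and promoter-activity
(`SOCS3prom`) parameters each play exactly the role their name states.

The rate-law algebra is this package's own reconstruction of the described
mechanism, intended for structural realism (phospho-transients, delayed
mRNA peaks, feedback attenuation, inhibitor-event responses) — not for
numerical reproduction of any measured data set. The EPOR–JAK2 and STAT5
initial concentrations, fixed per cell type, are synthetic representative
constants. Delay-chain length (4 intermediates per mRNA) is configurable.

The desk-scale joint-fit demonstration (`build_jakstat_smoke`) frees a
three-parameter testable subset (plus one shared rate), differing between
the synthetic cell types in the STAT5 import rate by a factor 3, and runs
the full scan/select machinery on a 5-point λ grid in about half a minute.

## Problem sizes and numerical defaults

The shipped studies use: 49-point λ grids for the cascade benchmark
(5-point for the signaling smoke test); 50 regenerated studies for the
selection-rate and recovery checks and 100 for profile-interval coverage;
3 multi-starts per individual cell-type fit (the cascade landscape is
benign — roughly every second random start reaches the optimum — and the
combined individual fits seed the joint problem deterministically);
verification oracles (closed forms, finite differences) run the solver at
1e-9..1e-13 tolerances so that solver noise sits below the asserted
agreement bounds, while all estimation runs at the standard 1e-6.

Known limitations: two cell types only (the design does not preclude more,
but the contract is pairwise); no prediction-band machinery for model
forecasts (parameter-ensemble simulation is the suggested approximation);
no correlated-error or outlier-robust likelihoods; delays only as linear
chains; events must have known times.
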