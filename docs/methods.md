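# Methods

## Dose-toxicity models and priors

The primary working model is the one-parameter power ("empiric") model

    ψ(dᵢ, β) = dᵢ^exp(β),      β ~ N(μ₀, σ₀²),

where the standardized dose labels dᵢ ∈ (0,1) are the *skeleton* — the
prior guesses of the per-dose DLT probabilities. The default prior is
N(0, 1.34), the widely used least-informative operational prior for
this model ("1.34" is the variance). `make_skeleton` builds a skeleton
by the indifference-interval recursion: the prior MTD is anchored at
the target γ, and each neighbor is placed so that, under the slope that
maps the current dose to toxicity γ∓h, the neighbor's toxicity is γ±h.
The half-width h (default 0.05 in the factory setups) controls skeleton
spacing. The construction is cross-checked in the test suite against an
independent root-finding implementation of the same recursion.

The EWOC-family and BLRM comparators use the two-parameter logistic
model ψ(d, β₁, β₂) = expit(β₁ + β₂ d) with a bivariate normal prior.
No canonical prior exists for every dose grid, so the prior is a config
input; the package default is mean (0, 1) with covariance diag(4, 1) on
(intercept, slope) — weakly informative, slope centered on a positive
value to respect monotonicity a priori.

## Posterior computation

Posteriors are represented by deterministic grid quadrature
(`PosteriorState`): nodes span the prior mean ± k·sd (default k = 8)
with N = 2001 nodes in 1-D (201 per axis in 2-D), carrying normalized
log-weights. Updates multiply in the Bernoulli likelihood of per-dose
(patients, DLTs) totals in log space (with `xlogy`/`xlog1py` so that
doses with no events remain well-defined where ψ underflows) and
renormalize by log-sum-exp. This makes every trial exactly replayable,
and accuracy is checkable by brute force: the suite verifies posterior
mean probabilities against a 10⁶-node direct quadrature to 1e-6, and
that doubling the node count moves them by less than 1e-8. If the data
annihilate every node (possible only for pathological model/grid
combinations), the update raises with a diagnostic rather than
returning a spurious state.

## Allocation criteria

All criteria are pure functions on the unit interval, minimized at the
target γ:

* squared distance (p − γ)²;
* Aitchison distance (logit p − logit γ)², natural logs;
* CIBP divergence (p − γ)² / (pᵃ(1−p)^(2−a)), 0 < a < 2, equal to the
  squared distance over the Bernoulli variance at a = 1 and infinite at
  p ∈ {0, 1};
* its absolute-distance variant |p − γ| / (pᵃ(1−p)^(2−a));
* the EWOC asymmetric linear loss α(γ−p)⁺ + (1−α)(p−γ)⁺;
* an interval ("BLRM") loss table, by default 1/0/1/2 on
  (0,0.26)/(0.26,0.41)/(0.41,0.66)/(0.66,1) for a 0.33 target, with
  right-open intervals (a measure-zero convention fixed for
  determinism).

### Choosing the asymmetry parameter

`asymmetry_from_interval(γ, θ)` returns the a for which the CIBP
divergence is equal at γ−θ and γ+θ: a = 2/(1+A) with
A = log((γ−θ)/(γ+θ)) / log((1−γ−θ)/(1−γ+θ)). θ is the half-width of
the interval of toxicity estimates in which the safer of two
equidistant estimates is always preferred; θ→0 recovers a = 2γ
(squared-distance-like allocation) and θ→γ gives strongly conservative
a. Logs are natural; A is a ratio of logs, so the value of a is
base-invariant.

### Infinite values and the score cap

The CIBP divergence is unbounded at the interval bounds — that is the
point: allocation is driven away from doses whose probability mass sits
near 0 or 1. It has, however, a consequence for posterior expectations
under the power model: in any trial state with *no DLTs observed yet*,
the exact posterior expectation of the divergence is +∞ for every dose,
because toward β → +∞ the integrand grows like exp(a·e^β·|ln d|) while
only a DLT likelihood factor decays fast enough to suppress it.
Allocation scores therefore cap per-node criterion values at a large
finite sentinel (10¹²). In DLT-free states the capped scores are
dominated by the safe tail, where the divergence is pointwise
decreasing in the dose — so the design escalates (subject to the
constraints below), which is also what the uncapped ordering would
dictate node by node. Once any DLT has been observed the cap is inert:
the likelihood suppresses the tail double-exponentially and scores
equal the exact expectations. Any finite score always sorts below the
sentinel, so boundary-heavy doses are never selected over interior
ones.

### Posterior-expected vs plug-in allocation

The CIBP design allocates by the posterior mean of the criterion,
E[δ(ψ(dᵢ, β), γ)], not by plugging the posterior mean probability into
δ: the expectation is what lets the criterion feel the estimate's
uncertainty. Plug-in mode (`allocation="plugin"`) is provided because
at a = 2γ plug-in CIBP reproduces squared-distance allocation — an
equivalence that is exact only locally around the target (the
denominator is maximized, and flat, at γ but not symmetric about it),
and is verified in the tests on monotone dose-toxicity-like
configurations without near-ties.

## Designs and escalation constraints

`next_dose` minimizes the design's score over doses (ties to the lowest
index — the safety-conservative, deterministic choice) and then applies:

* **no skipping**: the candidate may not exceed the highest dose ever
  administered plus one;
* **start lowest**: the first cohort goes to dose 1;
* **coherence**: the design never escalates immediately after a cohort
  containing at least one DLT. This is the standard coherence principle
  for cohort-based CRM designs; staying and de-escalating are always
  allowed. It applies to every design in the registry so that design
  comparisons differ only in the criterion.

CRM(M) restricts the admissible set to doses with estimated toxicity
strictly below γ and falls back to the lowest dose when that set is
empty (early in toxic trials the restriction would otherwise leave no
dose). The EWOC family shares the asymmetric linear loss with a
feasibility bound α that is fixed (EWOC, default 0.25), increases with
patient number (TR: 0.25 through patient 9, then +0.05 per patient,
capped at 0.50), or increases with the number of DLT-free patients
(TDFB: α = min(cap, α_min + (cap − α_min)(n − 1 − Σy)/S)). The TDFB
scale S is a required design parameter; the registry default is
S = 12.0, chosen once as a mid-range value at which the bound relaxes
over roughly the first half of a 40-patient trial. Schedules are
indexed by the number of the patient about to be enrolled. The final
MTD for every design is the unconstrained squared-distance argmin of
the posterior mean probabilities; a trial stopped for safety declares
no MTD.

## Trial engine

`run_trial` executes cohorts (default size 3) until a stopping rule
fires: maximum sample size, or a full cohort at the *lowest* dose all
experiencing DLTs (the safety stop; an all-toxic cohort at a higher
dose triggers de-escalation, not termination). Outcomes come either
from a scenario (true per-dose probabilities, sampled with a
counter-based Philox generator keyed by an explicit seed, so records
are reproducible across platforms and parallel layouts) or from fixed
per-dose outcome streams consumed in administration order — the replay
mode. The record keeps, per cohort, the dose, outcomes, posterior mean
probabilities after the update, and the recommendation, plus totals,
stop reason and final MTD; it serializes to JSON.

The bundled Everolimus fixture stores the trial's aggregated totals
(6/17/10 patients, 3/6/7 DLTs at the three regimens), the skeleton
(0.20, 0.30, 0.40), γ = 0.30, the N(0, 1.34) prior, and canonical
per-dose outcome streams. Within-cohort outcome order never affects the
posterior; the split of the three mid-dose DLTs across the two
consecutive de-escalation cohorts of the replay (1 then 2) is a
reconstruction consistent with the aggregated totals and the replayed
pathway, not a recorded sequence.

## Operating-characteristics simulation

`simulate_oc` runs independent replicate trials per (design, scenario)
cell. Replicate seeds derive from `SeedSequence(base_seed,
spawn_key=(design, scenario, replicate))`, so results are independent
of any parallel execution layout. Reported metrics: per-dose selection
probabilities πᵢ, PCS (the mass on the scenario's true MTD), the
accuracy index 𝒜 = 1 − m·Σ(pᵢ−γ)²πᵢ / Σ(pᵢ−γ)² (1 when all mass sits
at the target, 0 for uniform selection, negative when selections
concentrate on the worst doses; undefined and raising when every true
probability equals γ), mean DLTs and patients, each with Monte-Carlo
standard errors. Replicates stopped for safety contribute *no
selection*: they reduce every πᵢ and hence PCS. This convention is a
deliberate choice — counting safety stops as successes would reward
designs for terminating — and it makes Σπᵢ ≤ 1. Cross-scenario
aggregation uses geometric means for 𝒜 and PCS and the arithmetic mean
for DLT counts; nonpositive values abort geometric aggregation with an
error rather than silently dropping scenarios. The default replication
count is 2000; the test suite uses 500 replicates on 6-dose, 30-patient
setups, which resolves the qualitative contrasts it asserts (the
safety ordering in a, plug-in CIBP(2γ) vs CRM agreement) well beyond
their Monte-Carlo error.

### Scenario generator

`generate_scenarios` emulates monotone dose-toxicity curves: the
designated MTD is anchored at exactly γ and the other doses are placed
at logit-scale steps drawn uniformly from steepness·[0.5, 1.5] per
level — roughly halving-to-doubling the odds per dose at the default
steepness of 1.0, which is the spacing real dose grids aim for. What
the generator does not emulate: non-monotone curves, plateaus,
patient-level heterogeneity or covariates, and delayed or graded
toxicities. Passing simulations therefore demonstrate correct design
behavior under clean monotone single-agent conditions, not robustness
to model misspecification beyond curve shape.

## Numerical conventions

* Grid quadrature: N = 2001 nodes (1-D), 201² (2-D), range mean ± 8 sd;
  log-space weights with log-sum-exp renormalization.
* Criterion score cap 10¹² per node (see above); ties in every argmin
  break to the lowest dose; BLRM intervals right-open with p = 1 in the
  last interval.
* Aitchison distance and the asymmetry calibration use natural logs.
* RNG: numpy Philox (counter-based) with explicit seeds recorded in
  every trial record; per-replicate seeds below 2³¹.

## Known limitations

* The posterior-expected CIBP score is a regularized quantity in
  DLT-free states (see the cap discussion): its numerical value there
  is cap-dependent even though the induced dose ordering is not.
* The equivalence of plug-in CIBP(2γ) and squared-distance allocation
  is local to the target's neighborhood and is asserted only for
  monotone configurations without near-ties.
* BLRM and EWOC-family results depend on the logistic prior and dose
  covariates supplied in the config; the package defaults are
  documented above but are not canonical values.
* Discrete doses only; no continuous-dose EWOC, no dose-combination or
  dose-schedule extensions, no time-to-event outcomes.
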