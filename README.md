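# cibpcrm

Bayesian phase I dose-escalation designs built around the **convex
infinite bounds penalization (CIBP)** allocation criterion, with the
classical continual reassessment method (CRM) and the main model-based
comparators (CRM(M), EWOC, TR, TDFB, BLRM), a deterministic trial-replay
engine, and an operating-characteristics simulator.

## The problem

A phase I oncology trial seeks the maximum tolerated dose (MTD): the
dose whose probability of a dose-limiting toxicity (DLT) is closest to a
target γ (typically 0.2–0.33). Model-based designs such as the CRM fit a
dose-toxicity model after every cohort and treat the next cohort at the
dose minimizing a criterion in the estimated DLT probability p̂ᵢ —
classically the squared distance

    (p̂ᵢ − γ)².

The squared distance ignores two things: the *uncertainty* of the
estimates (probabilities near 0.5 are estimated less precisely than
probabilities near the boundaries), and the *ethical asymmetry* between
overdosing and underdosing. The CIBP criterion addresses both by
penalizing deviations relative to a variance-like denominator that blows
up at the boundaries of the unit interval:

    δ(p, γ) = (p − γ)² / ( pᵃ (1 − p)^(2−a) ),   0 < a < 2.

At `a = 1` the denominator is the Bernoulli variance `p(1 − p)` and the
criterion is symmetric on the logit scale. Smaller `a` penalizes overly
toxic doses more severely; `a = 2γ` approximately reproduces
squared-distance allocation, and `a` can be calibrated from an
*indifference half-width* θ — the width of the interval of toxicity
estimates inside which the clinician always prefers the safer dose
(`cibpcrm.asymmetry_from_interval`).

Embedded in a Bayesian CRM with the one-parameter power model
`ψ(d, β) = d^exp(β)`, the next cohort goes to the dose minimizing the
*posterior expectation* of δ; the final MTD is always selected by the
plain squared distance — conservatism matters during the trial, accuracy
at the end.

## Worked example: replaying an Everolimus combination trial

The package ships the data of a real phase I trial of Everolimus plus
Paclitaxel/Trastuzumab (three regimens, target γ = 0.30; 6, 17 and 10
patients treated with 3, 6 and 7 DLTs). `cibpcrm replay` re-runs the
trial cohort by cohort against fixed per-dose outcome streams, once with
the squared-distance CRM and once with CIBP(a = 0.3):

```
$ cibpcrm replay
CRM: d1 -> d2 -> d2 -> d3 -> d2 -> d2 -> d1
  21 patients, 10 DLTs, stop: lowest_dose_all_tox
CIBP(0.3): d1 -> d2 -> d2 -> d3 -> d1
  15 patients, 7 DLTs, stop: lowest_dose_all_tox
```

Both trials start at the lowest dose, escalate after a clean first
cohort, and are eventually stopped for safety when a full cohort at the
lowest dose all experience DLTs. The CRM needs 21 patients (10 DLTs) to
reach that conclusion; the conservative CIBP criterion de-escalates
sooner and stops after 15 patients (7 DLTs). The same run is available
in the library:

```python
from cibpcrm import everolimus_fixture, run_trial, standard_design

fx = everolimus_fixture()
design = standard_design("CIBP", fx.model, fx.gamma, a=0.3)
record = run_trial(design, fx.source, fx.cohort_size, fx.stopping)
print(record.doses_administered)   # (1, 2, 2, 3, 1)
print(record.n_patients, record.n_dlts)  # 15 7
```

## Operating characteristics

`cibpcrm simulate --config cfg.yaml` runs replicated trials over
dose-toxicity scenarios and reports, per design and scenario, the
selection probabilities, the proportion of correct selections (PCS), the
accuracy index

    𝒜 = 1 − m · Σᵢ (pᵢ − γ)² πᵢ / Σᵢ (pᵢ − γ)²,

and DLT summaries, with Monte-Carlo standard errors, plus cross-scenario
aggregates (geometric means of 𝒜 and PCS, arithmetic mean DLTs). A
scenario generator (`cibpcrm scenarios`) produces monotone logistic-
shaped toxicity curves with the MTD anchored at a chosen position.
Smaller asymmetry parameters trade a little selection accuracy for
materially fewer toxic responses; see `docs/methods.md` for the model,
the calibration of `a`, and all numerical conventions.

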