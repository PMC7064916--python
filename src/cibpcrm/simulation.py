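"""Operating-characteristics simulation for dose-escalation designs.

For each (design, scenario) cell, ``simulate_oc`` runs independent
replicate trials and summarizes

* the per-dose selection probabilities ``pi_i`` and the proportion of
  correct selections (PCS, the mass on the true MTD),
* the accuracy index
  ``A = 1 - m * sum((p_i - gamma)**2 * pi_i) / sum((p_i - gamma)**2)``,
  which weights wrong selections by how far their true toxicity lies
  from the target (1 for always selecting at the target, 0 for uniform
  selection),
* DLT and patient-allocation summaries,

each with Monte-Carlo standard errors.  Replicates that stop for
safety without declaring an MTD contribute *no selection*: they lower
every ``pi_i`` (and hence PCS), a deliberate and documented convention.

Cross-scenario aggregation uses geometric means for accuracy and PCS
and the arithmetic mean for DLT counts.

Replicate seeds are derived per (design, scenario, replicate) with
``numpy.random.SeedSequence``, so results are independent of any
parallel execution layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .designs import DesignSpec
from .trial_engine import OutcomeSource, StoppingRule, StopReason, TrialRecord, run_trial
from .dose_models import GridSpec

__all__ = [
    "Scenario",
    "OCResult",
    "accuracy_index",
    "pcs",
    "simulate_oc",
    "aggregate_oc",
    "generate_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """True dose-toxicity curve: per-dose DLT probabilities and the target.

    ``mtd_index`` (1-based) is derived: the dose whose true probability
    is closest to the target (lowest index on ties).
    """

    name: str
    probs: tuple[float, ...]
    gamma: float

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("scenario probabilities must lie in [0, 1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("scenario probabilities must be monotone nondecreasing")

    @property
    def mtd_index(self) -> int:
        d = (np.asarray(self.probs) - self.gamma) ** 2
        return int(np.argmin(d)) + 1

    @property
    def n_doses(self) -> int:
        return len(self.probs)


def accuracy_index(pi: Sequence[float], probs: Sequence[float], gamma: float) -> float:
    """Selection-quality index ``1 - m sum((p_i-gamma)^2 pi_i) / sum((p_i-gamma)^2)``.

    Equals 1 when all selection mass sits on doses with true toxicity
    exactly at the target and 0 for uniform selection; can be negative
    when selections concentrate on the worst doses.
    """
    pi = np.asarray(pi, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if pi.shape != probs.shape or probs.size < 2:
        raise ValueError("pi and probs must have equal length >= 2")
    if pi.sum() > 1.0 + 1e-9 or np.any(pi < 0):
        raise ValueError("pi must be selection probabilities summing to at most 1")
    d2 = (probs - gamma) ** 2
    denom = d2.sum()
    if denom == 0.0:
        raise ValueError("accuracy index undefined: every dose has true toxicity gamma")
    return float(1.0 - probs.size * (d2 @ pi) / denom)


def pcs(selections: Sequence[int | None], mtd_index: int) -> float:
    """Proportion of replicates selecting the true MTD; ``None`` counts as incorrect."""
    if len(selections) == 0:
        raise ValueError("selections must be nonempty")
    return sum(1 for s in selections if s == mtd_index) / len(selections)


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics of one design on one scenario."""

    design_name: str
    scenario: Scenario
    n_reps: int
    base_seed: int
    selection_probs: tuple[float, ...]
    no_selection_rate: float
    pcs: float
    pcs_se: float
    accuracy: float
    mean_dlts: float
    dlts_se: float
    mean_patients: float
    mean_patients_per_dose: tuple[float, ...]

    def to_row(self) -> dict:
        row = {
            "design": self.design_name,
            "scenario": self.scenario.name,
            "mtd_index": self.scenario.mtd_index,
            "n_reps": self.n_reps,
            "pcs": self.pcs,
            "pcs_se": self.pcs_se,
            "accuracy": self.accuracy,
            "mean_dlts": self.mean_dlts,
            "dlts_se": self.dlts_se,
            "mean_patients": self.mean_patients,
            "no_selection_rate": self.no_selection_rate,
        }
        for i, p in enumerate(self.selection_probs, start=1):
            row[f"pi_{i}"] = p
        return row


def _rep_seed(base_seed: int, design_idx: int, scenario_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(design_idx, scenario_idx, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_oc(
    designs: Sequence[DesignSpec],
    scenarios: Sequence[Scenario],
    n_reps: int = 2000,
    base_seed: int = 0,
    cohort_size: int = 3,
    max_patients: int = 30,
    grid: GridSpec | None = None,
    stop_if_lowest_cohort_all_tox: bool = True,
    keep_records: bool = False,
) -> list[OCResult] | tuple[list[OCResult], dict]:
    """Run ``n_reps`` replicate trials for every (design, scenario) cell.

    Returns one :class:`OCResult` per cell (row-major in the design,
    then scenario order).  With ``keep_records`` the raw
    :class:`~cibpcrm.trial_engine.TrialRecord` lists are returned too,
    keyed by ``(design_name, scenario_name)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    stopping = StoppingRule(max_patients, stop_if_lowest_cohort_all_tox)
    results: list[OCResult] = []
    records: dict[tuple[str, str], list[TrialRecord]] = {}
    for di, design in enumerate(designs):
        for si, scenario in enumerate(scenarios):
            m = scenario.n_doses
            selections: list[int | None] = []
            dlts = np.zeros(n_reps)
            patients = np.zeros(n_reps)
            per_dose = np.zeros(m)
            cell: list[TrialRecord] = []
            for rep in range(n_reps):
                seed = _rep_seed(base_seed, di, si, rep)
                source = OutcomeSource.from_scenario(scenario.probs, seed)
                rec = run_trial(design, source, cohort_size, stopping, grid)
                selections.append(rec.final_mtd)
                dlts[rep] = rec.n_dlts
                patients[rep] = rec.n_patients
                per_dose += rec.patients_per_dose(m)
                if keep_records:
                    cell.append(rec)
            pi = tuple(
                sum(1 for s in selections if s == i + 1) / n_reps for i in range(m)
            )
            p_correct = pcs(selections, scenario.mtd_index)
            results.append(
                OCResult(
                    design_name=design.name.value,
                    scenario=scenario,
                    n_reps=n_reps,
                    base_seed=base_seed,
                    selection_probs=pi,
                    no_selection_rate=1.0 - sum(pi),
                    pcs=p_correct,
                    pcs_se=math.sqrt(max(p_correct * (1 - p_correct), 0.0) / n_reps),
                    accuracy=accuracy_index(pi, scenario.probs, scenario.gamma),
                    mean_dlts=float(dlts.mean()),
                    dlts_se=float(dlts.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else float("nan"),
                    mean_patients=float(patients.mean()),
                    mean_patients_per_dose=tuple(per_dose / n_reps),
                )
            )
            if keep_records:
                records[(design.name.value, scenario.name)] = cell
    if keep_records:
        return results, records
    return results


def aggregate_oc(results: Sequence[OCResult]) -> list[dict]:
    """Cross-scenario aggregates per design.

    Geometric means for accuracy and PCS, arithmetic mean for DLTs.  A
    nonpositive accuracy or PCS makes the geometric mean meaningless
    and raises.
    """
    by_design: dict[str, list[OCResult]] = {}
    for r in results:
        by_design.setdefault(r.design_name, []).append(r)
    rows = []
    for name, rs in by_design.items():
        acc = np.array([r.accuracy for r in rs])
        p = np.array([r.pcs for r in rs])
        if np.any(acc <= 0.0) or np.any(p <= 0.0):
            raise ValueError(
                f"design {name}: nonpositive accuracy or PCS in some scenario; "
                "geometric-mean aggregation is undefined"
            )
        rows.append(
            {
                "design": name,
                "n_scenarios": len(rs),
                "geomean_accuracy": float(np.exp(np.mean(np.log(acc)))),
                "geomean_pcs": float(np.exp(np.mean(np.log(p)))),
                "mean_dlts": float(np.mean([r.mean_dlts for r in rs])),
            }
        )
    return rows


def generate_scenarios(
    m: int,
    gamma: float,
    mtd_positions: Sequence[int],
    steepness: float = 1.0,
    seed: int = 0,
) -> list[Scenario]:
    """Synthetic monotone dose-toxicity scenarios with a designated MTD.

    Each scenario anchors the dose at ``mtd_position`` to DLT
    probability exactly ``gamma`` and places the other doses at
    logit-scale distances drawn uniformly from
    ``steepness * [0.5, 1.5]`` per step, giving strictly increasing,
    realistically spaced curves (steepness 1.0 roughly doubles/halves
    the odds per dose level).  The anchor makes the designated dose the
    unique MTD by construction.
    """
    if steepness <= 0.0:
        raise ValueError("steepness must be positive")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must lie in (0, 1)")
    rng = np.random.Generator(np.random.Philox(seed))
    base = math.log(gamma / (1.0 - gamma))
    scenarios = []
    for pos in mtd_positions:
        if not (1 <= pos <= m):
            raise ValueError(f"mtd_position {pos} outside 1..{m}")
        gaps = steepness * rng.uniform(0.5, 1.5, size=m - 1)
        logits = np.zeros(m)
        for i in range(pos, m):
            logits[i] = logits[i - 1] + gaps[i - 1]
        for i in range(pos - 2, -1, -1):
            logits[i] = logits[i + 1] - gaps[i]
        probs = 1.0 / (1.0 + np.exp(-(base + logits)))
        probs[pos - 1] = gamma  # exact anchor
        scenarios.append(Scenario(name=f"mtd{pos}", probs=tuple(probs), gamma=gamma))
    return scenarios
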