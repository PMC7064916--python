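"""Sequential cohort-by-cohort execution of a dose-escalation trial.

A trial starts at the lowest dose, observes each cohort's binary DLT
outcomes, updates the posterior over the working-model parameters, and
asks the design for the next dose, until a stopping rule fires.  The
outcomes come from an :class:`OutcomeSource`, which is either

* a *scenario*: a vector of true per-dose DLT probabilities sampled
  with a counter-based RNG (Philox) so every trial is exactly
  reproducible from its seed, or
* *fixed streams*: pre-specified per-dose outcome sequences consumed in
  administration order, used to replay an observed trial.

The engine records a complete audit trail (:class:`TrialRecord`):
cohort allocations, outcomes, per-cohort posterior mean probabilities,
the recommendation after each cohort, the stop reason, and the final
MTD.  When a trial stops for safety (a full cohort at the lowest dose
all with DLTs) no MTD is declared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .designs import DesignSpec, next_dose, select_mtd
from .dose_models import (
    GridSpec,
    ObservationSet,
    PosteriorState,
    PowerModelSpec,
    Skeleton,
    init_posterior,
    posterior_mean_prob,
    update_posterior,
)

__all__ = [
    "OutcomeSource",
    "StoppingRule",
    "StopReason",
    "CohortRecord",
    "TrialRecord",
    "run_trial",
    "everolimus_fixture",
    "EverolimusFixture",
]


class StopReason(str, Enum):
    MAX_N = "max_n"
    LOWEST_DOSE_ALL_TOX = "lowest_dose_all_tox"
    STREAM_EXHAUSTED = "stream_exhausted"


@dataclass(frozen=True)
class OutcomeSource:
    """Where cohort outcomes come from.

    Exactly one of ``scenario`` (true DLT probabilities, sampled with
    the trial RNG) or ``streams`` (fixed per-dose outcome lists, keyed
    by 1-based dose index) must be given.
    """

    scenario: tuple[float, ...] | None = None
    streams: Mapping[int, Sequence[int]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.streams is None):
            raise ValueError("give exactly one of scenario or streams")
        if self.scenario is not None:
            probs = tuple(float(p) for p in self.scenario)
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValueError("scenario probabilities must lie in [0, 1]")
            object.__setattr__(self, "scenario", probs)
        else:
            streams = {int(k): tuple(int(y) for y in v) for k, v in self.streams.items()}
            if any(y not in (0, 1) for v in streams.values() for y in v):
                raise ValueError("stream outcomes must be 0 or 1")
            object.__setattr__(self, "streams", streams)

    @property
    def n_doses(self) -> int | None:
        if self.scenario is not None:
            return len(self.scenario)
        return max(self.streams) if self.streams else 0

    @classmethod
    def from_scenario(cls, probs: Sequence[float], seed: int) -> "OutcomeSource":
        return cls(scenario=tuple(probs), seed=seed)

    @classmethod
    def from_streams(cls, streams: Mapping[int, Sequence[int]]) -> "OutcomeSource":
        return cls(streams=streams)


@dataclass(frozen=True)
class StoppingRule:
    """When the trial ends.

    ``stop_if_lowest_cohort_all_tox`` models the clinician terminating
    for safety once a full cohort at the *lowest* dose all experience
    DLTs; an all-toxic cohort at a higher dose only triggers
    de-escalation.
    """

    max_patients: int
    stop_if_lowest_cohort_all_tox: bool = True

    def __post_init__(self) -> None:
        if self.max_patients < 1:
            raise ValueError("max_patients must be positive")


@dataclass(frozen=True)
class CohortRecord:
    cohort_index: int  # 1-based
    dose: int  # 1-based
    outcomes: tuple[int, ...]
    posterior_mean_probs: tuple[float, ...]  # after this cohort's update
    recommended_next: int | None  # None when the trial stops here


@dataclass(frozen=True)
class TrialRecord:
    """Complete, replayable audit trail of one trial."""

    design_name: str
    cohorts: tuple[CohortRecord, ...]
    stop_reason: StopReason
    final_mtd: int | None
    seed: int | None = None

    @property
    def doses_administered(self) -> tuple[int, ...]:
        return tuple(c.dose for c in self.cohorts)

    @property
    def last_cohort_had_dlt(self) -> bool:
        return bool(self.cohorts) and any(self.cohorts[-1].outcomes)

    @property
    def n_patients(self) -> int:
        return sum(len(c.outcomes) for c in self.cohorts)

    @property
    def n_dlts(self) -> int:
        return sum(sum(c.outcomes) for c in self.cohorts)

    def patients_per_dose(self, m: int) -> np.ndarray:
        out = np.zeros(m, dtype=int)
        for c in self.cohorts:
            out[c.dose - 1] += len(c.outcomes)
        return out

    def to_dict(self) -> dict:
        return {
            "schema": "cibpcrm.trial_record/1",
            "design": self.design_name,
            "seed": self.seed,
            "stop_reason": self.stop_reason.value,
            "final_mtd": self.final_mtd,
            "n_patients": self.n_patients,
            "n_dlts": self.n_dlts,
            "cohorts": [
                {
                    "cohort": c.cohort_index,
                    "dose": c.dose,
                    "outcomes": list(c.outcomes),
                    "posterior_mean_probs": list(c.posterior_mean_probs),
                    "recommended_next": c.recommended_next,
                }
                for c in self.cohorts
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_frame(self):
        """Flat per-cohort table (one row per cohort) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cohort": c.cohort_index,
                "dose": c.dose,
                "n": len(c.outcomes),
                "dlts": sum(c.outcomes),
                "recommended_next": c.recommended_next,
                **{
                    f"p_hat_{i+1}": p
                    for i, p in enumerate(c.posterior_mean_probs)
                },
            }
            for c in self.cohorts
        )


class _LiveHistory:
    """Mutable view of the trial so far, duck-typed for the designs module."""

    def __init__(self) -> None:
        self.doses_administered: list[int] = []
        self.n_patients = 0
        self.n_dlts = 0
        self.last_cohort_had_dlt = False

    def add(self, dose: int, outcomes: Sequence[int]) -> None:
        self.doses_administered.append(dose)
        self.n_patients += len(outcomes)
        self.n_dlts += int(sum(outcomes))
        self.last_cohort_had_dlt = any(outcomes)


def _draw_cohort(
    source: OutcomeSource,
    dose: int,
    size: int,
    rng: np.random.Generator | None,
    cursor: dict[int, int],
) -> list[int]:
    """Outcomes for one cohort; may return fewer than ``size`` if a stream runs dry."""
    if source.scenario is not None:
        p = source.scenario[dose - 1]
        return [int(y) for y in rng.random(size) < p]
    stream = source.streams.get(dose, ())
    start = cursor.get(dose, 0)
    taken = list(stream[start : start + size])
    cursor[dose] = start + len(taken)
    return taken


def run_trial(
    design: DesignSpec,
    source: OutcomeSource,
    cohort_size: int,
    stopping: StoppingRule,
    grid: GridSpec | None = None,
) -> TrialRecord:
    """Execute one trial and return its record.

    The first cohort goes to the lowest dose (when the design's
    constraints say so); each subsequent cohort to the design's
    constrained criterion argmin.  Scenario outcomes use a Philox
    counter-based generator keyed by ``source.seed``.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be positive")
    m = design.model.n_doses
    if source.scenario is not None and len(source.scenario) != m:
        raise ValueError(
            f"scenario has {len(source.scenario)} doses but the model has {m}"
        )
    if stopping.max_patients % cohort_size:
        import warnings

        warnings.warn(
            f"max_patients={stopping.max_patients} is not a multiple of cohort_size={cohort_size}",
            stacklevel=2,
        )
    rng = None
    if source.scenario is not None:
        if source.seed is None:
            raise ValueError("scenario sources require a seed")
        rng = np.random.Generator(np.random.Philox(source.seed))

    state = init_posterior(design.model, grid)
    history = _LiveHistory()
    cursor: dict[int, int] = {}
    cohorts: list[CohortRecord] = []
    dose = next_dose(design, state, history)  # empty history: dose 1 under start_lowest

    while True:
        outcomes = _draw_cohort(source, dose, cohort_size, rng, cursor)
        stop: StopReason | None = None
        if not outcomes:
            stop = StopReason.STREAM_EXHAUSTED
            # nothing was observed for this cohort; do not record it
            if not cohorts:
                raise RuntimeError("outcome source empty at the first cohort")
            last = cohorts[-1]
            cohorts[-1] = CohortRecord(
                last.cohort_index, last.dose, last.outcomes, last.posterior_mean_probs, None
            )
            final = select_mtd(state, design.gamma)
            return TrialRecord(design.name.value, tuple(cohorts), stop, final, source.seed)

        state = update_posterior(
            state, ObservationSet(tuple((dose, y) for y in outcomes))
        )
        history.add(dose, outcomes)
        p_hat = tuple(posterior_mean_prob(state, i + 1) for i in range(m))

        if len(outcomes) < cohort_size:
            stop = StopReason.STREAM_EXHAUSTED
        elif (
            stopping.stop_if_lowest_cohort_all_tox
            and dose == 1
            and all(y == 1 for y in outcomes)
        ):
            stop = StopReason.LOWEST_DOSE_ALL_TOX
        elif history.n_patients >= stopping.max_patients:
            stop = StopReason.MAX_N

        recommendation = None if stop is not None else next_dose(design, state, history)
        cohorts.append(
            CohortRecord(len(cohorts) + 1, dose, tuple(outcomes), p_hat, recommendation)
        )
        if stop is not None:
            final = None if stop is StopReason.LOWEST_DOSE_ALL_TOX else select_mtd(state, design.gamma)
            return TrialRecord(design.name.value, tuple(cohorts), stop, final, source.seed)
        dose = recommendation


# --------------------------------------------------------------------------
# Everolimus worked example
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EverolimusFixture:
    """Data of the Everolimus plus Paclitaxel/Trastuzumab phase I trial.

    Three regimens (5 mg daily, 10 mg daily, 30 mg weekly), target
    toxicity 0.30.  The trial's aggregated totals were 6, 17 and 10
    patients at the three regimens with 3, 6 and 7 DLTs respectively.
    ``streams`` is the canonical per-dose outcome ordering used for the
    cohort-by-cohort replay; within-cohort order does not affect the
    posterior, and the 1-DLT/2-DLT split of the mid-dose DLTs across
    the two consecutive de-escalation cohorts is a reconstruction
    consistent with the reported pathway, not a published sequence.
    """

    skeleton: Skeleton
    gamma: float
    prior_mean: float
    prior_var: float
    cohort_size: int
    n_patients: tuple[int, int, int]
    n_dlts: tuple[int, int, int]
    streams: Mapping[int, tuple[int, ...]]

    @property
    def model(self) -> PowerModelSpec:
        return PowerModelSpec(self.skeleton, self.prior_mean, self.prior_var)

    @property
    def source(self) -> OutcomeSource:
        return OutcomeSource.from_streams(self.streams)

    @property
    def stopping(self) -> StoppingRule:
        return StoppingRule(max_patients=sum(self.n_patients), stop_if_lowest_cohort_all_tox=True)


def everolimus_fixture() -> EverolimusFixture:
    """The Everolimus replay setup: skeleton (0.20, 0.30, 0.40), prior N(0, 1.34)."""
    return EverolimusFixture(
        skeleton=Skeleton((0.20, 0.30, 0.40)),
        gamma=0.30,
        prior_mean=0.0,
        prior_var=1.34,
        cohort_size=3,
        n_patients=(6, 17, 10),
        n_dlts=(3, 6, 7),
        streams={
            1: (0, 0, 0, 1, 1, 1),
            2: (1, 0, 0, 0, 0, 0, 1, 0, 0, 1, 1, 0),
            3: (1, 1, 1),
        },
    )
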