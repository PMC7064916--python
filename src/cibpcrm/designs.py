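"""Dose-allocation rules: mapping a posterior and trial history to the next dose.

Implemented designs
-------------------
CRM
    One-parameter power-model continual reassessment method allocating
    by the squared distance of the posterior mean DLT probability from
    the target.
CRM_M
    CRM restricted to doses whose estimated toxicity is strictly below
    the target (with fallback to the lowest dose when no dose
    qualifies).
CIBP
    CRM allocating by the posterior expectation of the convex infinite
    bounds penalization divergence; the asymmetry parameter ``a``
    controls conservatism (smaller ``a`` penalizes overdosing more).
EWOC / TR / TDFB
    Two-parameter logistic designs minimizing the posterior-expected
    asymmetric linear loss with a fixed (EWOC) or increasing (TR,
    toxicity-dependent TDFB) feasibility bound alpha.
BLRM
    Two-parameter logistic design minimizing the posterior-expected
    interval loss.

All designs share the escalation constraints (no dose skipping, start
at the lowest dose) and select the final MTD by the squared distance of
the posterior mean probabilities from the target, regardless of the
allocation criterion: conservatism matters during the trial, accuracy
at the end.

Dose indices are 1-based throughout.  Ties in every argmin are broken
toward the lowest dose index (the safety-conservative choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .criteria import CriterionKind, CriterionSpec
from .dose_models import Logistic2Spec, PosteriorState, PowerModelSpec

__all__ = [
    "DesignName",
    "AlphaSchedule",
    "EscalationConstraint",
    "DesignSpec",
    "tr_alpha",
    "tdfb_alpha",
    "apply_no_skip",
    "next_dose",
    "select_mtd",
    "standard_design",
]


class DesignName(str, Enum):
    CRM = "CRM"
    CRM_M = "CRM_M"
    CIBP = "CIBP"
    EWOC = "EWOC"
    TR = "TR"
    TDFB = "TDFB"
    BLRM = "BLRM"


def tr_alpha(n: int) -> float:
    """TR feasibility-bound schedule: 0.25 up to patient 9, then +0.05 per patient, capped at 0.50."""
    if n < 2:
        raise ValueError(f"the TR schedule starts at patient 2, got n={n}")
    return min(0.25 + 0.05 * max(0, n - 9), 0.50)


def tdfb_alpha(n: int, total_dlts: int, alpha_min: float = 0.25, S: float = 12.0, cap: float = 0.50) -> float:
    """Toxicity-dependent feasibility bound.

    ``alpha = min(cap, alpha_min + (cap - alpha_min) * (n - 1 - total_dlts) / S)``
    where ``n - 1 - total_dlts`` counts the DLT-free patients among the
    first ``n - 1``: the bound relaxes toward ``cap`` only as non-toxic
    outcomes accrue, at a rate set by ``S``.
    """
    if S <= 0.0:
        raise ValueError(f"S must be positive, got {S!r}")
    if total_dlts > n:
        raise ValueError("total_dlts cannot exceed the number of patients")
    return min(cap, alpha_min + (cap - alpha_min) * (n - 1 - total_dlts) / S)


@dataclass(frozen=True)
class AlphaSchedule:
    """Feasibility-bound schedule for the EWOC design family.

    ``kind='fixed'`` uses ``alpha_min`` throughout; ``'TR'`` uses the
    patient-indexed TR schedule; ``'TDFB'`` the toxicity-dependent
    update with scale ``S``.
    """

    kind: str = "fixed"
    alpha_min: float = 0.25
    cap: float = 0.50
    S: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "TR", "TDFB"):
            raise ValueError(f"unknown alpha schedule kind {self.kind!r}")
        if not (0.0 < self.alpha_min <= 1.0) or not (0.0 < self.cap <= 1.0):
            raise ValueError("alpha_min and cap must lie in (0, 1]")
        if self.cap < self.alpha_min:
            raise ValueError("cap must be at least alpha_min")

    def current(self, n_next: int, total_dlts: int) -> float:
        """Alpha used when allocating patient number ``n_next`` (1-based),
        given the DLT total among the ``n_next - 1`` patients so far."""
        if self.kind == "fixed" or n_next < 2:
            return self.alpha_min
        if self.kind == "TR":
            return tr_alpha(n_next)
        return tdfb_alpha(n_next - 1, total_dlts, self.alpha_min, self.S, self.cap)


@dataclass(frozen=True)
class EscalationConstraint:
    """Escalation restrictions applied on top of the criterion argmin.

    ``no_skip``: the next dose may not exceed the highest dose yet
    administered plus one.  ``start_lowest``: the first cohort goes to
    dose 1.  ``coherent``: the design never escalates immediately after
    a cohort containing at least one DLT (the CRM coherence principle;
    de-escalation and staying are always allowed).
    ``restrict_below_target`` is the CRM(M) rule: only doses with
    estimated toxicity strictly below the target are admissible.
    """

    no_skip: bool = True
    start_lowest: bool = True
    coherent: bool = True
    restrict_below_target: bool = False  # CRM(M) only


@dataclass(frozen=True)
class DesignSpec:
    """A complete design: working model + criterion + constraints.

    ``allocation`` selects how the criterion enters the decision:
    ``'posterior'`` minimizes the posterior expectation of the
    criterion (the default, and the recommended mode for CIBP),
    ``'plugin'`` evaluates the criterion at the posterior mean
    probability.  CRM and CRM(M) always use the posterior mean
    probability inside the squared distance, which coincides with
    plug-in allocation.
    """

    #: Ceiling on per-node criterion values inside posterior-expected
    #: allocation scores.  The CIBP divergence is unbounded as the DLT
    #: probability approaches 0 or 1, and in states with no DLTs yet the
    #: exact posterior expectation under the power model diverges through
    #: the safe (p -> 0) tail; capping keeps scores finite while
    #: preserving the criterion's ordering (boundary-heavy doses are
    #: still penalized most, and any finite value sorts below the cap).
    CRITERION_CAP = 1e12

    name: DesignName
    model: PowerModelSpec | Logistic2Spec
    criterion: CriterionSpec
    constraints: EscalationConstraint = field(default_factory=EscalationConstraint)
    alpha_schedule: AlphaSchedule | None = None
    allocation: str = "posterior"

    def __post_init__(self) -> None:
        name = DesignName(self.name)
        object.__setattr__(self, "name", name)
        if self.allocation not in ("posterior", "plugin"):
            raise ValueError(f"allocation must be 'posterior' or 'plugin', got {self.allocation!r}")
        expected_kind = {
            DesignName.CRM: (CriterionKind.SQUARED,),
            DesignName.CRM_M: (CriterionKind.SQUARED,),
            DesignName.CIBP: (CriterionKind.CIBP, CriterionKind.CIBP_ABS),
            DesignName.EWOC: (CriterionKind.EWOC,),
            DesignName.TR: (CriterionKind.EWOC,),
            DesignName.TDFB: (CriterionKind.EWOC,),
            DesignName.BLRM: (CriterionKind.BLRM,),
        }[name]
        if self.criterion.kind not in expected_kind:
            raise ValueError(
                f"design {name.value} requires a criterion of kind "
                f"{'/'.join(k.value for k in expected_kind)}, got {self.criterion.kind.value}"
            )
        if name in (DesignName.EWOC, DesignName.TR, DesignName.TDFB) and self.alpha_schedule is None:
            raise ValueError(f"design {name.value} requires an alpha schedule")
        ewoc_kind = {DesignName.EWOC: "fixed", DesignName.TR: "TR", DesignName.TDFB: "TDFB"}
        if name in ewoc_kind and self.alpha_schedule.kind != ewoc_kind[name]:
            raise ValueError(
                f"design {name.value} requires an alpha schedule of kind {ewoc_kind[name]!r}"
            )

    @property
    def gamma(self) -> float:
        return self.criterion.gamma


def _doses_tried(history) -> tuple[int, ...]:
    """Accept a TrialRecord or a plain sequence of dose indices."""
    if history is None:
        return ()
    doses = getattr(history, "doses_administered", history)
    return tuple(int(d) for d in doses)


def apply_no_skip(candidate: int, history, start_lowest: bool = True) -> int:
    """Clip a candidate dose so escalation never skips an untried level.

    The candidate may not exceed (highest dose ever administered + 1);
    de-escalation is never blocked.  With an empty history and
    ``start_lowest`` the first cohort goes to dose 1.
    """
    tried = _doses_tried(history)
    if not tried:
        return 1 if start_lowest else candidate
    return min(candidate, max(tried) + 1)


def _alpha_for(design: DesignSpec, history) -> float | None:
    if design.alpha_schedule is None:
        return None
    n_enrolled = getattr(history, "n_patients", None)
    total_dlts = getattr(history, "n_dlts", 0)
    if n_enrolled is None:
        tried = _doses_tried(history)
        n_enrolled = len(tried)
        total_dlts = 0
    return design.alpha_schedule.current(n_enrolled + 1, total_dlts)


def allocation_scores(design: DesignSpec, state: PosteriorState, history=None) -> np.ndarray:
    """Per-dose allocation score (lower is better) before escalation constraints."""
    m = state.n_doses
    gamma = design.gamma
    p_hat = state.weights @ state.psi.T  # posterior mean probability per dose
    if design.name in (DesignName.CRM, DesignName.CRM_M):
        scores = (p_hat - gamma) ** 2
        if design.name is DesignName.CRM_M or design.constraints.restrict_below_target:
            scores = np.where(p_hat < gamma, scores, np.inf)
        return scores
    alpha = _alpha_for(design, history)
    if design.allocation == "plugin":
        return np.asarray(design.criterion(p_hat, alpha=alpha) if alpha is not None
                          else design.criterion(p_hat), dtype=float)
    w = state.weights
    mask = w > 0.0
    vals = design.criterion(state.psi[:, mask], alpha=alpha) if alpha is not None \
        else design.criterion(state.psi[:, mask])
    # cap per-node values: see CRITERION_CAP
    vals = np.minimum(np.asarray(vals, dtype=float), DesignSpec.CRITERION_CAP)
    scores = vals @ w[mask]
    if np.any(np.isnan(scores)):
        raise FloatingPointError("criterion produced non-finite scores on interior probabilities")
    return scores


def next_dose(design: DesignSpec, state: PosteriorState, history=None) -> int:
    """Dose for the next cohort: constrained argmin of the design's score.

    ``history`` is a TrialRecord (or a bare sequence of administered
    dose indices); it supplies the no-skipping clip, the coherence
    restriction and, for EWOC-family designs, the current feasibility
    bound.
    """
    scores = allocation_scores(design, state, history)
    if np.all(np.isinf(scores)):
        # CRM(M) with no dose estimated below target: fall back to the lowest dose
        candidate = 1
    else:
        candidate = int(np.argmin(scores)) + 1  # ties break to the lowest index
    tried = _doses_tried(history)
    if design.constraints.coherent and tried:
        last_dose = tried[-1]
        last_had_dlt = bool(getattr(history, "last_cohort_had_dlt", False))
        if last_had_dlt:
            candidate = min(candidate, last_dose)
    if design.constraints.no_skip:
        candidate = apply_no_skip(candidate, history, design.constraints.start_lowest)
    return candidate


def select_mtd(state: PosteriorState, gamma: float) -> int:
    """Final MTD: squared-distance argmin of posterior mean probabilities.

    Unconstrained by escalation history; ties break to the lowest dose.
    """
    p_hat = state.weights @ state.psi.T
    return int(np.argmin((p_hat - gamma) ** 2)) + 1


def standard_design(
    name: str | DesignName,
    model: PowerModelSpec | Logistic2Spec,
    gamma: float,
    *,
    a: float | None = None,
    alpha: float = 0.25,
    S: float = 12.0,
    allocation: str = "posterior",
    constraints: EscalationConstraint | None = None,
) -> DesignSpec:
    """Factory with the conventional settings for each named design."""
    name = DesignName(name)
    constraints = constraints or EscalationConstraint(
        restrict_below_target=(name is DesignName.CRM_M)
    )
    schedule = None
    if name is DesignName.CRM or name is DesignName.CRM_M:
        crit = CriterionSpec(kind=CriterionKind.SQUARED, gamma=gamma)
    elif name is DesignName.CIBP:
        if a is None:
            raise ValueError("CIBP requires the asymmetry parameter a")
        crit = CriterionSpec(kind=CriterionKind.CIBP, gamma=gamma, a=a)
    elif name in (DesignName.EWOC, DesignName.TR, DesignName.TDFB):
        crit = CriterionSpec(kind=CriterionKind.EWOC, gamma=gamma, alpha=alpha)
        schedule = AlphaSchedule(
            kind={"EWOC": "fixed", "TR": "TR", "TDFB": "TDFB"}[name.value],
            alpha_min=alpha,
            S=S,
        )
    elif name is DesignName.BLRM:
        crit = CriterionSpec(kind=CriterionKind.BLRM, gamma=gamma)
    else:  # pragma: no cover
        raise AssertionError(name)
    return DesignSpec(
        name=name,
        model=model,
        criterion=crit,
        constraints=constraints,
        alpha_schedule=schedule,
        allocation=allocation,
    )
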