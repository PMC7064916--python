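"""Allocation criteria for phase I dose-escalation designs.

Every criterion maps a DLT probability ``p`` and a target toxicity
``gamma`` to a nonnegative penalty; the dose minimizing the (plug-in or
posterior-expected) penalty is given to the next cohort.  The module
implements:

* the classical squared distance ``(p - gamma)**2``,
* the Aitchison (logit) distance,
* the convex infinite bounds penalization (CIBP) divergence
  ``(p - gamma)**2 / (p**a * (1 - p)**(2 - a))`` and its
  absolute-distance variant,
* the EWOC asymmetric linear loss, and
* the interval-based loss table used by Bayesian logistic regression
  model (BLRM) designs,

together with the calibration of the CIBP asymmetry parameter ``a``
from an indifference half-width.

All functions accept scalars or numpy arrays in ``p`` and broadcast.
CIBP values at ``p`` exactly 0 or 1 are ``+inf`` (the divergence blows
up at the bounds, which is what keeps allocation away from extreme
doses); comparisons therefore never select a boundary probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "CriterionKind",
    "CriterionSpec",
    "DEFAULT_BLRM_INTERVALS",
    "squared_distance",
    "cibp_divergence",
    "cibp_abs_divergence",
    "aitchison_distance",
    "asymmetry_from_interval",
    "ewoc_loss",
    "blrm_loss",
]


class CriterionKind(str, Enum):
    SQUARED = "squared"
    CIBP = "cibp"
    CIBP_ABS = "cibp_abs"
    AITCHISON = "aitchison"
    EWOC = "ewoc"
    BLRM = "blrm"


#: Interval loss table for a target toxicity of 0.33: doses in the
#: on-target band (0.26, 0.41) carry no loss, underdosing costs 1,
#: overdosing costs 1 and excessive toxicity above 0.66 costs 2.
#: Intervals are right-open [lo, hi); p = 1 falls in the last interval.
DEFAULT_BLRM_INTERVALS: tuple[tuple[float, float, float], ...] = (
    (0.00, 0.26, 1.0),
    (0.26, 0.41, 0.0),
    (0.41, 0.66, 1.0),
    (0.66, 1.00, 2.0),
)


def _check_asymmetry(a: float) -> None:
    if not (0.0 < a < 2.0):
        raise ValueError(f"asymmetry parameter a must lie in (0, 2), got {a!r}")


def squared_distance(p, gamma: float):
    """Squared distance ``(p - gamma)**2`` between a DLT probability and the target."""
    p = np.asarray(p, dtype=float)
    out = (p - gamma) ** 2
    return out if out.ndim else float(out)


def cibp_divergence(p, gamma: float, a: float):
    """CIBP divergence ``(p - gamma)**2 / (p**a * (1 - p)**(2 - a))``.

    The denominator generalizes the Bernoulli variance ``p (1 - p)``
    (recovered at ``a = 1``); exponent ``a`` weights the penalty on
    overly toxic doses and ``2 - a`` the penalty on overly safe ones,
    so ``a < 1`` penalizes toxic doses more severely.  The value is 0
    iff ``p == gamma`` and ``+inf`` at ``p`` in {0, 1} (for
    ``gamma`` strictly inside the unit interval).

    Parameters
    ----------
    p : float or array-like
        DLT probability in [0, 1].
    gamma : float
        Target toxicity.
    a : float
        Asymmetry parameter, strictly inside (0, 2).
    """
    _check_asymmetry(a)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = p**a * (1.0 - p) ** (2.0 - a)
        out = np.where(denom > 0.0, (p - gamma) ** 2 / np.where(denom > 0, denom, 1.0), np.inf)
    # p == gamma on a boundary (gamma in {0,1}) is still a zero of the numerator
    out = np.where(p == gamma, 0.0, out)
    return out if out.ndim else float(out)


def cibp_abs_divergence(p, gamma: float, a: float):
    """Absolute-distance CIBP variant ``|p - gamma| / (p**a * (1 - p)**(2 - a))``.

    Penalizes small deviations more than the squared-numerator form, so
    for equal ``a`` it trades some safety for accuracy.
    """
    _check_asymmetry(a)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = p**a * (1.0 - p) ** (2.0 - a)
        out = np.where(denom > 0.0, np.abs(p - gamma) / np.where(denom > 0, denom, 1.0), np.inf)
    out = np.where(p == gamma, 0.0, out)
    return out if out.ndim else float(out)


def aitchison_distance(p, gamma: float):
    """Squared distance between logit-transformed probabilities.

    ``(logit p - logit gamma)**2`` with natural logarithms.  Defined
    only for ``p`` and ``gamma`` strictly inside (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)) or not (0.0 < gamma < 1.0):
        raise ValueError("aitchison_distance requires p and gamma strictly in (0, 1)")
    lg = math.log(gamma / (1.0 - gamma))
    out = (np.log(p / (1.0 - p)) - lg) ** 2
    return out if out.ndim else float(out)


def asymmetry_from_interval(gamma: float, theta: float) -> float:
    """Calibrate the CIBP asymmetry parameter from an indifference half-width.

    ``(gamma - theta, gamma + theta)`` is the interval of toxicity
    estimates inside which the investigator, given two estimates at the
    same squared distance from the target, prefers the safer dose.  The
    returned ``a = 2 / (1 + A)`` with
    ``A = log((gamma - theta) / (gamma + theta)) / log((1 - gamma - theta) / (1 - gamma + theta))``
    makes the CIBP divergence equal at the two interval endpoints.  As
    ``theta -> 0`` the calibrated ``a`` tends to ``2 * gamma``, which
    reproduces plug-in squared-distance allocation; larger ``theta``
    gives smaller ``a``, i.e. more conservative allocation.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must lie in (0, 1), got {gamma!r}")
    if not (0.0 < theta < min(gamma, 1.0 - gamma)):
        raise ValueError(
            f"theta must lie in (0, min(gamma, 1 - gamma)) = (0, {min(gamma, 1.0 - gamma)}), got {theta!r}"
        )
    A = math.log((gamma - theta) / (gamma + theta)) / math.log(
        (1.0 - gamma - theta) / (1.0 - gamma + theta)
    )
    return 2.0 / (1.0 + A)


def ewoc_loss(p, gamma: float, alpha: float):
    """EWOC asymmetric linear loss ``alpha (gamma - p)+ + (1 - alpha) (p - gamma)+``.

    ``alpha`` is the feasibility bound: values below 0.5 penalize
    overdosing more heavily than underdosing.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    p = np.asarray(p, dtype=float)
    out = alpha * np.maximum(0.0, gamma - p) + (1.0 - alpha) * np.maximum(0.0, p - gamma)
    return out if out.ndim else float(out)


def blrm_loss(p, loss_intervals: Sequence[tuple[float, float, float]] = DEFAULT_BLRM_INTERVALS):
    """Interval loss: the loss of the interval containing ``p``.

    ``loss_intervals`` is a sequence of ``(lo, hi, loss)`` triples
    partitioning [0, 1].  Intervals are treated as right-open
    ``[lo, hi)``; ``p = 1`` is assigned to the last interval.
    """
    _validate_intervals(loss_intervals)
    p = np.asarray(p, dtype=float)
    edges = np.array([iv[1] for iv in loss_intervals[:-1]])
    losses = np.array([iv[2] for iv in loss_intervals])
    idx = np.searchsorted(edges, p, side="right")
    out = losses[idx]
    return out if out.ndim else float(out)


def _validate_intervals(loss_intervals: Sequence[tuple[float, float, float]]) -> None:
    if not loss_intervals:
        raise ValueError("loss_intervals must be nonempty")
    lo0 = loss_intervals[0][0]
    hiN = loss_intervals[-1][1]
    if lo0 != 0.0 or hiN != 1.0:
        raise ValueError("loss_intervals must span [0, 1]")
    for (lo_a, hi_a, loss_a), (lo_b, _, _) in zip(loss_intervals, loss_intervals[1:]):
        if hi_a != lo_b:
            raise ValueError("loss_intervals must be contiguous")
        if hi_a <= lo_a:
            raise ValueError("loss_intervals must have positive width")
        if not math.isfinite(loss_a):
            raise ValueError("losses must be finite")
    if not math.isfinite(loss_intervals[-1][2]):
        raise ValueError("losses must be finite")


@dataclass(frozen=True)
class CriterionSpec:
    """A named allocation criterion together with its parameters.

    Parameters
    ----------
    kind : CriterionKind
        Which criterion family.
    gamma : float
        Target toxicity; by phase I convention below 0.5 (a value at or
        above 0.5 is accepted with a warning).
    a : float, optional
        CIBP asymmetry parameter, required for the ``cibp`` and
        ``cibp_abs`` kinds.
    alpha : float, optional
        EWOC feasibility bound, required for the ``ewoc`` kind.
    loss_intervals : tuple of (lo, hi, loss), optional
        Loss table for the ``blrm`` kind.
    """

    kind: CriterionKind
    gamma: float
    a: float | None = None
    alpha: float | None = None
    loss_intervals: tuple[tuple[float, float, float], ...] = field(
        default=DEFAULT_BLRM_INTERVALS
    )

    def __post_init__(self) -> None:
        kind = CriterionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma!r}")
        if self.gamma >= 0.5:
            warnings.warn(
                f"target toxicity gamma={self.gamma} is unusually high for a phase I trial",
                stacklevel=2,
            )
        if kind in (CriterionKind.CIBP, CriterionKind.CIBP_ABS):
            if self.a is None:
                raise ValueError(f"criterion kind {kind.value!r} requires the asymmetry parameter a")
            _check_asymmetry(self.a)
        if kind is CriterionKind.EWOC:
            if self.alpha is None:
                raise ValueError("criterion kind 'ewoc' requires alpha")
            if not (0.0 < self.alpha < 1.0):
                raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if kind is CriterionKind.BLRM:
            _validate_intervals(self.loss_intervals)

    def __call__(self, p, *, alpha: float | None = None):
        """Evaluate the criterion at probability ``p``.

        ``alpha`` overrides the stored EWOC feasibility bound; EWOC
        variants with a schedule (TR, TDFB) pass the current value here.
        """
        if self.kind is CriterionKind.SQUARED:
            return squared_distance(p, self.gamma)
        if self.kind is CriterionKind.CIBP:
            return cibp_divergence(p, self.gamma, self.a)
        if self.kind is CriterionKind.CIBP_ABS:
            return cibp_abs_divergence(p, self.gamma, self.a)
        if self.kind is CriterionKind.AITCHISON:
            return aitchison_distance(p, self.gamma)
        if self.kind is CriterionKind.EWOC:
            eff = self.alpha if alpha is None else alpha
            return ewoc_loss(p, self.gamma, eff)
        if self.kind is CriterionKind.BLRM:
            return blrm_loss(p, self.loss_intervals)
        raise AssertionError(f"unhandled criterion kind {self.kind!r}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind.value, "gamma": self.gamma}
        if self.a is not None:
            d["a"] = self.a
        if self.alpha is not None:
            d["alpha"] = self.alpha
        if self.kind is CriterionKind.BLRM:
            d["loss_intervals"] = [list(iv) for iv in self.loss_intervals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionSpec":
        kw = dict(d)
        if "loss_intervals" in kw:
            kw["loss_intervals"] = tuple(tuple(iv) for iv in kw["loss_intervals"])
        return cls(**kw)
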