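"""Dose-toxicity working models and Bayesian posterior machinery.

Two working models are provided, matching common practice in
model-based phase I designs:

* the one-parameter power model ``psi(d, beta) = d ** exp(beta)`` with a
  normal prior on ``beta``, where the standardized dose labels ``d`` are
  the skeleton (the prior guesses of the per-dose DLT probabilities);
* the two-parameter logistic model
  ``psi(d, b1, b2) = expit(b1 + b2 * d)`` with a bivariate normal prior,
  used by EWOC-family and BLRM designs.

Posteriors are represented by deterministic grid quadrature
(:class:`PosteriorState`): a fixed grid of parameter nodes spanning the
prior mean +/- ``k`` prior standard deviations carries log posterior
weights, updated in log space after each cohort.  For the one- and
two-dimensional parameter spaces of these models this is simpler, fully
reproducible, and easier to verify against brute-force refinement than
Monte Carlo posterior sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit, logsumexp, xlog1py, xlogy
from scipy.stats import multivariate_normal, norm

__all__ = [
    "Skeleton",
    "PowerModelSpec",
    "Logistic2Spec",
    "GridSpec",
    "ObservationSet",
    "PosteriorState",
    "power_prob",
    "logistic2_prob",
    "make_skeleton",
    "init_posterior",
    "update_posterior",
    "posterior_mean_prob",
    "posterior_expected",
]


# --------------------------------------------------------------------------
# model specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Skeleton:
    """Ordered prior DLT probabilities, doubling as standardized dose labels."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 1:
            raise ValueError("skeleton must contain at least one dose")
        if any(not (0.0 < v < 1.0) for v in vals):
            raise ValueError(f"skeleton values must lie strictly in (0, 1): {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"skeleton must be strictly increasing: {vals}")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class PowerModelSpec:
    """One-parameter power model ``psi(d, beta) = d ** exp(beta)``.

    ``prior_var`` is the variance of the normal prior on ``beta``; the
    default 1.34 is the widely used least-informative operational prior.
    """

    skeleton: Skeleton
    prior_mean: float = 0.0
    prior_var: float = 1.34

    def __post_init__(self) -> None:
        if self.prior_var <= 0.0:
            raise ValueError(f"prior_var must be positive, got {self.prior_var!r}")

    @property
    def n_doses(self) -> int:
        return len(self.skeleton)

    def prob_matrix(self, nodes: np.ndarray) -> np.ndarray:
        """psi(d_i, beta_g) for every dose i (rows) and node g (columns)."""
        d = self.skeleton.as_array()[:, None]
        return d ** np.exp(np.asarray(nodes, dtype=float)[None, :])


@dataclass(frozen=True)
class Logistic2Spec:
    """Two-parameter logistic model ``psi(d) = expit(b1 + b2 * d)``."""

    dose_values: tuple[float, ...]
    prior_mean: tuple[float, float] = (0.0, 1.0)
    prior_cov: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 0.0), (0.0, 1.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_values", tuple(float(v) for v in self.dose_values))
        cov = np.asarray(self.prior_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("prior_cov must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0.0):
            raise ValueError("prior_cov must be positive definite")
        if any(b <= a for a, b in zip(self.dose_values, self.dose_values[1:])):
            raise ValueError("dose_values must be strictly increasing")

    @property
    def n_doses(self) -> int:
        return len(self.dose_values)

    def prob_matrix(self, nodes: np.ndarray) -> np.ndarray:
        nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
        d = np.asarray(self.dose_values)[:, None]
        return expit(nodes[:, 0][None, :] + nodes[:, 1][None, :] * d)


def power_prob(d: float, beta: float) -> float:
    """DLT probability ``d ** exp(beta)`` of the power model."""
    if not (0.0 < d < 1.0):
        raise ValueError(f"standardized dose must lie in (0, 1), got {d!r}")
    return float(d ** math.exp(beta))


def logistic2_prob(d: float, beta1: float, beta2: float) -> float:
    """DLT probability ``expit(beta1 + beta2 * d)`` of the logistic model."""
    return float(expit(beta1 + beta2 * d))


# --------------------------------------------------------------------------
# skeleton construction
# --------------------------------------------------------------------------

def make_skeleton(m: int, prior_mtd_index: int, gamma: float, halfwidth: float) -> Skeleton:
    """Indifference-interval skeleton for the power model.

    The skeleton value at the prior MTD is ``gamma``.  Neighbors are
    generated iteratively: moving up, the next skeleton value is chosen
    so that under the ``beta`` mapping the current dose to toxicity
    ``gamma - halfwidth`` the next dose has toxicity
    ``gamma + halfwidth`` (and symmetrically moving down).  The
    half-width therefore encodes the interval of DLT probabilities an
    investigator treats as equivalent to the target.

    Parameters use 1-based dose indexing (``prior_mtd_index`` in
    ``1..m``), the clinical convention used throughout this package.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if not (1 <= prior_mtd_index <= m):
        raise ValueError(f"prior_mtd_index must lie in 1..{m}, got {prior_mtd_index}")
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must lie in (0, 1), got {gamma!r}")
    if not (0.0 < halfwidth < min(gamma, 1.0 - gamma)):
        raise ValueError(
            f"halfwidth must lie in (0, min(gamma, 1 - gamma)), got {halfwidth!r}"
        )
    lo = math.log(gamma - halfwidth)
    hi = math.log(gamma + halfwidth)
    s = [float("nan")] * m
    k0 = prior_mtd_index - 1
    s[k0] = gamma
    for k in range(k0, m - 1):
        # beta* solves s_k ** exp(beta*) = gamma - halfwidth; the next
        # skeleton value is the dose with toxicity gamma + halfwidth there
        s[k + 1] = math.exp(hi * math.log(s[k]) / lo)
    for k in range(k0, 0, -1):
        s[k - 1] = math.exp(lo * math.log(s[k]) / hi)
    try:
        return Skeleton(tuple(s))
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(f"skeleton construction failed for the given parameters: {exc}")


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationSet:
    """Per-patient (dose index, DLT outcome) pairs in administration order.

    Dose indices are 1-based.  ``counts(m)`` aggregates to per-dose
    (patients, DLTs) totals, which are sufficient for the Bernoulli
    likelihood (the ordering does not affect the posterior).
    """

    patients: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(d), int(y)) for d, y in self.patients)
        object.__setattr__(self, "patients", pts)
        for d, y in pts:
            if d < 1:
                raise ValueError(f"dose indices are 1-based, got {d}")
            if y not in (0, 1):
                raise ValueError(f"DLT outcomes must be 0 or 1, got {y}")

    @classmethod
    def from_counts(cls, n: Sequence[int], tox: Sequence[int]) -> "ObservationSet":
        """Build from per-dose totals ``n`` (patients) and ``tox`` (DLTs)."""
        if len(n) != len(tox):
            raise ValueError("n and tox must have equal length")
        pts: list[tuple[int, int]] = []
        for i, (ni, ti) in enumerate(zip(n, tox), start=1):
            if ti > ni:
                raise ValueError(f"dose {i}: DLT count {ti} exceeds patient count {ni}")
            pts.extend([(i, 1)] * ti)
            pts.extend([(i, 0)] * (ni - ti))
        return cls(tuple(pts))

    def __len__(self) -> int:
        return len(self.patients)

    def __add__(self, other: "ObservationSet") -> "ObservationSet":
        return ObservationSet(self.patients + other.patients)

    def counts(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        n = np.zeros(m, dtype=int)
        tox = np.zeros(m, dtype=int)
        for d, y in self.patients:
            if d > m:
                raise ValueError(f"dose index {d} exceeds number of doses {m}")
            n[d - 1] += 1
            tox[d - 1] += y
        return n, tox


# --------------------------------------------------------------------------
# posterior state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Quadrature grid: ``n_nodes`` per dimension spanning mean +/- k sd."""

    n_nodes: int = 2001
    k: float = 8.0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.k <= 0.0:
            raise ValueError("k must be positive")


DEFAULT_GRID_1D = GridSpec(n_nodes=2001, k=8.0)
DEFAULT_GRID_2D = GridSpec(n_nodes=201, k=8.0)


@dataclass(frozen=True)
class PosteriorState:
    """Discretized posterior over model parameters.

    ``nodes`` is the parameter grid (shape ``(N,)`` for the power model,
    ``(N, 2)`` for the logistic model), ``log_weights`` the normalized
    log posterior mass per node, and ``psi`` the precomputed per-dose
    DLT probabilities ``psi[i, g]`` at every node.
    """

    nodes: np.ndarray
    log_weights: np.ndarray
    psi: np.ndarray
    model: PowerModelSpec | Logistic2Spec | None = None

    @property
    def n_doses(self) -> int:
        return self.psi.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @classmethod
    def from_probs(cls, probs: Iterable[float]) -> "PosteriorState":
        """Degenerate point-mass state with the given per-dose probabilities.

        Useful for plug-in allocation checks and for exercising
        allocation rules at exactly known probability vectors.
        """
        p = np.asarray(list(probs), dtype=float)[:, None]
        return cls(nodes=np.zeros(1), log_weights=np.zeros(1), psi=p, model=None)

    def to_dict(self) -> dict:
        """JSON-serializable snapshot (posterior summaries, not the full grid)."""
        return {
            "n_nodes": int(self.log_weights.size),
            "posterior_mean_prob": [posterior_mean_prob(self, i + 1) for i in range(self.n_doses)],
        }


def init_posterior(model: PowerModelSpec | Logistic2Spec, grid: GridSpec | None = None) -> PosteriorState:
    """Prior-only posterior state on a fixed quadrature grid."""
    if isinstance(model, PowerModelSpec):
        grid = grid or DEFAULT_GRID_1D
        sd = math.sqrt(model.prior_var)
        nodes = np.linspace(model.prior_mean - grid.k * sd, model.prior_mean + grid.k * sd, grid.n_nodes)
        logw = norm.logpdf(nodes, loc=model.prior_mean, scale=sd)
    elif isinstance(model, Logistic2Spec):
        grid = grid or DEFAULT_GRID_2D
        mean = np.asarray(model.prior_mean, dtype=float)
        cov = np.asarray(model.prior_cov, dtype=float)
        sds = np.sqrt(np.diag(cov))
        ax = [np.linspace(mean[j] - grid.k * sds[j], mean[j] + grid.k * sds[j], grid.n_nodes) for j in (0, 1)]
        g1, g2 = np.meshgrid(ax[0], ax[1], indexing="ij")
        nodes = np.column_stack([g1.ravel(), g2.ravel()])
        logw = multivariate_normal.logpdf(nodes, mean=mean, cov=cov)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    logw = logw - logsumexp(logw)
    psi = model.prob_matrix(nodes)
    return PosteriorState(nodes=nodes, log_weights=logw, psi=psi, model=model)


def update_posterior(state: PosteriorState, obs: ObservationSet) -> PosteriorState:
    """Multiply node weights by the Bernoulli likelihood and renormalize.

    The likelihood factorizes over patients, so batch and sequential
    updates agree and the within-batch ordering is irrelevant.
    """
    if len(obs) == 0:
        return state
    n, tox = obs.counts(state.n_doses)
    active = n > 0
    # xlogy/xlog1py give 0 * log(0) = 0, so doses with no events stay
    # well-defined even where psi underflows to 0 or rounds to 1
    psi_a = state.psi[active]
    loglik = (
        xlogy(tox[active][:, None], psi_a) + xlog1py((n - tox)[active][:, None], -psi_a)
    ).sum(axis=0)
    logw = state.log_weights + loglik
    total = logsumexp(logw)
    if not np.isfinite(total):
        raise FloatingPointError(
            "posterior update underflowed: total mass is zero on the grid "
            f"(n={n.tolist()}, tox={tox.tolist()}); widen the grid or check the data"
        )
    return PosteriorState(
        nodes=state.nodes, log_weights=logw - total, psi=state.psi, model=state.model
    )


def posterior_mean_prob(state: PosteriorState, dose_index: int) -> float:
    """Posterior mean DLT probability at a dose (1-based index)."""
    _check_dose(state, dose_index)
    return float(state.weights @ state.psi[dose_index - 1])


def posterior_expected(state: PosteriorState, dose_index: int, g: Callable) -> float:
    """Posterior expectation ``E[g(psi(d_i, beta))]`` under the state.

    With ``g`` a CIBP divergence this is the posterior-expected
    allocation score; with the identity it reduces to
    :func:`posterior_mean_prob`.  Nodes with zero posterior mass are
    excluded so that an infinite ``g`` there cannot poison the sum.
    """
    _check_dose(state, dose_index)
    w = state.weights
    mask = w > 0.0
    vals = np.asarray(g(state.psi[dose_index - 1][mask]), dtype=float)
    out = float(w[mask] @ vals)
    if math.isnan(out):
        raise FloatingPointError(
            f"criterion returned non-finite values on interior probabilities at dose {dose_index}"
        )
    return out


def _check_dose(state: PosteriorState, dose_index: int) -> None:
    if not (1 <= dose_index <= state.n_doses):
        raise ValueError(f"dose index must lie in 1..{state.n_doses}, got {dose_index}")
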