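"""Working models, skeleton construction and quadrature posteriors."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from cibpcrm import (
    GridSpec,
    Logistic2Spec,
    ObservationSet,
    PosteriorState,
    PowerModelSpec,
    Skeleton,
    cibp_divergence,
    init_posterior,
    logistic2_prob,
    make_skeleton,
    posterior_expected,
    posterior_mean_prob,
    power_prob,
    update_posterior,
)


# --------------------------------------------------------------------------
# model functions
# --------------------------------------------------------------------------

@pytest.mark.parametrize("d,b,expected", [(0.2, 0.0, 0.2), (0.5, 0.0, 0.5), (0.3, math.log(2), 0.09)])
def test_power_prob_values(d, b, expected):
    assert power_prob(d, b) == pytest.approx(expected, rel=1e-12)


def test_power_prob_domain():
    with pytest.raises(ValueError):
        power_prob(0.0, 0.0)
    with pytest.raises(ValueError):
        power_prob(1.0, 0.0)


def test_power_prob_monotonicity():
    assert power_prob(0.2, 0.5) < power_prob(0.3, 0.5) < power_prob(0.4, 0.5)
    assert power_prob(0.3, 1.0) < power_prob(0.3, 0.0) < power_prob(0.3, -1.0)


@pytest.mark.parametrize("d,b1,b2", [(0.0, 0.0, 1.0), (1.0, 0.0, 0.0), (1.0, -1.0, 1.0)])
def test_logistic2_prob_half(d, b1, b2):
    assert logistic2_prob(d, b1, b2) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# skeleton
# --------------------------------------------------------------------------

def oracle_skeleton(m, prior_mtd_index, gamma, halfwidth):
    """Independent indifference-interval construction via root finding.

    Moving up from the anchor: solve for the power-model slope at which
    the current dose's toxicity is gamma - halfwidth, then solve for the
    dose whose toxicity is gamma + halfwidth under that slope (and
    symmetrically downward).  Uses numerical root finding only, no
    closed-form logs.
    """
    s = [None] * m
    s[prior_mtd_index - 1] = gamma

    def prob(d, beta):
        return d ** math.exp(beta)

    for k in range(prior_mtd_index - 1, m - 1):
        b = brentq(lambda x: prob(s[k], x) - (gamma - halfwidth), -20, 20, xtol=1e-14)
        s[k + 1] = brentq(lambda d: prob(d, b) - (gamma + halfwidth), 1e-12, 1 - 1e-12, xtol=1e-15)
    for k in range(prior_mtd_index - 1, 0, -1):
        b = brentq(lambda x: prob(s[k], x) - (gamma + halfwidth), -20, 20, xtol=1e-14)
        s[k - 1] = brentq(lambda d: prob(d, b) - (gamma - halfwidth), 1e-12, 1 - 1e-12, xtol=1e-15)
    return s


@pytest.mark.parametrize(
    "m,idx,gamma,h",
    [(3, 2, 0.3, 0.05), (6, 2, 0.25, 0.05), (6, 4, 0.25, 0.05), (5, 1, 0.2, 0.03), (4, 4, 0.33, 0.07)],
)
def test_make_skeleton_matches_root_finding_oracle(m, idx, gamma, h):
    got = make_skeleton(m, idx, gamma, h).as_array()
    want = np.array(oracle_skeleton(m, idx, gamma, h))
    np.testing.assert_allclose(got, want, atol=1e-10)
    assert got[idx - 1] == pytest.approx(gamma, abs=1e-15)
    assert np.all(np.diff(got) > 0)
    assert np.all((got > 0) & (got < 1))


def test_make_skeleton_anchor_exact():
    for m, idx, gamma in [(3, 2, 0.30), (6, 2, 0.25), (7, 3, 0.2)]:
        s = make_skeleton(m, idx, gamma, gamma / 5)
        assert s.values[idx - 1] == gamma


def test_make_skeleton_invalid():
    with pytest.raises(ValueError):
        make_skeleton(3, 4, 0.3, 0.05)
    with pytest.raises(ValueError):
        make_skeleton(3, 2, 0.3, 0.3)  # halfwidth not below gamma


def test_skeleton_validation():
    with pytest.raises(ValueError):
        Skeleton((0.3, 0.2))
    with pytest.raises(ValueError):
        Skeleton((0.0, 0.5))


# --------------------------------------------------------------------------
# posterior state
# --------------------------------------------------------------------------

def test_init_posterior_normalized(ev_model):
    state = init_posterior(ev_model, GridSpec(2001, 8.0))
    assert state.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert state.psi.shape == (3, 2001)


def test_init_posterior_2d_normalized():
    model = Logistic2Spec(dose_values=(-1.0, 0.0, 1.0))
    state = init_posterior(model, GridSpec(81, 6.0))
    assert state.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert state.nodes.shape == (81 * 81, 2)
    assert state.psi.shape == (3, 81 * 81)


def test_init_posterior_point_mass_limit():
    """A near-degenerate prior at beta=0 returns the skeleton itself."""
    model = PowerModelSpec(Skeleton((0.2, 0.3, 0.4)), prior_mean=0.0, prior_var=1e-12)
    state = init_posterior(model, GridSpec(101, 4.0))
    for i, d in enumerate((0.2, 0.3, 0.4), start=1):
        assert posterior_mean_prob(state, i) == pytest.approx(d, abs=1e-5)


def test_init_posterior_rejects_tiny_grid(ev_model):
    with pytest.raises(ValueError):
        GridSpec(1)


def test_update_with_empty_obs_is_identity(ev_prior_state):
    out = update_posterior(ev_prior_state, ObservationSet(()))
    assert out is ev_prior_state


def test_update_batch_equals_sequential(ev_prior_state):
    a = ObservationSet(((1, 0), (1, 1), (2, 0)))
    b = ObservationSet(((2, 1), (3, 0)))
    seq = update_posterior(update_posterior(ev_prior_state, a), b)
    batch = update_posterior(ev_prior_state, a + b)
    np.testing.assert_allclose(seq.log_weights, batch.log_weights, atol=1e-10)


def test_update_order_invariance(ev_prior_state):
    a = ObservationSet(((1, 0), (2, 1), (3, 0), (2, 0)))
    b = ObservationSet(((2, 0), (3, 0), (2, 1), (1, 0)))
    np.testing.assert_allclose(
        update_posterior(ev_prior_state, a).log_weights,
        update_posterior(ev_prior_state, b).log_weights,
        atol=1e-12,
    )


def brute_force_posterior_means(model, n_list, tox_list, n_nodes=1_000_001, k=8.0):
    """Direct fine-grid quadrature of the posterior mean DLT probabilities."""
    sd = math.sqrt(model.prior_var)
    beta = np.linspace(model.prior_mean - k * sd, model.prior_mean + k * sd, n_nodes)
    log_post = norm.logpdf(beta, model.prior_mean, sd)
    skel = model.skeleton.as_array()
    for d, n, t in zip(skel, n_list, tox_list):
        if n == 0:
            continue
        p = d ** np.exp(beta)
        with np.errstate(divide="ignore"):
            if t > 0:
                log_post = log_post + t * np.log(p)
            if n - t > 0:
                log_post = log_post + (n - t) * np.log1p(-p)
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()
    return np.array([w @ (d ** np.exp(beta)) for d in skel])


def test_posterior_mean_matches_brute_force_oracle(ev_model, ev_state_c1):
    """Default grid vs a million-node direct quadrature after cohort 1."""
    want = brute_force_posterior_means(ev_model, [3, 0, 0], [0, 0, 0])
    got = np.array([posterior_mean_prob(ev_state_c1, i) for i in (1, 2, 3)])
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_prior_mean_prob_matches_oracle(ev_model, ev_prior_state):
    want = brute_force_posterior_means(ev_model, [0, 0, 0], [0, 0, 0])
    got = np.array([posterior_mean_prob(ev_prior_state, i) for i in (1, 2, 3)])
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_posterior_mean_monotone_in_dose(ev_state_c2):
    p = [posterior_mean_prob(ev_state_c2, i) for i in (1, 2, 3)]
    assert p[0] < p[1] < p[2]
    assert all(0.0 < x < 1.0 for x in p)


def test_quadrature_convergence_on_worked_data(ev_model, everolimus):
    """Doubling the node count leaves posterior means unchanged to 1e-8."""
    obs = ObservationSet.from_counts(everolimus.n_patients, everolimus.n_dlts)
    means = []
    for n in (2001, 4001):
        st = update_posterior(init_posterior(ev_model, GridSpec(n, 8.0)), obs)
        means.append(np.array([posterior_mean_prob(st, i) for i in (1, 2, 3)]))
    np.testing.assert_allclose(means[0], means[1], atol=1e-8)


def test_dlt_never_decreases_posterior_means(ev_model):
    """An extra DLT anywhere shifts every dose's toxicity estimate up."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = rng.integers(0, 5, size=3)
        tox = np.array([rng.integers(0, ni + 1) for ni in n])
        base = update_posterior(init_posterior(ev_model), ObservationSet.from_counts(n, tox))
        base_means = [posterior_mean_prob(base, i) for i in (1, 2, 3)]
        for dose in (1, 2, 3):
            bumped = update_posterior(base, ObservationSet(((dose, 1),)))
            for i in (1, 2, 3):
                assert posterior_mean_prob(bumped, i) >= base_means[i - 1] - 1e-12


def test_underflow_raises_with_diagnostic():
    # a DLT at a dose whose probability underflows to zero on every grid
    # node leaves no posterior mass anywhere
    model = PowerModelSpec(Skeleton((1e-300, 0.5)), prior_mean=5.0, prior_var=0.01)
    state = init_posterior(model, GridSpec(51, 2.0))
    with pytest.raises(FloatingPointError, match="underflow"):
        update_posterior(state, ObservationSet(((1, 1),)))


# --------------------------------------------------------------------------
# posterior expectations
# --------------------------------------------------------------------------

def test_posterior_expected_point_mass_cibp():
    state = PosteriorState.from_probs((0.2, 0.4))
    got = posterior_expected(state, 1, lambda p: cibp_divergence(p, 0.3, 1.0))
    assert got == pytest.approx(1 / 16, rel=1e-12)


def test_posterior_expected_normalization_and_identity(ev_state_c2):
    assert posterior_expected(ev_state_c2, 2, lambda p: np.ones_like(p)) == pytest.approx(1.0, abs=1e-12)
    assert posterior_expected(ev_state_c2, 2, lambda p: p) == pytest.approx(
        posterior_mean_prob(ev_state_c2, 2), abs=1e-14
    )


def test_posterior_expected_squared_is_variance_plus_bias_sq(ev_state_c2):
    gamma = 0.3
    for i in (1, 2, 3):
        direct = posterior_expected(ev_state_c2, i, lambda p: (p - gamma) ** 2)
        mean = posterior_mean_prob(ev_state_c2, i)
        second = posterior_expected(ev_state_c2, i, lambda p: p**2)
        var = second - mean**2
        assert direct == pytest.approx(var + (mean - gamma) ** 2, abs=1e-10)


def test_posterior_state_snapshot(ev_state_c1):
    d = ev_state_c1.to_dict()
    assert d["n_nodes"] == ev_state_c1.log_weights.size
    assert len(d["posterior_mean_prob"]) == 3
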