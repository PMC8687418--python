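"""Interval-wise transition moments, Gaussian log-density and the sampler."""
import numpy as np
import pytest

import mssfit.lna as lna_mod
from mssfit import (
    IntegratorOptions,
    MomentIntegrationError,
    TransitionMoments,
    approximate_simulate,
    diffusion_matrix,
    gillespie_simulate,
    integrate_moments,
    integrate_moments_batch,
    transition_logpdf,
)
from mssfit.networks import Factor, RateLaw, ReactionNetwork
from conftest import ID_THETA, LV_THETA


def _id_exact_moments(n0, theta, dt):
    """Closed-form conditional moments of the immigration-death process."""
    th1, th2 = theta
    p = np.exp(-th2 * dt)
    m = th1 / th2
    mean = m + (n0 - m) * p
    var = n0 * p * (1 - p) + m * (1 - p)
    return mean, var


def test_zero_interval_returns_initial_conditions(lv_net):
    tm = integrate_moments(lv_net, [71, 79], LV_THETA, 0.0)
    assert np.array_equal(tm.mean, [71, 79])
    assert np.array_equal(tm.cov, np.zeros((2, 2)))


def test_immigration_death_closed_form(id_net):
    tm = integrate_moments(id_net, [30], ID_THETA, 2.0)
    mean, var = _id_exact_moments(30, ID_THETA, 2.0)
    assert abs(tm.mean[0] - mean) < 1e-8
    assert abs(tm.cov[0, 0] - var) < 1e-8
    # frozen closed-form values: mu = 20 + 10 e^{-0.06}
    assert np.isclose(tm.mean[0], 20 + 10 * np.exp(-0.06))
    assert np.isclose(tm.cov[0, 0], 2.8100322343277613)


def test_variance_reaches_stationary_poisson_limit(id_net):
    tm = integrate_moments(id_net, [20], ID_THETA, 300.0)
    assert abs(tm.cov[0, 0] - 20.0) < 1e-4
    assert abs(tm.mean[0] - 20.0) < 1e-6


def test_short_time_covariance_is_diffusion_times_dt(lv_net):
    x0 = np.array([71.0, 79.0])
    dt = 1e-4
    tm = integrate_moments(lv_net, x0, LV_THETA, dt)
    D = diffusion_matrix(lv_net, x0, LV_THETA)
    assert np.max(np.abs(tm.cov / dt - D)) < 1e-2 * np.max(np.abs(D))


def test_negative_interval_rejected(id_net):
    with pytest.raises(ValueError):
        integrate_moments(id_net, [5], ID_THETA, -1.0)


def test_integration_blowup_reports_failure():
    # autocatalytic birth X -> 2X at a huge rate over a long horizon overflows
    net = ReactionNetwork(
        species_names=["X"],
        educts=[[1]],
        products=[[2]],
        rate_laws=[RateLaw(0, (Factor.power(0),))],
        param_names=["k"],
    )
    with pytest.raises(MomentIntegrationError):
        integrate_moments_batch(
            net, [[1.0]], [100.0], [1000.0], options=IntegratorOptions(method="rk4")
        )


def test_rk4_matches_reference_integrator(lv_net, ar_net):
    from conftest import AR_THETA

    cases = [
        (lv_net, [71.0, 79.0], LV_THETA, 1.0),
        (ar_net, [6.0, 6.0, 8.0, 25.0], AR_THETA, 0.1),
    ]
    for net, x0, th, dt in cases:
        mr, cr = integrate_moments_batch(
            net, [x0], th, [dt], options=IntegratorOptions(method="rk4", n_steps=24)
        )
        ml, cl = integrate_moments_batch(
            net, [x0], th, [dt],
            options=IntegratorOptions(method="lsoda", rtol=1e-10, atol=1e-12),
        )
        assert np.max(np.abs(mr - ml)) < 1e-6
        assert np.max(np.abs(cr - cl)) < 1e-5


def test_compiled_kernel_equals_numpy_scheme(lv_net):
    opts = IntegratorOptions(method="rk4", n_steps=16)
    m1, c1 = integrate_moments_batch(
        lv_net, [[71.0, 79.0], [10.0, 200.0]], LV_THETA, [1.0, 2.0], options=opts
    )
    saved = lna_mod._rk4_batch_compiled
    lna_mod._rk4_batch_compiled = None
    try:
        m2, c2 = integrate_moments_batch(
            lv_net, [[71.0, 79.0], [10.0, 200.0]], LV_THETA, [1.0, 2.0], options=opts
        )
    finally:
        lna_mod._rk4_batch_compiled = saved
    assert np.max(np.abs(m1 - m2)) < 1e-12
    assert np.max(np.abs(c1 - c2)) < 1e-12


def test_covariance_symmetric_psd_along_trajectory(lv_net, lv_series):
    means, covs = integrate_moments_batch(
        lv_net, lv_series.states[:-1].astype(float), LV_THETA, lv_series.dts,
        options=IntegratorOptions(method="rk4", n_steps=24),
    )
    for C in covs:
        assert np.max(np.abs(C - C.T)) < 1e-10
        assert np.min(np.linalg.eigvalsh(C)) > -1e-10


# ---------------------------------------------------------------------------
# transition log-density
# ---------------------------------------------------------------------------

def test_logpdf_at_mean_is_normalisation_constant():
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    tm = TransitionMoments(np.array([5.0, 7.0]), cov)
    val = transition_logpdf(tm, [5.0, 7.0])
    expected = -0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(cov))
    assert np.isclose(val, expected, atol=1e-12)


def test_logpdf_standard_normal_unit_deviation():
    tm = TransitionMoments(np.array([0.0]), np.array([[1.0]]))
    assert np.isclose(
        transition_logpdf(tm, [1.0]), -0.5 * np.log(2 * np.pi) - 0.5
    )


def test_logpdf_agrees_with_naive_formula():
    rng = np.random.default_rng(2)
    A = rng.standard_normal((3, 3))
    cov = A @ A.T + 0.5 * np.eye(3)
    mean = rng.standard_normal(3)
    y = rng.standard_normal(3)
    tm = TransitionMoments(mean, cov)
    dev = y - mean
    naive = -0.5 * (
        3 * np.log(2 * np.pi)
        + np.log(np.linalg.det(cov))
        + dev @ np.linalg.inv(cov) @ dev
    )
    assert abs(transition_logpdf(tm, y) - naive) < 1e-10


def test_logpdf_marginalises_and_adds_noise():
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    tm = TransitionMoments(np.array([5.0, 7.0]), cov)
    v1 = transition_logpdf(tm, [6.0, 0.0], obs_idx=[0], sigma_meas=[[0.5]])
    tm1 = TransitionMoments(np.array([5.0]), np.array([[2.5]]))
    assert np.isclose(v1, transition_logpdf(tm1, [6.0]), atol=1e-12)


def test_logpdf_invariant_under_species_permutation(lv_net):
    perm = [1, 0]
    net2 = lv_net.reordered(perm)
    x0 = np.array([71.0, 79.0])
    y = np.array([80.0, 70.0])
    v1 = transition_logpdf(
        integrate_moments(lv_net, x0, LV_THETA, 1.0), y
    )
    v2 = transition_logpdf(
        integrate_moments(net2, x0[perm], LV_THETA, 1.0), y[perm]
    )
    assert abs(v1 - v2) < 1e-10


# ---------------------------------------------------------------------------
# approximate trajectory sampler
# ---------------------------------------------------------------------------

def test_sampler_outputs_nonnegative_integers(lv_net):
    ts = approximate_simulate(lv_net, [71, 79], 1.0 * np.arange(20), LV_THETA, seed=1)
    assert np.all(ts.states >= 0)
    assert ts.states.dtype == np.int64
    again = approximate_simulate(lv_net, [71, 79], 1.0 * np.arange(20), LV_THETA, seed=1)
    assert again == ts


def test_noise_free_limit_is_rounded_ode_chain(id_net):
    grid = 2.0 * np.arange(6)
    ts = approximate_simulate(id_net, [30], grid, ID_THETA, seed=0, noise=False)
    x = 30.0
    for i in range(1, 6):
        x = np.round(integrate_moments(id_net, [x], ID_THETA, 2.0).mean[0])
        assert ts.states[i, 0] == x


def test_sampler_mean_matches_ssa_ensemble(id_net):
    """For linear propensities the Gaussian sampler reproduces SSA means."""
    grid = np.array([0.0, 2.0, 4.0, 6.0])
    n = 1500
    fast = IntegratorOptions(method="rk4", n_steps=16)
    approx = np.array(
        [
            approximate_simulate(id_net, [35], grid, ID_THETA, seed=s, options=fast).states[:, 0]
            for s in range(n)
        ],
        dtype=float,
    )
    ssa = np.array(
        [
            gillespie_simulate(id_net, [35], grid, ID_THETA, seed=50_000 + s).states[:, 0]
            for s in range(n)
        ],
        dtype=float,
    )
    se = np.sqrt(ssa.var(axis=0, ddof=1) / n + approx.var(axis=0, ddof=1) / n)
    gap = np.abs(approx.mean(axis=0) - ssa.mean(axis=0))
    assert np.all(gap[1:] < 4 * se[1:] + 0.3)  # 0.3 allows the rounding bias
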