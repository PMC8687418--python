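"""Multiple-shooting objectives: factorisation, partial observation, noise."""
import numpy as np
from scipy.integrate import solve_ivp

from mssfit import (
    IntegratorOptions,
    ObservationModel,
    TimeSeries,
    constant_variance_objective,
    estimate,
    gillespie_simulate,
    integrate_moments,
    integrate_moments_batch,
    mss_objective,
    mss_objective_noise,
    mss_objective_partial,
)
from conftest import ID_THETA, LV_THETA


def test_single_interval_at_the_mean(id_net):
    """Datum equal to the interval ODE solution: F is the normalising constant."""
    # started at the steady state the mean stays exactly at 20
    ts = TimeSeries([0.0, 2.0], [[20], [20]], ["X"])
    sigma = integrate_moments(id_net, [20], ID_THETA, 2.0).cov[0, 0]
    obj = mss_objective(ts, id_net, ID_THETA)
    assert np.isclose(obj.value, 0.5 * np.log(2 * np.pi * sigma), atol=1e-6)


def test_per_interval_terms_sum_to_value(lv_net, lv_series):
    obj = mss_objective(lv_series, lv_net, LV_THETA)
    assert obj.per_interval.size == lv_series.n_intervals
    assert np.isclose(obj.value, obj.per_interval.sum(), atol=1e-10)


def test_multiple_shooting_locality(lv_net, lv_series):
    """Perturbing datum i only touches the two adjoining interval terms."""
    base = mss_objective(lv_series, lv_net, LV_THETA).per_interval
    i = 17
    states = lv_series.states.copy()
    states[i] += [3, -2]
    bumped = TimeSeries(lv_series.times, states, lv_series.species_names)
    pert = mss_objective(bumped, lv_net, LV_THETA).per_interval
    changed = np.nonzero(base != pert)[0]
    assert set(changed) <= {i - 1, i}
    assert base[i - 1] != pert[i - 1]


def test_full_observation_reduces_partial_to_plain(lv_net, lv_series):
    om = ObservationModel.fully_observed(lv_net)
    a = mss_objective(lv_series, lv_net, LV_THETA)
    b = mss_objective_partial(lv_series, lv_net, LV_THETA, obs_model=om)
    assert abs(a.value - b.value) < 1e-12
    assert np.max(np.abs(a.per_interval - b.per_interval)) < 1e-12


def test_zero_measurement_noise_equals_partial(lv_net, lv_series):
    om = ObservationModel([0], sigma_meas=np.zeros((1, 1)))
    obs = lv_series.select_species([0])
    a = mss_objective_partial(obs, lv_net, LV_THETA, nu0_hid=[79.0], obs_model=om)
    b = mss_objective_noise(obs, lv_net, LV_THETA, nu0_hid=[79.0], obs_model=om)
    assert abs(a.value - b.value) < 1e-12


def test_marginal_dimension_is_observed_count(lv_net, lv_series):
    om = ObservationModel([0])
    obs = lv_series.select_species([0])
    obj = mss_objective_partial(obs, lv_net, LV_THETA, nu0_hid=[79.0], obs_model=om)
    assert obj.hidden_path.shape == (lv_series.n_intervals, 1)


def test_hidden_path_matches_independent_propagation(lv_net, lv_series):
    """Recompute the hidden predator chain step by step with scipy directly."""
    om = ObservationModel([0])
    obs = lv_series.select_species([0])
    obj = mss_objective_partial(
        obs, lv_net, LV_THETA, nu0_hid=[79.0], obs_model=om,
        options=IntegratorOptions(method="rk4", n_steps=24),
    )
    th1, th2, th3 = LV_THETA

    def rhs(_t, y):
        return [th1 * y[0] - th2 * y[0] * y[1], th2 * y[0] * y[1] - th3 * y[1]]

    y2 = 79.0
    for i in range(lv_series.n_intervals):
        assert abs(obj.hidden_path[i, 0] - y2) < 1e-5
        sol = solve_ivp(
            rhs, (0, 1.0), [float(obs.states[i, 0]), y2],
            rtol=1e-10, atol=1e-12,
        )
        y2 = sol.y[1, -1]


def test_noise_dominated_limit_washes_out_theta(id_net, id_series):
    om = ObservationModel([0])
    sig = 1e6
    a = mss_objective_noise(id_series, id_net, ID_THETA, obs_model=om, sigma=sig)
    b = mss_objective_noise(id_series, id_net, ID_THETA * 3, obs_model=om, sigma=sig)
    const = 0.5 * np.log(2 * np.pi * sig**2)
    assert np.max(np.abs(a.per_interval - const)) < 1e-3
    assert abs(a.value - b.value) < 1e-3


def test_constant_variance_is_shifted_least_squares(id_net, id_series):
    c = 7.0
    obj = constant_variance_objective(id_series, id_net, ID_THETA, c=c)
    means, _ = integrate_moments_batch(
        id_net, id_series.states[:-1].astype(float), ID_THETA, id_series.dts,
        mean_only=True,
    )
    ss = np.sum((id_series.states[1:] - means) ** 2)
    n, D = id_series.n_intervals, 1
    expected = 0.5 * ss / c + 0.5 * n * D * np.log(2 * np.pi * c)
    assert np.isclose(obj.value, expected, atol=1e-8)


def test_constant_variance_minimiser_is_c_invariant(id_net):
    # 101-point design: the least-squares optimum is well determined there
    # (short near-steady series leave a flat ridge in the absolute rates)
    ts = gillespie_simulate(id_net, [20], 10.0 * np.arange(101), ID_THETA, seed=9)
    res1 = estimate(
        ts, id_net, init_theta=[0.4, 0.02],
        options={"objective": "const", "const_c": 1.0},
    )
    res7 = estimate(
        ts, id_net, init_theta=[0.4, 0.02],
        options={"objective": "const", "const_c": 7.0},
    )
    assert np.max(np.abs(res1.params - res7.params) / res7.params) < 1e-4


def test_gross_misspecification_raises_objective(id_net):
    grid = 2.0 * np.arange(21)
    diffs = []
    for s in range(20):
        ts = gillespie_simulate(id_net, [20], grid, ID_THETA, seed=200 + s)
        good = mss_objective(ts, id_net, ID_THETA).value
        bad = mss_objective(ts, id_net, 10 * ID_THETA).value
        diffs.append(bad - good)
    assert np.mean(diffs) > 0


def test_objective_continuous_on_theta_grid(id_net, id_series):
    for f1 in (0.5, 0.8, 1.0, 1.3, 2.0):
        for f2 in (0.5, 1.0, 2.0):
            val = mss_objective(id_series, id_net, ID_THETA * [f1, f2]).value
            assert np.isfinite(val)


def test_sigma_estimation_recovers_noise_level(ar_net):
    """Joint (theta, sigma) fit on noisy data finds the noise level."""
    from conftest import AR_THETA
    from mssfit import MSSModel, add_measurement_noise

    grid = 0.1 * np.arange(500)
    ts = gillespie_simulate(ar_net, [6, 6, 8, 25], grid, AR_THETA, seed=21)
    noisy = add_measurement_noise(ts, 0.5, seed=22)
    model = MSSModel(noisy, ar_net, nu0_hid=None, estimate_sigma=True)
    res = model.fit(start_params=AR_THETA, start_sigma=1.0)
    assert res.sigma is not None
    assert abs(res.sigma - 0.5) / 0.5 < 0.4
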