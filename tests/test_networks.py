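"""Reaction-network construction, propensities, Jacobian and diffusion."""
import numpy as np
import pytest

from mssfit import (
    Factor,
    NetworkError,
    RateLaw,
    ReactionNetwork,
    build_autoreg,
    build_immigration_death,
    build_lotka_volterra,
    diffusion_matrix,
    get_model,
    jacobian,
    network_from_dict,
    network_from_file,
    ode_rhs,
    propensities,
)
from conftest import AR_THETA, ID_THETA, LV_THETA


def _random_states(net, rng, n=5):
    return rng.uniform(0.5, 30.0, size=(n, net.n_species))


# ---------------------------------------------------------------------------
# propensities
# ---------------------------------------------------------------------------

def test_propensity_values():
    idn = build_immigration_death()
    assert np.allclose(propensities(idn, [10], [0.6, 0.03]), [0.6, 0.3])
    lv = build_lotka_volterra()
    assert np.allclose(
        propensities(lv, [71, 79], LV_THETA), [35.5, 14.0225, 23.7]
    )


@pytest.mark.parametrize("name", ["immigration_death", "autoreg", "lotka_volterra"])
def test_zero_state_kills_consuming_reactions(name):
    net = get_model(name)
    x = np.zeros(net.n_species)
    v = propensities(net, x, np.ones(net.n_params))
    consuming = np.any(net.educts > 0, axis=0)
    assert np.all(v[consuming] == 0)
    assert np.all(v >= 0)


def test_propensity_input_validation(id_net):
    with pytest.raises(NetworkError):
        propensities(id_net, [-1.0], ID_THETA)
    with pytest.raises(NetworkError):
        propensities(id_net, [1.0], [0.6])


def test_stoichiometry_is_products_minus_educts():
    for name in ("immigration_death", "autoreg", "lotka_volterra"):
        net = get_model(name)
        assert np.array_equal(net.S, net.products - net.educts)


def test_immigration_death_stoichiometry(id_net):
    assert np.array_equal(id_net.S, [[1, -1]])


def test_lotka_volterra_stoichiometry(lv_net):
    assert np.array_equal(lv_net.S, [[1, -1, 0], [0, 1, -1]])


def test_autoreg_repression_column(ar_net):
    # DNA + P2 -> DNA.P2 on the reduced (DNA, P2, mRNA, P) space
    assert np.array_equal(ar_net.S[:, 0], [-1, -1, 0, 0])


# ---------------------------------------------------------------------------
# Jacobian and diffusion
# ---------------------------------------------------------------------------

def test_immigration_death_jacobian_constant(id_net):
    for x in ([0.0], [7.0], [100.0]):
        assert np.allclose(jacobian(id_net, x, ID_THETA), [[-ID_THETA[1]]])


def test_lv_jacobian_traceless_at_equilibrium(lv_net):
    th1, th2, th3 = LV_THETA
    eq = [th3 / th2, th1 / th2]  # (120, 200)
    J = jacobian(lv_net, eq, LV_THETA)
    assert abs(np.trace(J)) < 1e-12
    assert np.max(np.abs(ode_rhs(lv_net, eq, LV_THETA))) < 1e-12


@pytest.mark.parametrize("name,theta", [
    ("immigration_death", ID_THETA),
    ("lotka_volterra", LV_THETA),
    ("autoreg", AR_THETA),
])
def test_jacobian_matches_central_differences(name, theta):
    net = get_model(name)
    rng = np.random.default_rng(11)
    h = 1e-5
    for x in _random_states(net, rng):
        J = jacobian(net, x, theta)
        J_num = np.empty_like(J)
        for i in range(net.n_species):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            J_num[:, i] = (
                ode_rhs(net, xp, theta) - ode_rhs(net, xm, theta)
            ) / (2 * h)
        assert np.max(np.abs(J - J_num)) < 1e-6


def test_immigration_death_diffusion_scalar(id_net):
    D = diffusion_matrix(id_net, [20], [0.6, 0.03])
    assert np.allclose(D, [[1.2]])


def test_lv_diffusion_structure(lv_net):
    x = [71.0, 79.0]
    v = propensities(lv_net, x, LV_THETA)
    D = diffusion_matrix(lv_net, x, LV_THETA)
    expected = np.array([[v[0] + v[1], -v[1]], [-v[1], v[1] + v[2]]])
    assert np.allclose(D, expected)


@pytest.mark.parametrize("name,theta", [
    ("immigration_death", ID_THETA),
    ("lotka_volterra", LV_THETA),
    ("autoreg", AR_THETA),
])
def test_diffusion_symmetric_psd(name, theta):
    net = get_model(name)
    rng = np.random.default_rng(5)
    for x in _random_states(net, rng):
        D = diffusion_matrix(net, x, theta)
        assert np.allclose(D, D.T)
        assert np.min(np.linalg.eigvalsh(D)) >= -1e-12


# ---------------------------------------------------------------------------
# printed rate-equation right-hand sides
# ---------------------------------------------------------------------------

def _id_rhs(x, th):
    return np.array([th[0] - th[1] * x[0]])


def _lv_rhs(x, th):
    y1, y2 = x
    return np.array([th[0] * y1 - th[1] * y1 * y2, th[1] * y1 * y2 - th[2] * y2])


def _autoreg_rhs(x, th, dna_t=10):
    dna, p2, mrna, p = x
    dna_p2 = dna_t - dna
    return np.array(
        [
            -th[0] * dna * p2 + th[1] * dna_p2,
            -th[0] * dna * p2 + th[1] * dna_p2 + th[4] * p**2 - th[5] * p2,
            th[2] * dna - th[3] * mrna,
            -2 * th[4] * p**2 + 2 * th[5] * p2 + th[6] * mrna - th[7] * p,
        ]
    )


@pytest.mark.parametrize("name,theta,ref", [
    ("immigration_death", ID_THETA, _id_rhs),
    ("lotka_volterra", LV_THETA, _lv_rhs),
    ("autoreg", AR_THETA, _autoreg_rhs),
])
def test_sv_matches_textbook_rhs(name, theta, ref):
    net = get_model(name)
    rng = np.random.default_rng(3)
    for x in _random_states(net, rng):
        if name == "autoreg":
            x[0] = rng.uniform(0, 10)  # DNA below the conserved total
        assert np.max(np.abs(ode_rhs(net, x, theta) - ref(x, theta))) < 1e-12


# ---------------------------------------------------------------------------
# options, builders, files
# ---------------------------------------------------------------------------

def test_combinatorial_dimerisation_option():
    net = build_autoreg(10, combinatorial_dimer=True)
    p = 7.0
    v = propensities(net, [5, 3, 2, p], AR_THETA)
    assert np.isclose(v[4], AR_THETA[4] * p * (p - 1) / 2)


def test_autoreg_requires_positive_dna_total():
    with pytest.raises(NetworkError):
        build_autoreg(0)


def test_conserved_total_must_annihilate_stoichiometry():
    # reversible isomerisation A <-> B conserves A + B
    net = ReactionNetwork(
        species_names=["A", "B"],
        educts=[[1, 0], [0, 1]],
        products=[[0, 1], [1, 0]],
        rate_laws=[RateLaw(0, (Factor.power(0),)), RateLaw(1, (Factor.power(1),))],
        param_names=["kf", "kr"],
        conserved_totals=[([1.0, 1.0], 10.0)],
    )
    assert np.allclose(np.array([1.0, 1.0]) @ net.S, 0)
    with pytest.raises(NetworkError):
        ReactionNetwork(
            species_names=["A", "B"],
            educts=[[1, 0], [0, 1]],
            products=[[0, 1], [1, 0]],
            rate_laws=[RateLaw(0, (Factor.power(0),)), RateLaw(1, (Factor.power(1),))],
            param_names=["kf", "kr"],
            conserved_totals=[([1.0, 0.0], 10.0)],
        )


def test_network_from_dict_matches_builtin(id_net):
    defn = {
        "species": ["X"],
        "reactions": [
            {"educts": {}, "products": {"X": 1}, "parameter": "theta1"},
            {"educts": {"X": 1}, "products": {}, "parameter": "theta2"},
        ],
    }
    net = network_from_dict(defn)
    x, th = [13.0], [0.4, 0.07]
    assert np.allclose(propensities(net, x, th), propensities(id_net, x, th))


def test_network_from_yaml_file(tmp_path):
    path = tmp_path / "model.yaml"
    path.write_text(
        "species: [Y1, Y2]\n"
        "reactions:\n"
        "  - {educts: {Y1: 1}, products: {Y1: 2}, parameter: a}\n"
        "  - {educts: {Y1: 1, Y2: 1}, products: {Y2: 2}, parameter: b}\n"
        "  - {educts: {Y2: 1}, products: {}, parameter: c}\n"
    )
    net = network_from_file(path)
    ref = build_lotka_volterra()
    x = [11.0, 5.0]
    assert np.allclose(
        propensities(net, x, LV_THETA), propensities(ref, x, LV_THETA)
    )


def test_reordered_network_permutes_quantities(lv_net):
    perm = [1, 0]
    net2 = lv_net.reordered(perm)
    x = np.array([40.0, 60.0])
    v1 = propensities(lv_net, x, LV_THETA)
    v2 = propensities(net2, x[perm], LV_THETA)
    assert np.allclose(v1, v2)
    J1 = jacobian(lv_net, x, LV_THETA)
    J2 = jacobian(net2, x[perm], LV_THETA)
    assert np.allclose(J1[np.ix_(perm, perm)], J2)
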