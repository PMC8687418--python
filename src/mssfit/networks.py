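"""Mass-action reaction networks and their local characteristics.

A network couples a stoichiometric matrix ``S`` (species x reactions) with
mass-action rate laws.  Everything downstream -- exact Gillespie simulation,
the interval-wise linear noise approximation (LNA) and the transition
likelihood -- is driven by three quantities evaluated at a state ``x``:

* the propensity vector ``v(x, theta)``,
* the drift Jacobian ``J(x, theta) = S dv/dx``,
* the diffusion matrix ``D(x, theta) = S diag(v) S^T``.

Rate laws are products of polynomial factors in single species counts, which
covers plain mass action (``x^q``), the combinatorial convention
(``x (x-1) ... / q!``) and conserved-moiety complements (``total - x``), each
with an exact analytic derivative.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Factor",
    "RateLaw",
    "ReactionNetwork",
    "NetworkError",
    "propensities",
    "jacobian",
    "diffusion_matrix",
    "ode_rhs",
    "build_immigration_death",
    "build_autoreg",
    "build_lotka_volterra",
    "get_model",
    "network_from_dict",
    "network_from_file",
    "MODEL_REGISTRY",
]


class NetworkError(ValueError):
    """Raised for malformed networks or invalid evaluation inputs."""


def _falling_factorial_coeffs(order: int) -> np.ndarray:
    # ascending coefficients of g(g-1)...(g-order+1)/order!
    c = np.array([1.0])
    for k in range(order):
        c = np.polynomial.polynomial.polymul(c, np.array([-float(k), 1.0]))
    return c / math.factorial(order)


@dataclass(frozen=True)
class Factor:
    """One polynomial factor ``p(offset + sign * x[species])`` of a rate law."""

    species: int
    coeffs: tuple  # ascending polynomial coefficients in g = offset + sign*x
    offset: float = 0.0
    sign: int = 1

    @classmethod
    def power(cls, species: int, exponent: int = 1) -> "Factor":
        c = np.zeros(exponent + 1)
        c[exponent] = 1.0
        return cls(species, tuple(c))

    @classmethod
    def combinatorial(cls, species: int, order: int) -> "Factor":
        """Combinatorial mass-action factor ``x(x-1).../order!`` (binomial hazard)."""
        return cls(species, tuple(_falling_factorial_coeffs(order)))

    @classmethod
    def complement(cls, species: int, total: float) -> "Factor":
        """Conserved-moiety complement ``total - x[species]``."""
        return cls(species, (0.0, 1.0), offset=float(total), sign=-1)

    @property
    def dcoeffs(self) -> np.ndarray:
        return np.polynomial.polynomial.polyder(np.asarray(self.coeffs))

    def value(self, x):
        g = self.offset + self.sign * np.asarray(x)
        return np.polynomial.polynomial.polyval(g, np.asarray(self.coeffs))

    def derivative(self, x):
        """d/dx of the factor (chain rule includes ``sign``)."""
        g = self.offset + self.sign * np.asarray(x)
        return self.sign * np.polynomial.polynomial.polyval(g, self.dcoeffs)


@dataclass(frozen=True)
class RateLaw:
    """Mass-action descriptor: one rate constant times a product of factors."""

    param_index: int
    factors: tuple = ()


@dataclass
class ReactionNetwork:
    species_names: list
    educts: np.ndarray  # D x r non-negative integers (q_ij)
    products: np.ndarray  # D x r non-negative integers (u_ij)
    rate_laws: list
    param_names: list
    volume: float = 1.0
    conserved_totals: list = field(default_factory=list)  # (weights, total) pairs
    name: str = ""

    def __post_init__(self):
        self.educts = np.asarray(self.educts, dtype=np.int64)
        self.products = np.asarray(self.products, dtype=np.int64)
        D, r = self.educts.shape
        if self.products.shape != (D, r):
            raise NetworkError("educt and product matrices must share shape")
        if len(self.species_names) != D:
            raise NetworkError("species_names length does not match matrices")
        if len(self.rate_laws) != r:
            raise NetworkError("one rate law per reaction required")
        if np.any(self.educts < 0) or np.any(self.products < 0):
            raise NetworkError("educt/product counts must be non-negative")
        if self.volume <= 0:
            raise NetworkError("volume must be positive")
        self.stoichiometry = self.products - self.educts
        for weights, _total in self.conserved_totals:
            combo = np.asarray(weights, dtype=float) @ self.stoichiometry
            if np.max(np.abs(combo)) > 1e-12:
                raise NetworkError(
                    "declared conserved total is not invariant under the reactions"
                )

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.educts.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.educts.shape[1]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometry

    def check_theta(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise NetworkError(
                f"expected {self.n_params} parameters, got shape {theta.shape}"
            )
        return theta

    def reordered(self, order) -> "ReactionNetwork":
        """Return the same network with species permuted by ``order``."""
        order = list(order)
        remap = {old: new for new, old in enumerate(order)}
        laws = [
            RateLaw(
                rl.param_index,
                tuple(
                    Factor(remap[f.species], f.coeffs, f.offset, f.sign)
                    for f in rl.factors
                ),
            )
            for rl in self.rate_laws
        ]
        return ReactionNetwork(
            species_names=[self.species_names[i] for i in order],
            educts=self.educts[order],
            products=self.products[order],
            rate_laws=laws,
            param_names=list(self.param_names),
            volume=self.volume,
            conserved_totals=[(np.asarray(w)[order], t) for w, t in self.conserved_totals],
            name=self.name,
        )


# ---------------------------------------------------------------------------
# vectorised evaluation of v, dv/dx
# ---------------------------------------------------------------------------

def _rate_terms(net: ReactionNetwork, X: np.ndarray, theta: np.ndarray, deriv: bool):
    """Propensities (and optionally their state derivatives) for a batch of states.

    X has shape (n, D).  Returns V (n, r) with the rate constants included and,
    when ``deriv``, dV (n, r, D).
    """
    n = X.shape[0]
    r = net.n_reactions
    V = np.empty((n, r))
    dV = np.zeros((n, r, net.n_species)) if deriv else None
    for j, rl in enumerate(net.rate_laws):
        th = theta[rl.param_index]
        if not rl.factors:
            V[:, j] = th
            continue
        vals = [f.value(X[:, f.species]) for f in rl.factors]
        prod = vals[0].copy()
        for v in vals[1:]:
            prod *= v
        V[:, j] = th * prod
        if deriv:
            for k, f in enumerate(rl.factors):
                dv = f.derivative(X[:, f.species])
                for m, v in enumerate(vals):
                    if m != k:
                        dv = dv * v
                dV[:, j, f.species] += th * dv
    return V, dV


def propensities(net: ReactionNetwork, x, theta) -> np.ndarray:
    """Mass-action propensity vector ``v(x, theta)`` (length r)."""
    theta = net.check_theta(theta)
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_species,):
        raise NetworkError(f"state must have length {net.n_species}")
    if np.any(x < 0):
        raise NetworkError("state components must be non-negative")
    V, _ = _rate_terms(net, x[None, :], theta, deriv=False)
    return V[0]


def jacobian(net: ReactionNetwork, x, theta) -> np.ndarray:
    """Drift Jacobian ``J(x, theta) = S dv/dx`` (D x D, closed form)."""
    theta = net.check_theta(theta)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise NetworkError("state components must be non-negative")
    _, dV = _rate_terms(net, x[None, :], theta, deriv=True)
    return net.S @ dV[0]


def diffusion_matrix(net: ReactionNetwork, x, theta) -> np.ndarray:
    """Diffusion matrix ``D_ij = sum_k S_ik S_jk v_k(x, theta)`` (symmetric PSD)."""
    theta = net.check_theta(theta)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise NetworkError("state components must be non-negative")
    V, _ = _rate_terms(net, x[None, :], theta, deriv=False)
    return (net.S * V[0]) @ net.S.T


def ode_rhs(net: ReactionNetwork, x, theta) -> np.ndarray:
    """Deterministic rate-equation right-hand side ``S v(x, theta)``."""
    theta = net.check_theta(theta)
    X = np.asarray(x, dtype=float)[None, :]
    V, _ = _rate_terms(net, X, theta, deriv=False)
    return net.S @ V[0]


# ---------------------------------------------------------------------------
# built-in benchmark models
# ---------------------------------------------------------------------------

def build_immigration_death() -> ReactionNetwork:
    """Immigration-death process: 0 -> X at rate theta1, X -> 0 at rate theta2*x.

    One species, two reactions, S = (1, -1); the deterministic steady state is
    theta1/theta2.
    """
    return ReactionNetwork(
        species_names=["X"],
        educts=np.array([[0, 1]]),
        products=np.array([[1, 0]]),
        rate_laws=[
            RateLaw(0),
            RateLaw(1, (Factor.power(0),)),
        ],
        param_names=["theta1", "theta2"],
        name="immigration_death",
    )


def build_autoreg(dna_total: int = 10, combinatorial_dimer: bool = False) -> ReactionNetwork:
    """Prokaryotic auto-regulatory gene network, reduced to 4 independent species.

    Species (in order): DNA, P2, mRNA, P.  The repressed promoter DNA.P2 is
    eliminated through the conserved total DNA.P2 = dna_total - DNA, which keeps
    the LNA covariance non-singular.  Eight reactions:

    1. DNA + P2 -> DNA.P2        theta1 * DNA * P2
    2. DNA.P2 -> DNA + P2        theta2 * (dna_total - DNA)
    3. DNA -> DNA + mRNA         theta3 * DNA
    4. mRNA -> 0                 theta4 * mRNA
    5. 2P -> P2                  theta5 * P^2   (or theta5*P(P-1)/2 with
                                 ``combinatorial_dimer=True``)
    6. P2 -> 2P                  theta6 * P2
    7. mRNA -> mRNA + P          theta7 * mRNA
    8. P -> 0                    theta8 * P
    """
    if dna_total <= 0:
        raise NetworkError("dna_total must be a positive integer")
    # rows: DNA, P2, mRNA, P; columns: reactions 1..8
    educts = np.array(
        [
            [1, 0, 1, 0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0, 1, 0, 0],
            [0, 0, 0, 1, 0, 0, 1, 0],
            [0, 0, 0, 0, 2, 0, 0, 1],
        ]
    )
    products = np.array(
        [
            [0, 1, 1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 1, 0, 0, 0],
            [0, 0, 1, 0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0, 2, 1, 0],
        ]
    )
    dimer = (
        Factor.combinatorial(3, 2) if combinatorial_dimer else Factor.power(3, 2)
    )
    laws = [
        RateLaw(0, (Factor.power(0), Factor.power(1))),
        RateLaw(1, (Factor.complement(0, dna_total),)),
        RateLaw(2, (Factor.power(0),)),
        RateLaw(3, (Factor.power(2),)),
        RateLaw(4, (dimer,)),
        RateLaw(5, (Factor.power(1),)),
        RateLaw(6, (Factor.power(2),)),
        RateLaw(7, (Factor.power(3),)),
    ]
    net = ReactionNetwork(
        species_names=["DNA", "P2", "mRNA", "P"],
        educts=educts,
        products=products,
        rate_laws=laws,
        param_names=[f"theta{i}" for i in range(1, 9)],
        name="autoreg",
    )
    net.dna_total = dna_total
    return net


def build_lotka_volterra() -> ReactionNetwork:
    """Stochastic Lotka-Volterra predator-prey model.

    Y1 -> 2 Y1 (prey birth, theta1*y1); Y1 + Y2 -> 2 Y2 (predation,
    theta2*y1*y2); Y2 -> 0 (predator death, theta3*y2).
    S = [[1, -1, 0], [0, 1, -1]].
    """
    return ReactionNetwork(
        species_names=["Y1", "Y2"],
        educts=np.array([[1, 1, 0], [0, 1, 1]]),
        products=np.array([[2, 0, 0], [0, 2, 0]]),
        rate_laws=[
            RateLaw(0, (Factor.power(0),)),
            RateLaw(1, (Factor.power(0), Factor.power(1))),
            RateLaw(2, (Factor.power(1),)),
        ],
        param_names=["theta1", "theta2", "theta3"],
        name="lotka_volterra",
    )


MODEL_REGISTRY = {
    "immigration_death": build_immigration_death,
    "autoreg": build_autoreg,
    "lotka_volterra": build_lotka_volterra,
}


def get_model(name: str, **kwargs) -> ReactionNetwork:
    """Look up a built-in benchmark network by name."""
    try:
        builder = MODEL_REGISTRY[name]
    except KeyError:
        raise NetworkError(
            f"unknown model {name!r}; built-ins: {sorted(MODEL_REGISTRY)}"
        ) from None
    return builder(**kwargs)


# ---------------------------------------------------------------------------
# model definition files (JSON / YAML)
# ---------------------------------------------------------------------------

def network_from_dict(defn: dict) -> ReactionNetwork:
    """Build a network from a plain-dict model definition.

    Expected keys: ``species`` (list of names), ``reactions`` (list of dicts
    with ``educts``/``products`` name->count maps, ``parameter`` name, optional
    ``combinatorial`` flag and optional ``complement`` {species, total} rate
    modifier), optional ``volume`` and ``conserved_totals``.
    """
    species = list(defn["species"])
    idx = {s: i for i, s in enumerate(species)}
    reactions = defn["reactions"]
    D, r = len(species), len(reactions)
    educts = np.zeros((D, r), dtype=int)
    products = np.zeros((D, r), dtype=int)
    param_names = []
    laws = []
    for j, rx in enumerate(reactions):
        for s, c in rx.get("educts", {}).items():
            educts[idx[s], j] = c
        for s, c in rx.get("products", {}).items():
            products[idx[s], j] = c
        pname = rx["parameter"]
        if pname not in param_names:
            param_names.append(pname)
        factors = []
        if "complement" in rx:
            comp = rx["complement"]
            factors.append(Factor.complement(idx[comp["species"]], comp["total"]))
        else:
            for s, c in rx.get("educts", {}).items():
                if rx.get("combinatorial", False):
                    factors.append(Factor.combinatorial(idx[s], c))
                else:
                    factors.append(Factor.power(idx[s], c))
        laws.append(RateLaw(param_names.index(pname), tuple(factors)))
    conserved = [
        (np.asarray(ct["weights"], dtype=float), float(ct["total"]))
        for ct in defn.get("conserved_totals", [])
    ]
    return ReactionNetwork(
        species_names=species,
        educts=educts,
        products=products,
        rate_laws=laws,
        param_names=param_names,
        volume=float(defn.get("volume", 1.0)),
        conserved_totals=conserved,
        name=defn.get("name", ""),
    )


def network_from_file(path) -> ReactionNetwork:
    """Load a model definition from a JSON or YAML file."""
    with open(path) as fh:
        text = fh.read()
    try:
        defn = json.loads(text)
    except json.JSONDecodeError:
        defn = yaml.safe_load(text)
    return network_from_dict(defn)
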