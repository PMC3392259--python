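"""Built-in model fixtures and model-construction operators.

The central fixture is a three-reaction linear pathway with linlog kinetics:
an external substrate S is converted to an external product P through two
internal metabolites,

    S --R1--> M1 --R2--> M2 --R3--> P

with reference state x0 = (1, 1), J0 = (1, 1, 1), e0 = (1, 1, 1).  The base
elasticities are: R1 is product-inhibited by M1 (eps = -0.5) and driven by
external S (eps = +1); R2 is driven by its substrate M1 (+0.5); R3 is driven
by M2 (+0.5).  M2 exerts no kinetic effect on R1 or R2 in the base network,
so large M2 excursions leave the pathway flux unchanged.  Two optional
regulatory links can be switched on: end-product feedback inhibition of R1
by M2 (elasticity <= 0) and feedforward activation of R3 by M1 (>= 0).

The exact elasticity values are package defaults chosen to satisfy the
qualitative structure above; every value can be overridden.

The module also provides environment couplings: a chemostat balance that
turns a clamped external substrate into a dynamic species, a multi-strain
Monod competition simulator with an enzyme-cost penalty on growth, and a
"turbo design" rescue operator that adds a T6P-like storage branch whose
intermediate feedback-inhibits the substrate kinase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetic_core import (
    CONC_FLOOR,
    KineticModel,
    LinlogModel,
    ReferenceState,
    check_reference_consistency,
)


class FeatureUnavailable(RuntimeError):
    """An optional, externally parameterized feature was requested without
    its parameter source."""


# -----------------------------------------------------------------------------
# toy linear pathway
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyFixtureOptions:
    """Regulatory-link options for the toy pathway.

    feedback_strength : elasticity of R1 towards M2, <= 0 (end-product
        feedback inhibition; 0 disables the link).
    feedforward_strength : elasticity of R3 towards M1, >= 0 (feedforward
        activation; 0 disables the link).
    eps_m1_r1, eps_m1_r2, eps_m2_r3, eps_s_r1 : base elasticities,
        overridable for sensitivity studies.
    """

    feedback_strength: float = 0.0
    feedforward_strength: float = 0.0
    eps_m1_r1: float = -0.5
    eps_m1_r2: float = 0.5
    eps_m2_r3: float = 0.5
    eps_s_r1: float = 1.0


def build_toy_model(options: ToyFixtureOptions | None = None) -> LinlogModel:
    """Construct the three-reaction linlog pathway fixture."""
    opt = options or ToyFixtureOptions()
    if opt.feedback_strength > 0:
        raise ValueError("feedback_strength must be <= 0 (inhibition)")
    if opt.feedforward_strength < 0:
        raise ValueError("feedforward_strength must be >= 0 (activation)")
    reference = ReferenceState(
        x0=np.array([1.0, 1.0]),
        c0=np.array([1.0, 1.0]),
        J0=np.array([1.0, 1.0, 1.0]),
        e0=np.array([1.0, 1.0, 1.0]),
    )
    Ex = np.array([
        [opt.eps_m1_r1, opt.feedback_strength],   # R1: inhibited by M1, optional fb by M2
        [opt.eps_m1_r2, 0.0],                     # R2: driven by M1, M2 inert
        [opt.feedforward_strength, opt.eps_m2_r3] # R3: driven by M2, optional ff by M1
    ])
    Ec = np.array([
        [opt.eps_s_r1, 0.0],  # R1 driven by external substrate
        [0.0, 0.0],
        [0.0, 0.0],           # product P kinetically inert (far from equilibrium)
    ])
    model = LinlogModel(
        internal_species=("M1", "M2"),
        external_species=("S", "P"),
        reactions=("R1", "R2", "R3"),
        N=np.array([[1.0, -1.0, 0.0],
                    [0.0, 1.0, -1.0]]),
        reference=reference,
        irreversible=frozenset({"R1", "R2", "R3"}),
        Ex=Ex,
        Ec=Ec,
        name="toy-linear-pathway",
    )
    check_reference_consistency(model)
    return model


# -----------------------------------------------------------------------------
# chemostat coupling
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemostatEnv:
    """Chemostat environment parameters.

    D : dilution rate (1/time).
    S_in : feed substrate concentration; if None it is derived on attachment
        so that the reference state is a steady state of the coupled system.
    X : biomass density of the (sub)population (biomass units/volume).
    Ks : Monod half-saturation constant (concentration units).
    mu0 : maximum specific growth rate; must exceed D so the chemostat has a
        positive residual substrate S* = Ks*D/(mu0-D) at which growth
        balances dilution.
    cost_coeff : linear enzyme-cost penalty on growth (dimensionless):
        mu is multiplied by (1 - cost_coeff*(sum(e)/sum(e0) - 1)).
    yield_coeff : biomass produced per substrate consumed.
    """

    D: float = 0.1
    S_in: float | None = None
    X: float = 1.0
    Ks: float = 0.1
    mu0: float = 0.2
    cost_coeff: float = 0.1
    yield_coeff: float = 0.5

    def __post_init__(self):
        if self.D <= 0 or self.Ks <= 0:
            raise ValueError("D and Ks must be positive")
        if self.mu0 <= self.D:
            raise ValueError("mu0 must exceed D (otherwise washout)")

    @property
    def S_star(self) -> float:
        """Residual substrate at which mu(S) = D for a cost-neutral strain."""
        return self.Ks * self.D / (self.mu0 - self.D)

    def growth_rate(self, S: float, total_enzyme_rel: float = 1.0,
                    uptake_rel: float = 1.0) -> float:
        """Monod growth with uptake-capacity scaling and enzyme-cost penalty."""
        monod = self.mu0 * uptake_rel * S / (self.Ks + S)
        return monod * (1.0 - self.cost_coeff * (total_enzyme_rel - 1.0))


class ChemostatModel(KineticModel):
    """A kinetic model coupled to a fermentor substrate balance.

    The designated external substrate becomes a dynamic state variable with
    dS/dt = D*(S_in - S) - q_upt*X, where q_upt is the flux of the designated
    uptake reaction.  The internal state vector is extended to
    ``[x_internal..., S]``.
    """

    def __init__(self, base: KineticModel, env: ChemostatEnv,
                 substrate: str, uptake_reaction: str):
        if substrate not in base.external_species:
            raise ValueError(f"{substrate!r} is not an external species of the model")
        if uptake_reaction not in base.reactions:
            raise ValueError(f"{uptake_reaction!r} is not a reaction of the model")
        self.base = base
        self.env = env
        self.substrate = substrate
        self.uptake_reaction = uptake_reaction
        self._s_idx = base.external_species.index(substrate)
        self._u_idx = base.reactions.index(uptake_reaction)
        S0 = base.reference.c0[self._s_idx]
        q0 = base.reference.J0[self._u_idx]
        S_in = env.S_in
        if S_in is None:
            # feed chosen so the reference is a steady state of the coupling
            S_in = S0 + q0 * env.X / env.D
        self.S_in = float(S_in)
        ref = base.reference
        super().__init__(
            internal_species=base.internal_species + (substrate,),
            external_species=tuple(s for s in base.external_species if s != substrate),
            reactions=base.reactions,
            N=np.vstack([base.N, np.zeros(base.n_reactions)]),
            reference=ReferenceState(
                x0=np.append(ref.x0, S0),
                c0=np.delete(ref.c0, self._s_idx),
                J0=ref.J0.copy(),
                e0=ref.e0.copy(),
            ),
            name=base.name + "+chemostat",
            irreversible=base.irreversible,
        )

    def _split(self, x):
        return x[:-1], x[-1]

    def _full_c(self, S, c=None):
        c_base = self.base.reference.c0.copy() if c is None else None
        if c_base is None:
            c_base = np.insert(np.asarray(c, dtype=float), self._s_idx, 0.0)
        c_base[self._s_idx] = S
        return c_base

    def rates(self, r, x, c=None):
        x_int, S = self._split(np.asarray(x, dtype=float))
        return self.base.rates(r, x_int, self._full_c(S, c))

    def ode_rhs(self, r, c=None):
        env = self.env

        def rhs(t, y):
            y = np.maximum(y, CONC_FLOOR)
            x_int, S = self._split(y)
            v = self.base.rates(r, x_int, self._full_c(S, c))
            dx = self.base.N @ v
            dS = env.D * (self.S_in - S) - v[self._u_idx] * env.X
            return np.append(dx, dS)

        return rhs


def attach_chemostat(model: KineticModel, env: ChemostatEnv,
                     substrate: str = "S",
                     uptake_reaction: str | None = None) -> ChemostatModel:
    """Couple a kinetic model to a chemostat substrate balance.

    The substrate species stops being clamped and follows
    dS/dt = D*(S_in - S) - q_upt*X.  When ``env.S_in`` is None the feed
    concentration is derived so that the model's reference state is also a
    steady state of the coupled system.
    """
    if uptake_reaction is None:
        uptake_reaction = model.reactions[0]
    return ChemostatModel(model, env, substrate, uptake_reaction)


# -----------------------------------------------------------------------------
# competition in the chemostat
# -----------------------------------------------------------------------------

@dataclass
class Strain:
    """A subpopulation competing in the chemostat.

    ``enzymes`` are levels relative to the wild-type reference; the first
    entry is taken as the substrate-uptake enzyme unless ``uptake_index``
    says otherwise.
    """

    name: str
    enzymes: np.ndarray
    X0: float = 1.0
    uptake_index: int = 0

    def __post_init__(self):
        self.enzymes = np.asarray(self.enzymes, dtype=float)

    @property
    def total_rel(self) -> float:
        return float(np.mean(self.enzymes))

    @property
    def uptake_rel(self) -> float:
        return float(self.enzymes[self.uptake_index])


def paper_style_strains(n_enzymes: int = 5,
                        uptake_boost: float = 1.6,
                        economy_factor: float = 0.7) -> list[Strain]:
    """The four canonical competition strains.

    wild-type: all enzymes at reference; economy: every enzyme scaled down
    (cheaper proteome, weaker uptake); competition: uptake enzyme boosted,
    rest at reference (stronger uptake, costlier proteome); trade-off:
    uptake boosted while the remaining enzymes are scaled down (strong
    uptake at roughly reference cost).
    """
    ones = np.ones(n_enzymes)
    econ = np.full(n_enzymes, economy_factor)
    comp = ones.copy()
    comp[0] = uptake_boost
    trade = np.full(n_enzymes, economy_factor)
    trade[0] = uptake_boost
    return [
        Strain("wild-type", ones),
        Strain("economy", econ),
        Strain("competition", comp),
        Strain("trade-off", trade),
    ]


def competition_simulate(strains: Sequence[Strain], env: ChemostatEnv,
                         t_end: float = 5000.0, n_points: int = 400):
    """Simulate multi-strain competition for a shared substrate pool.

    Per strain k: dX_k/dt = (mu_k - D) * X_k with
    mu_k = mu0 * u_k * S/(Ks+S) * (1 - cost_coeff*(sum(e_k)/sum(e0) - 1)),
    where u_k is the strain's relative uptake-enzyme level; the shared pool
    follows dS/dt = D*(S_in - S) - sum_k mu_k*X_k/Y.

    Returns a dict with keys ``t``, ``S``, ``X`` (n_strains x n_points),
    ``fractions`` (biomass fractions over time) and ``names``.  Total
    washout is reported in the result, not raised.
    """
    if not strains:
        raise ValueError("need at least one strain")
    if env.S_in is not None:
        env_Sin = env.S_in
    else:
        # default feed: residual substrate plus what sustains the initial
        # biomass at growth rate D
        env_Sin = env.S_star + sum(s.X0 for s in strains) / env.yield_coeff

    u = np.array([s.uptake_rel for s in strains])
    tot = np.array([s.total_rel for s in strains])
    cost = 1.0 - env.cost_coeff * (tot - 1.0)

    def rhs(t, y):
        X, S = y[:-1], max(y[-1], 0.0)
        mu = env.mu0 * u * S / (env.Ks + S) * cost
        dX = (mu - env.D) * X
        dS = env.D * (env_Sin - S) - float(mu @ X) / env.yield_coeff
        return np.append(dX, dS)

    y0 = np.append([s.X0 for s in strains], env.S_star)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=1e-8, atol=1e-12)
    X = np.maximum(sol.y[:-1], 0.0)
    total = X.sum(axis=0)
    washed_out = bool(total[-1] < 1e-9 * total[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(total > 0, X / np.maximum(total, 1e-300), 0.0)
    return {
        "t": sol.t,
        "S": sol.y[-1],
        "X": X,
        "fractions": fractions,
        "names": [s.name for s in strains],
        "washed_out": washed_out,
    }


# -----------------------------------------------------------------------------
# turbo-design rescue: storage-branch feedback inhibition of the kinase
# -----------------------------------------------------------------------------

class T6PInhibitedModel(KineticModel):
    """A model extended with a storage branch whose intermediate (T6P)
    feedback-inhibits the substrate kinase.

    Two first-order mass-action reactions are added: tps1 converts the
    kinase product (G6P) into T6P, tps2 drains T6P.  The kinase rate is
    multiplied by a non-competitive inhibition factor 1/(1 + T6P/Ki) and
    rescaled so that the original reference state (with T6P at its reference
    level and the storage branch carrying its reference flux) remains a
    steady state of the extended system.
    """

    def __init__(self, base: KineticModel, Ki: float, hk_reaction: str,
                 g6p_species: str, t6p0: float = 0.1, j_tps0: float = 0.01):
        if Ki <= 0:
            raise ValueError("Ki must be positive")
        if hk_reaction not in base.reactions:
            raise ValueError(f"model has no kinase reaction {hk_reaction!r}")
        if g6p_species not in base.internal_species:
            raise ValueError(f"model has no species {g6p_species!r}")
        self.base = base
        self.Ki = float(Ki)
        self.t6p0 = float(t6p0)
        self.j_tps0 = float(j_tps0)
        self._hk = base.reactions.index(hk_reaction)
        self._g6p = base.internal_species.index(g6p_species)
        ref = base.reference
        # the kinase must additionally supply the storage flux at reference
        J0_new = np.concatenate([ref.J0, [j_tps0, j_tps0]])
        J0_new[self._hk] = ref.J0[self._hk] + j_tps0
        self._hk_scale = ((ref.J0[self._hk] + j_tps0) / ref.J0[self._hk]
                          * (1.0 + t6p0 / Ki))
        self.k_tps1 = j_tps0 / ref.x0[self._g6p]
        self.k_tps2 = j_tps0 / t6p0
        n_int, n_rxn = base.N.shape
        N = np.zeros((n_int + 1, n_rxn + 2))
        N[:n_int, :n_rxn] = base.N
        N[self._g6p, n_rxn] = -1.0   # tps1 consumes G6P
        N[n_int, n_rxn] = 1.0        # tps1 produces T6P
        N[n_int, n_rxn + 1] = -1.0   # tps2 drains T6P
        super().__init__(
            internal_species=base.internal_species + ("T6P",),
            external_species=base.external_species,
            reactions=base.reactions + ("tps1", "tps2"),
            N=N,
            reference=ReferenceState(
                x0=np.append(ref.x0, t6p0),
                c0=ref.c0.copy(),
                J0=J0_new,
                e0=np.append(ref.e0, [1.0, 1.0]),
            ),
            irreversible=base.irreversible | {"tps1", "tps2"},
            name=base.name + "+T6P",
        )

    def rates(self, r, x, c=None):
        r = np.asarray(r, dtype=float)
        x = np.asarray(x, dtype=float)
        x_base, t6p = x[:-1], x[-1]
        v_base = self.base.rates(r[:-2], x_base, c)
        v_base[self._hk] *= self._hk_scale / (1.0 + t6p / self.Ki)
        v_tps1 = r[-2] * self.k_tps1 * x_base[self._g6p]
        v_tps2 = r[-1] * self.k_tps2 * t6p
        return np.concatenate([v_base, [v_tps1, v_tps2]])


def apply_t6p_inhibition(model: KineticModel, Ki: float,
                         hk_reaction: str = "HK", g6p_species: str = "G6P",
                         t6p0: float = 0.1, j_tps0: float = 0.01,
                         tol: float = 1e-9) -> T6PInhibitedModel:
    """Extend a model with the T6P storage branch and kinase inhibition.

    Reference invariance (the extended reference reproduces the extended J0
    and N @ J0 = 0) is verified on construction; a violation beyond ``tol``
    is a construction error.
    """
    ext = T6PInhibitedModel(model, Ki, hk_reaction, g6p_species,
                            t6p0=t6p0, j_tps0=j_tps0)
    check_reference_consistency(ext, atol=tol)
    return ext


# -----------------------------------------------------------------------------
# optional externally parameterized glycolysis model
# -----------------------------------------------------------------------------

def build_glycolysis_model(parameter_source=None) -> KineticModel:
    """Load an externally parameterized yeast glycolysis model.

    The full yeast glycolysis kinetics are not shipped with this package;
    they must be supplied externally, either as a file in the internal YAML
    model format or as a pre-built :class:`KineticModel`.  Without a
    parameter source the feature is disabled with a clear message.
    """
    if parameter_source is None:
        raise FeatureUnavailable(
            "the yeast glycolysis model requires an external parameter source "
            "(a kinetic model file in the internal YAML format, or a "
            "KineticModel built from the published kinetics); none was supplied"
        )
    if isinstance(parameter_source, KineticModel):
        check_reference_consistency(parameter_source)
        return parameter_source
    from .kinetic_core import load_model

    return load_model(parameter_source)


#: registry of built-in fixtures addressable by name from configs and the CLI
FIXTURES = {
    "toy": build_toy_model,
}


def get_fixture(name: str, **kwargs) -> KineticModel:
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown model fixture {name!r}; "
                         f"available: {sorted(FIXTURES)}") from None
    if kwargs and name == "toy":
        return builder(ToyFixtureOptions(**kwargs))
    return builder()
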