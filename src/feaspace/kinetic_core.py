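"""Kinetic model representation, rate evaluation, steady states and stability.

A kinetic metabolic model is the genotype->phenotype map of feasibility
analysis: a vector of relative enzyme levels ``r`` (dimensionless, 1 at the
reference state) is mapped through the model's rate laws and stoichiometry to
a steady-state physiological state (metabolite concentrations ``x`` and
fluxes ``J``).

Two solution routes are provided.  For linlog models -- rate laws linear in
the enzyme level and in logarithms of metabolite ratios -- the steady state
is available in closed form: writing ``z = ln(x/x0)``, mass balance
``N v = 0`` becomes the linear system ``N diag(r*J0) (k + Ex z) = 0`` where
``k`` collects the constant and external terms.  For arbitrary rate laws the
ODE system ``dx/dt = N v(r, x, c)`` is integrated until the relative rate of
change falls below tolerance.  The two routes agree to high precision on
linlog models and are used as mutual oracles in the test-suite.

Local stability is assessed from the eigenvalues of the system Jacobian
``A = N dv/dx`` at the steady state: a state is stable when every eigenvalue
has a strictly negative real part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger("feaspace")

# -- numerical policy ---------------------------------------------------------
#: relative rate-of-change threshold declaring an ODE trajectory stationary
STEADY_STATE_TOL = 1e-8
#: concentration floor used when normalising rates of change
CONC_FLOOR = 1e-12
#: maximum integration horizon (model time units)
T_MAX = 1e6
#: eigenvalues with real part above -EIG_TOL are labelled non-stable
EIG_TOL = 1e-10


class DimensionError(ValueError):
    """Vector/matrix shapes inconsistent with the model dimensions."""


class DomainError(ValueError):
    """Input outside the mathematical domain (e.g. log of a non-positive)."""


def _as1d(v, n: int, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (n,):
        raise DimensionError(f"{name} must have shape ({n},), got {a.shape}")
    return a


# -----------------------------------------------------------------------------
# domain types
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceState:
    """The reference steady state all relative quantities are measured against.

    Attributes
    ----------
    x0 : internal metabolite concentrations (model units, > 0)
    c0 : external metabolite concentrations (> 0)
    J0 : reference reaction fluxes (a steady state: N @ J0 == 0)
    e0 : reference enzyme levels (dimensionless, conventionally all 1)
    """

    x0: np.ndarray
    c0: np.ndarray
    J0: np.ndarray
    e0: np.ndarray

    def __post_init__(self):
        for name in ("x0", "c0", "J0", "e0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.x0 <= 0) or np.any(self.c0 <= 0):
            raise DomainError("reference concentrations must be strictly positive")


@dataclass
class KineticModel:
    """A kinetic metabolic model: stoichiometry, rate laws and reference state.

    ``rate_laws`` maps (r_i, x, c, params) -> rate for each reaction.  Rate
    laws must satisfy ``rate_law_i(1, x0, c0, params) == J0_i`` so that the
    reference state is reproduced at unit enzyme levels.  Rates are assumed
    proportional to the enzyme level (``v = e * g(x, c)``), the property the
    regulation decomposition relies on.
    """

    internal_species: tuple[str, ...]
    external_species: tuple[str, ...]
    reactions: tuple[str, ...]
    N: np.ndarray
    reference: ReferenceState
    rate_laws: Sequence[Callable] | None = None
    params: Mapping | None = None
    irreversible: frozenset[str] = frozenset()
    name: str = "model"

    def __post_init__(self):
        self.internal_species = tuple(self.internal_species)
        self.external_species = tuple(self.external_species)
        self.reactions = tuple(self.reactions)
        self.N = np.asarray(self.N, dtype=float)
        if self.N.shape != (len(self.internal_species), len(self.reactions)):
            raise DimensionError(
                f"N has shape {self.N.shape}, expected "
                f"({len(self.internal_species)}, {len(self.reactions)})"
            )
        self.irreversible = frozenset(self.irreversible)
        unknown = self.irreversible - set(self.reactions)
        if unknown:
            raise ValueError(f"irreversible set names unknown reactions: {sorted(unknown)}")

    # index helpers -----------------------------------------------------------
    @property
    def n_internal(self) -> int:
        return len(self.internal_species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, species: str) -> int:
        return self.internal_species.index(species)

    def reaction_index(self, reaction: str) -> int:
        return self.reactions.index(reaction)

    @property
    def irreversible_mask(self) -> np.ndarray:
        return np.array([rx in self.irreversible for rx in self.reactions])

    # rates -------------------------------------------------------------------
    def rates(self, r: np.ndarray, x: np.ndarray, c: np.ndarray | None = None) -> np.ndarray:
        if self.rate_laws is None:
            raise NotImplementedError("model defines no rate laws")
        c = self.reference.c0 if c is None else np.asarray(c, dtype=float)
        return np.array(
            [law(r[i], x, c, self.params) for i, law in enumerate(self.rate_laws)]
        )

    def ode_rhs(self, r: np.ndarray, c: np.ndarray | None = None) -> Callable:
        """Right-hand side dx/dt = N v(r, x, c) with a positivity guard."""

        def rhs(t, x):
            xx = np.maximum(x, CONC_FLOOR)
            return self.N @ self.rates(r, xx, c)

        return rhs


@dataclass
class LinlogModel(KineticModel):
    """Kinetic model with linlog rate laws.

    v_i = r_i * J0_i * (1 + sum_j Ex[i,j] ln(x_j/x0_j)
                          + sum_k Ec[i,k] ln(c_k/c0_k))

    ``Ex`` and ``Ec`` are the (scaled) elasticity matrices towards internal
    and external metabolites.  Linlog models admit a closed-form steady state.
    """

    Ex: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    Ec: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self):
        super().__post_init__()
        self.Ex = np.asarray(self.Ex, dtype=float)
        self.Ec = np.asarray(self.Ec, dtype=float)
        if self.Ex.shape != (self.n_reactions, self.n_internal):
            raise DimensionError("Ex shape inconsistent with reactions x internal species")
        if self.Ec.shape != (self.n_reactions, len(self.external_species)):
            raise DimensionError("Ec shape inconsistent with reactions x external species")

    def rates(self, r, x, c=None):
        ref = self.reference
        x = np.asarray(x, dtype=float)
        c = ref.c0 if c is None else np.asarray(c, dtype=float)
        if np.any(x <= 0) or np.any(c <= 0):
            raise DomainError("linlog rates require strictly positive concentrations")
        lin = 1.0 + self.Ex @ np.log(x / ref.x0) + self.Ec @ np.log(c / ref.c0)
        return np.asarray(r, dtype=float) * ref.J0 * lin


@dataclass
class SteadyState:
    """Outcome of a steady-state solve: the physiological state of one sample."""

    x_ss: np.ndarray
    J_ss: np.ndarray
    converged: bool
    stable: bool
    residual: float
    reason: str = ""

    def __bool__(self) -> bool:  # truthy == usable state
        return bool(self.converged)


def _failed_state(model: KineticModel, reason: str) -> SteadyState:
    nan_x = np.full(model.n_internal, np.nan)
    nan_J = np.full(model.n_reactions, np.nan)
    return SteadyState(nan_x, nan_J, converged=False, stable=False,
                       residual=np.inf, reason=reason)


# -----------------------------------------------------------------------------
# operations
# -----------------------------------------------------------------------------

def evaluate_rates(model: KineticModel, r, x, c=None) -> np.ndarray:
    """Evaluate all reaction rates at enzyme levels ``r`` and state ``(x, c)``."""
    r = _as1d(r, model.n_reactions, "r")
    x = _as1d(x, model.n_internal, "x")
    if c is not None:
        c = _as1d(c, len(model.external_species), "c")
    if np.any(r < 0):
        raise DomainError("enzyme levels must be non-negative")
    if np.any(x <= 0):
        raise DomainError("metabolite concentrations must be strictly positive")
    return model.rates(r, x, c)


def linlog_steady_state(model: LinlogModel, r, c=None,
                        check_stability: bool = True) -> SteadyState:
    """Closed-form steady state of a linlog model.

    Solves ``N diag(r*J0) (k + Ex z) = 0`` for ``z = ln(x_ss/x0)`` where
    ``k = 1 + Ec ln(c/c0)`` folds any non-reference external state into the
    constant term.  A singular system (no unique steady state) is flagged on
    the returned state, never raised, so batch sampling is never aborted by
    a degenerate draw.
    """
    r = _as1d(r, model.n_reactions, "r")
    if np.any(r <= 0):
        return _failed_state(model, "nonpositive enzyme level")
    ref = model.reference
    c_arr = ref.c0 if c is None else _as1d(c, len(model.external_species), "c")
    k = 1.0 + model.Ec @ np.log(c_arr / ref.c0)
    w = r * ref.J0  # diag weights
    M = model.N @ (w[:, None] * model.Ex)
    b = -model.N @ (w * k)
    # guard against numerically singular systems
    if M.shape[0] != M.shape[1]:
        return _failed_state(model, "non-square steady-state system")
    try:
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > 1e12:
            return _failed_state(model, "no unique steady state (singular system)")
        z = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        return _failed_state(model, "no unique steady state (singular system)")
    x_ss = ref.x0 * np.exp(z)
    if not np.all(np.isfinite(x_ss)):
        return _failed_state(model, "steady state overflow")
    J_ss = model.rates(r, x_ss, c_arr)
    residual = float(np.max(np.abs(model.N @ J_ss)))
    stable = is_stable(system_jacobian(model, r, x_ss)) if check_stability else False
    return SteadyState(x_ss, J_ss, converged=True, stable=stable, residual=residual)


def integrate_to_steady_state(model: KineticModel, r, x_init=None, c=None,
                              tol: float = STEADY_STATE_TOL,
                              t_max: float = T_MAX,
                              check_stability: bool = True) -> SteadyState:
    """Integrate dx/dt = N v(r, x, c) until stationary.

    Convergence criterion: ``max_i |dx_i/dt| / max(x_i, floor) <= tol``.
    Divergence (blow-up, non-positive concentrations, or no convergence by
    ``t_max``) is reported through the ``converged`` flag and ``reason``,
    never as an exception.
    """
    r = _as1d(r, model.n_reactions, "r")
    if np.any(r < 0):
        return _failed_state(model, "negative enzyme level")
    ref = model.reference
    x = ref.x0.copy() if x_init is None else _as1d(x_init, model.n_internal, "x_init")
    if np.any(x <= 0):
        raise DomainError("x_init must be strictly positive")
    rhs = model.ode_rhs(r, c)

    def rel_rate(x):
        return float(np.max(np.abs(rhs(0.0, x)) / np.maximum(np.abs(x), CONC_FLOOR)))

    t, span = 0.0, 1.0
    while t < t_max:
        span = min(span, t_max - t)
        sol = solve_ivp(rhs, (t, t + span), x, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            return _failed_state(model, f"integrator failure: {sol.message}")
        x = sol.y[:, -1]
        t += span
        if np.any(~np.isfinite(x)) or np.max(np.abs(x)) > 1e12:
            return _failed_state(model, "trajectory diverged")
        if np.any(x <= 0):
            return _failed_state(model, "concentration reached non-positive value")
        if rel_rate(x) <= tol:
            x = _newton_polish(model, r, x, c)
            J_ss = model.rates(r, x, c)
            residual = float(np.max(np.abs(model.N @ J_ss)))
            stable = (is_stable(system_jacobian(model, r, x, c))
                      if check_stability else False)
            return SteadyState(x, J_ss, converged=True, stable=stable,
                               residual=residual)
        span *= 4.0  # geometric horizon growth: cheap early exit, bounded cost
    # horizon reached: slow modes may still be relaxing -- try a Newton
    # refinement from the endpoint; accept only a genuinely balanced root
    x_pol = _newton_polish(model, r, x, c)
    J_pol = model.rates(r, x_pol, c)
    residual = float(np.max(np.abs(model.N @ J_pol)))
    if residual <= 1e-9 * max(1.0, float(np.max(np.abs(J_pol)))):
        stable = (is_stable(system_jacobian(model, r, x_pol, c))
                  if check_stability else False)
        return SteadyState(x_pol, J_pol, converged=True, stable=stable,
                           residual=residual,
                           reason="newton refinement at integration horizon")
    st = _failed_state(model, "no steady state within t_max")
    st.x_ss, st.residual = x, rel_rate(x)
    return st


def _newton_polish(model: KineticModel, r, x, c=None,
                   max_iter: int = 25) -> np.ndarray:
    """Refine an integrated endpoint by damped Newton on N v(x) = 0.

    The rate-of-change stopping rule can trigger while slow modes (large
    metabolite pools with small drain rates) still carry a visible flux
    imbalance; a few Newton steps on the mass-balance root remove it.
    Falls back to the unpolished point if the iteration stalls or leaves
    the positive orthant.
    """
    best = x.copy()
    best_res = float(np.max(np.abs(model.N @ model.rates(r, np.maximum(x, CONC_FLOOR), c))))
    for _ in range(max_iter):
        xx = np.maximum(x, CONC_FLOOR)
        f = model.N @ model.rates(r, xx, c)
        res = float(np.max(np.abs(f)))
        if res < best_res:
            best, best_res = xx.copy(), res
        if res <= 1e-13 * max(1.0, float(np.max(np.abs(model.rates(r, xx, c))))):
            break
        try:
            A = system_jacobian(model, r, xx, c)
            step = np.linalg.solve(A, f)
        except (np.linalg.LinAlgError, DomainError):
            break
        x_new = xx - step
        damp = 1.0
        while np.any(x_new <= 0) and damp > 1e-6:
            damp *= 0.5
            x_new = xx - damp * step
        if np.any(x_new <= 0) or not np.all(np.isfinite(x_new)):
            break
        x = x_new
    return best


def system_jacobian(model: KineticModel, r, x, c=None) -> np.ndarray:
    """Jacobian A = N dv/dx of the mass-balance ODEs at state (r, x).

    Analytic for linlog models (dv_i/dx_j = r_i J0_i Ex[i,j] / x_j), central
    finite differences otherwise.
    """
    r = _as1d(r, model.n_reactions, "r")
    x = _as1d(x, model.n_internal, "x")
    if np.any(x <= 0):
        raise DomainError("Jacobian requires strictly positive concentrations")
    if isinstance(model, LinlogModel):
        dvdx = (r * model.reference.J0)[:, None] * model.Ex / x[None, :]
        return model.N @ dvdx
    dvdx = np.empty((model.n_reactions, model.n_internal))
    for j in range(model.n_internal):
        h = 1e-6 * x[j]
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        dvdx[:, j] = (model.rates(r, xp, c) - model.rates(r, xm, c)) / (2 * h)
    return model.N @ dvdx


def is_stable(A: np.ndarray, tol_eig: float = EIG_TOL) -> bool:
    """True iff every eigenvalue of ``A`` has real part < -tol_eig.

    Marginal cases (eigenvalues on or numerically near the imaginary axis)
    are conservatively labelled non-stable.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError("Jacobian must be square")
    return bool(np.all(np.linalg.eigvals(A).real < -tol_eig))


def check_reference_consistency(model: KineticModel, atol: float = 1e-9) -> None:
    """Assert v(1, x0, c0) == J0 and N @ J0 == 0; raise ValueError otherwise."""
    ref = model.reference
    v = model.rates(np.ones(model.n_reactions), ref.x0, ref.c0)
    if not np.allclose(v, ref.J0, atol=atol, rtol=1e-9):
        raise ValueError(f"rate laws do not reproduce J0 at reference: {v} != {ref.J0}")
    if not np.allclose(model.N @ ref.J0, 0.0, atol=atol):
        raise ValueError("reference fluxes are not a steady state (N @ J0 != 0)")


# -----------------------------------------------------------------------------
# internal structured-text model format (YAML)
# -----------------------------------------------------------------------------

def load_model(path) -> KineticModel:
    """Load a model from the internal YAML format.

    Layout::

        name: my-model
        internal_species: [M1, M2]
        external_species: [S, P]
        reactions: [R1, R2, R3]
        stoichiometry:          # rows = internal species
          M1: [1, -1, 0]
          M2: [0, 1, -1]
        kind: linlog
        Ex:                     # rows = reactions
          R1: [-0.5, 0.0]
          R2: [0.5, 0.0]
          R3: [0.0, 0.5]
        Ec:
          R1: [1.0, 0.0]
        irreversible: [R1, R2, R3]
        reference:
          x0: [1.0, 1.0]
          c0: [1.0, 1.0]
          J0: [1.0, 1.0, 1.0]

    Only ``kind: linlog`` is currently supported by the text format; other
    kinds are constructed programmatically.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = doc.get("kind", "linlog")
    if kind != "linlog":
        raise ValueError(f"unsupported rate-law kind in model file: {kind!r}")
    internal = list(doc["internal_species"])
    external = list(doc.get("external_species", []))
    reactions = list(doc["reactions"])
    N = np.array([doc["stoichiometry"][sp] for sp in internal], dtype=float)
    Ex = np.array([doc.get("Ex", {}).get(rx, [0.0] * len(internal))
                   for rx in reactions], dtype=float)
    Ec = np.array([doc.get("Ec", {}).get(rx, [0.0] * len(external))
                   for rx in reactions], dtype=float)
    ref = doc["reference"]
    reference = ReferenceState(
        x0=np.asarray(ref["x0"], dtype=float),
        c0=np.asarray(ref.get("c0", [1.0] * len(external)), dtype=float),
        J0=np.asarray(ref["J0"], dtype=float),
        e0=np.asarray(ref.get("e0", [1.0] * len(reactions)), dtype=float),
    )
    model = LinlogModel(
        internal_species=internal, external_species=external,
        reactions=reactions, N=N, reference=reference,
        irreversible=frozenset(doc.get("irreversible", [])),
        Ex=Ex, Ec=Ec, name=doc.get("name", "model"),
    )
    check_reference_consistency(model)
    return model


def dump_model(model: LinlogModel, path) -> None:
    """Write a linlog model to the internal YAML format."""
    doc = {
        "name": model.name,
        "kind": "linlog",
        "internal_species": list(model.internal_species),
        "external_species": list(model.external_species),
        "reactions": list(model.reactions),
        "stoichiometry": {sp: [float(v) for v in model.N[i]]
                          for i, sp in enumerate(model.internal_species)},
        "Ex": {rx: [float(v) for v in model.Ex[i]]
               for i, rx in enumerate(model.reactions)},
        "Ec": {rx: [float(v) for v in model.Ec[i]]
               for i, rx in enumerate(model.reactions)},
        "irreversible": sorted(model.irreversible),
        "reference": {
            "x0": [float(v) for v in model.reference.x0],
            "c0": [float(v) for v in model.reference.c0],
            "J0": [float(v) for v in model.reference.J0],
            "e0": [float(v) for v in model.reference.e0],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
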