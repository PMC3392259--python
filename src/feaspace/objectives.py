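"""Quantitative cellular objectives: function, robustness/homeostasis and
temporal responsiveness.

Feasibility analysis scores every viable physiological state against three
objectives:

* **Function** -- near-optimal flux through a target reaction under the
  enzyme budget: F = J_target / J_max, feasible when F >= 1 - theta_flux
  (e.g. theta_flux = 0.25 keeps the top quartile of fluxes).

* **Robustness and homeostasis** -- both are quantified by co-response
  coefficients from metabolic control analysis.  The control coefficient
  C^y_{e_i} = (e_i/y) dy/de_i is the scaled steady-state sensitivity of a
  system variable y (a flux or a concentration) to enzyme i; the co-response
  O^{a,b}_{e_i} = C^a_{e_i} / C^b_{e_i} measures how variables a and b
  co-move under a perturbation of enzyme i.  For a transition between two
  steady states the finite-change analogue is
  O_hat_j = ln(x_j/x0_j) / ln(J/J0).  Homeostasis (the *state* is kept) asks
  for a small aggregate |O_hat| over the metabolites of interest; robustness
  (the *function* is kept) asks for a large one -- the same number read
  against opposite criteria.

* **Temporal responsiveness** -- the turnover time
  tau_j = x_j / (total consumption flux of j) must be small for the network
  to respond quickly; feasible when tau_j <= theta_tau (e.g. 0.5).

Scores are computed per sample in "finite-change" mode (the transition from
the reference state to the sampled state, the default) or "local" mode
(derivative-based co-responses at the sampled state, worst case over the
perturbed enzymes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetic_core import (
    KineticModel,
    LinlogModel,
    ReferenceState,
    SteadyState,
    integrate_to_steady_state,
    linlog_steady_state,
)
from .sampling import SampleSet
from .constraints import ViabilityRecord, viable_mask

logger = logging.getLogger("feaspace")

#: denominators below this magnitude are treated as zero in co-responses
EPS_DIV = 1e-9
#: log-changes below this magnitude count as "unchanged"
EPS_NUM = 1e-6


@dataclass(frozen=True)
class ObjectiveConfig:
    """Cut-offs and evaluation mode for the objective scores.

    target_flux : reaction id whose flux is the "function" (default: the
        last reaction of the model, the pathway output).
    homeostasis_metabolites : metabolite subset entering the aggregate
        co-response (None = all internal metabolites).
    theta_flux : function cut-off; feasible when F >= 1 - theta_flux.
    theta_robust : robustness cut-off; feasible when R >= theta_robust.
    theta_homeo : homeostasis cut-off; feasible when H <= theta_homeo.
    theta_tau : turnover-time cut-off; feasible when every monitored
        metabolite has tau <= theta_tau.
    mode : "finite-change" (reference -> sample transition) or "local"
        (derivative co-responses at the sample).
    fd_step : relative finite-difference step for control coefficients.
    aggregate : "sum" (default) or "mean" of |co-response| over metabolites.
    """

    target_flux: str | None = None
    homeostasis_metabolites: tuple[str, ...] | None = None
    theta_flux: float = 0.25
    theta_robust: float = 2.0
    theta_homeo: float = 0.5
    theta_tau: float = 0.5
    mode: str = "finite-change"
    fd_step: float = 1e-4
    aggregate: str = "sum"

    def __post_init__(self):
        for name in ("theta_flux", "theta_robust", "theta_homeo", "theta_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("finite-change", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.aggregate not in ("sum", "mean"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")


@dataclass
class ControlCoefficientSet:
    """Scaled control coefficients at one steady state.

    ``C_J`` is (reactions x enzymes), ``C_x`` is (metabolites x enzymes).
    At a stable steady state of an enzyme-proportional model the summation
    theorems hold: every row of C_J sums to 1, every row of C_x to 0.
    Columns for enzymes whose perturbed steady state could not be re-solved
    are NaN.
    """

    C_J: np.ndarray
    C_x: np.ndarray
    model: KineticModel
    evaluated_at: int | str = "reference"

    def feature_row(self, feature) -> np.ndarray:
        """Look up a coefficient row; feature is ("J", rxn) or ("x", met),
        or a string "J:rxn" / "x:met"."""
        if isinstance(feature, str):
            kind, _, name = feature.partition(":")
        else:
            kind, name = feature
        if kind == "J":
            return self.C_J[self.model.reaction_index(name)]
        if kind == "x":
            return self.C_x[self.model.species_index(name)]
        raise ValueError(f"unknown feature kind {kind!r} (use 'J' or 'x')")


def _resolve(model: KineticModel, r: np.ndarray) -> SteadyState:
    if isinstance(model, LinlogModel):
        return linlog_steady_state(model, r, check_stability=False)
    return integrate_to_steady_state(model, r, check_stability=False)


def control_coefficients(model: KineticModel, r, fd_step: float = 1e-4,
                         method: str = "auto") -> ControlCoefficientSet:
    """Scaled flux and concentration control coefficients at steady state.

    For linlog models the coefficients follow in closed form from implicit
    differentiation of the steady-state system: with M = N diag(r*J0) Ex,

        C_x = -M^{-1} N diag(J_ss)          (d ln x / d ln e)
        C_J = I + diag(r*J0/J_ss) Ex C_x    (d ln J / d ln e)

    under which the summation theorems (rows of C_J sum to 1, rows of C_x
    to 0) hold to machine precision since N @ J_ss = 0.  For generic models
    each enzyme is perturbed multiplicatively by exp(+/-fd_step), the steady
    state re-solved, and central differences taken; enzymes whose perturbed
    systems fail to re-solve get NaN columns.  ``method`` is "auto",
    "analytic" or "fd".
    """
    r = np.asarray(r, dtype=float)
    base = _resolve(model, r)
    if not base.converged:
        raise ValueError("control coefficients require a solvable steady state")
    if method == "auto":
        method = "analytic" if isinstance(model, LinlogModel) else "fd"
    if method == "analytic":
        if not isinstance(model, LinlogModel):
            raise ValueError("analytic control coefficients require a linlog model")
        w = r * model.reference.J0
        M = model.N @ (w[:, None] * model.Ex)
        C_x = -np.linalg.solve(M, model.N * base.J_ss[None, :])
        C_J = np.eye(model.n_reactions) + (w / base.J_ss)[:, None] * (model.Ex @ C_x)
        return ControlCoefficientSet(C_J=C_J, C_x=C_x, model=model)
    h = fd_step
    n_rxn, n_met = model.n_reactions, model.n_internal
    C_J = np.full((n_rxn, n_rxn), np.nan)
    C_x = np.full((n_met, n_rxn), np.nan)
    for i in range(n_rxn):
        rp, rm = r.copy(), r.copy()
        rp[i] *= np.exp(h)
        rm[i] *= np.exp(-h)
        sp, sm = _resolve(model, rp), _resolve(model, rm)
        if not (sp.converged and sm.converged):
            continue  # flagged undefined for this enzyme
        # relative central difference == d ln y / d ln e_i to O(h^2),
        # without requiring positive fluxes
        C_J[:, i] = (sp.J_ss - sm.J_ss) / (2 * h * base.J_ss)
        C_x[:, i] = (sp.x_ss - sm.x_ss) / (2 * h * base.x_ss)
    return ControlCoefficientSet(C_J=C_J, C_x=C_x, model=model)


def co_response(C: ControlCoefficientSet, a, b, enzyme: str | int) -> float:
    """Co-response coefficient O^{a,b}_{e_i} = C^a_{e_i} / C^b_{e_i}.

    A vanishing denominator with a non-vanishing numerator returns a signed
    infinity marker; 0/0 returns NaN (undefined).
    """
    i = (C.model.reaction_index(enzyme) if isinstance(enzyme, str) else enzyme)
    ca = C.feature_row(a)[i]
    cb = C.feature_row(b)[i]
    if np.isnan(ca) or np.isnan(cb):
        return np.nan
    if abs(cb) < EPS_DIV:
        if abs(ca) < EPS_DIV:
            return np.nan
        return np.sign(ca) * np.inf
    return float(ca / cb)


def finite_change_coresponse(reference: ReferenceState | SteadyState,
                             state: SteadyState,
                             model: KineticModel,
                             target_flux: str | int | None = None) -> np.ndarray:
    """Per-metabolite finite-change co-response for a reference -> state
    transition: O_hat_j = ln(x_j/x0_j) / ln(J/J0) for the target flux.

    Conventions for degenerate transitions: if the flux is unchanged
    (|ln(J/J0)| < EPS_DIV) but metabolites moved, every entry is a signed
    infinity marker (perfect robustness, no homeostasis); if neither moved,
    the transition trivially maintains the state and all entries are 0.
    """
    if isinstance(reference, SteadyState):
        if not reference.converged:
            raise ValueError("reference state did not converge")
        x0, J0 = reference.x_ss, reference.J_ss
    else:
        x0, J0 = reference.x0, reference.J0
    if not state.converged:
        raise ValueError("cannot score a non-converged state")
    if target_flux is None:
        t = model.n_reactions - 1
    elif isinstance(target_flux, str):
        t = model.reaction_index(target_flux)
    else:
        t = target_flux
    if state.J_ss[t] <= 0 or J0[t] <= 0:
        raise ValueError("finite-change co-response requires positive target flux")
    dlnx = np.log(state.x_ss / x0)
    dlnJ = float(np.log(state.J_ss[t] / J0[t]))
    if abs(dlnJ) < EPS_DIV:
        if np.all(np.abs(dlnx) < EPS_NUM):
            return np.zeros_like(dlnx)  # identity transition
        out = np.zeros_like(dlnx)
        moved = np.abs(dlnx) >= EPS_NUM
        out[moved] = np.sign(dlnx[moved]) * np.inf
        return out
    return dlnx / dlnJ


def _subset_idx(model: KineticModel, subset) -> np.ndarray:
    if subset is None:
        return np.arange(model.n_internal)
    idx = np.array([model.species_index(sp) for sp in subset])
    if idx.size == 0:
        raise ValueError("metabolite subset must be non-empty")
    return idx


def homeostasis_score(O_hat: np.ndarray, subset_idx=None,
                      theta_homeo: float = 0.5,
                      aggregate: str = "sum") -> tuple[float, bool]:
    """Aggregate |co-response| over the metabolite subset; small = state kept.

    Returns (H, feasible) with H the sum (or mean) of |O_hat_j|; divergent
    markers propagate to H = +inf (not homeostatic).
    """
    O = np.asarray(O_hat, dtype=float)
    vals = O if subset_idx is None else O[subset_idx]
    if vals.size == 0:
        raise ValueError("metabolite subset must be non-empty")
    H = float(np.sum(np.abs(vals)))
    if aggregate == "mean":
        H /= vals.size
    return H, bool(H <= theta_homeo)


def robustness_score(O_hat: np.ndarray, subset_idx=None,
                     theta_robust: float = 2.0,
                     aggregate: str = "sum") -> tuple[float, bool]:
    """Same aggregate as :func:`homeostasis_score`, read the other way:
    large co-response = flux buffered by metabolite adjustment = robust.
    A divergent marker (function unchanged while metabolites moved) gives
    R = +inf, robust-feasible."""
    R, _ = homeostasis_score(O_hat, subset_idx, np.inf, aggregate)
    return R, bool(R >= theta_robust)


def function_score(J_target: float, J_max: float,
                   theta_flux: float = 0.25) -> tuple[float, bool]:
    """F = J_target / J_max; feasible when within theta_flux of the optimum.

    J_max <= 0 leaves the score undefined (NaN, infeasible)."""
    if J_max <= 0:
        return np.nan, False
    F = float(J_target / J_max)
    return F, bool(F >= 1.0 - theta_flux)


def turnover_time(state: SteadyState, model: KineticModel,
                  metabolite: str | int | None = None):
    """Turnover time tau_j = x_j / total consumption flux of j.

    Consumption sums every flux that drains metabolite j at the steady
    state, max(-N[j,i]*J_i, 0) over reactions.  Zero consumption leaves tau
    infinite (the pool cannot be flushed, hence not responsive).
    Returns the full vector, or a scalar when a metabolite is named.
    """
    if not state.converged:
        raise ValueError("turnover time requires a converged state")
    consumption = np.maximum(-model.N * state.J_ss[None, :], 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        tau = np.where(consumption > 0, state.x_ss / np.maximum(consumption, 1e-300),
                       np.inf)
    if metabolite is None:
        return tau
    j = (model.species_index(metabolite) if isinstance(metabolite, str)
         else metabolite)
    return float(tau[j])


# -----------------------------------------------------------------------------
# batch scoring
# -----------------------------------------------------------------------------

def score_objectives(samples: SampleSet,
                     records: Sequence[ViabilityRecord],
                     config: ObjectiveConfig | None = None) -> pd.DataFrame:
    """Score every viable sample on all three objectives.

    Returns one row per sample: F, R, H, per-metabolite turnover times,
    signed per-metabolite co-responses (for scenario plots), the four
    feasibility labels and their conjunction.  Non-viable samples carry NaN
    scores and all-false labels.
    """
    config = config or ObjectiveConfig()
    model = samples.model
    t_idx = (model.n_reactions - 1 if config.target_flux is None
             else model.reaction_index(config.target_flux))
    sub_idx = _subset_idx(model, config.homeostasis_metabolites)
    viable = viable_mask(list(records))
    X, J, conv, _ = samples.state_arrays()

    J_target = J[:, t_idx]
    vt = J_target[viable]
    J_max = float(np.max(vt)) if vt.size and np.max(vt) > 0 else np.nan

    n = len(samples)
    F = np.full(n, np.nan)
    H = np.full(n, np.nan)
    R = np.full(n, np.nan)
    O_all = np.full((n, model.n_internal), np.nan)
    tau_all = np.full((n, model.n_internal), np.nan)
    feas_f = np.zeros(n, bool)
    feas_r = np.zeros(n, bool)
    feas_h = np.zeros(n, bool)
    feas_t = np.zeros(n, bool)

    for k in range(n):
        if not viable[k]:
            continue
        state = samples.states[k]
        if np.isfinite(J_max):
            F[k], feas_f[k] = function_score(J_target[k], J_max, config.theta_flux)
        if config.mode == "finite-change":
            O = finite_change_coresponse(model.reference, state, model, t_idx)
        else:
            O = _local_worst_case_coresponse(model, samples.R[k], t_idx,
                                             config.fd_step)
        O_all[k] = O
        H[k], feas_h[k] = homeostasis_score(O, sub_idx, config.theta_homeo,
                                            config.aggregate)
        R[k], feas_r[k] = robustness_score(O, sub_idx, config.theta_robust,
                                           config.aggregate)
        tau = turnover_time(state, model)
        tau_all[k] = tau
        feas_t[k] = bool(np.all(tau[sub_idx] <= config.theta_tau))

    out = {"id": samples.ids, "viable": viable, "F": F, "R": R, "H": H}
    for j, sp in enumerate(model.internal_species):
        out[f"tau_{sp}"] = tau_all[:, j]
    for j, sp in enumerate(model.internal_species):
        out[f"O_{sp}"] = O_all[:, j]
    out["feasible_function"] = feas_f
    out["feasible_robust"] = feas_r
    out["feasible_homeo"] = feas_h
    out["feasible_responsive"] = feas_t
    return pd.DataFrame(out)


def _local_worst_case_coresponse(model, r, t_idx, fd_step):
    """Local-mode score: derivative co-responses at the sampled state, taking
    for each metabolite the largest |O| over the perturbed enzymes."""
    C = control_coefficients(model, r, fd_step)
    O = np.full(model.n_internal, np.nan)
    for j in range(model.n_internal):
        vals = []
        for i in range(model.n_reactions):
            cx, cj = C.C_x[j, i], C.C_J[t_idx, i]
            if np.isnan(cx) or np.isnan(cj):
                continue
            if abs(cj) < EPS_DIV:
                vals.append(np.inf if abs(cx) >= EPS_DIV else 0.0)
            else:
                vals.append(cx / cj)
        if vals:
            O[j] = max(vals, key=abs)
    return O


def classify_and_combine(scores: pd.DataFrame,
                         config: ObjectiveConfig | None = None) -> pd.DataFrame:
    """Add the all-objective conjunction label and log label-combination counts.

    The conjunction requires function, homeostasis and responsiveness
    simultaneously (the joint-feasibility coloring of the combined-objective
    analysis); robustness is reported alongside as its criterion direction
    opposes homeostasis.
    """
    out = scores.copy()
    out["feasible_all"] = (out["feasible_function"]
                           & out["feasible_homeo"]
                           & out["feasible_responsive"])
    combo = (out["feasible_function"].astype(int).astype(str)
             + out["feasible_homeo"].astype(int).astype(str)
             + out["feasible_responsive"].astype(int).astype(str))
    counts = combo[out["viable"]].value_counts().to_dict()
    logger.info("objective label combinations (func/homeo/resp): %s", counts)
    return out
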