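"""Hard constraints carving the viable space out of the sampled space.

Four explicit checks are applied to every mapped sample: thermodynamic
consistency (non-negative flux through irreversible reactions, positive
metabolite levels, and optionally flux running down the Gibbs-energy
gradient), a total-enzyme budget (the summed, cost-weighted enzyme level may
deviate from the reference total by at most a fraction delta, while
individual enzymes interconvert freely), optional per-reaction capacity caps,
and local stability of the steady state.

Two constraints are enforced implicitly by the architecture rather than
re-checked: kinetic consistency, because physiological states are only ever
produced through the model's rate laws; and mass balance, because the
steady-state solvers only mark a state converged when the balance residual
is below tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetic_core import KineticModel, SteadyState
from .sampling import SampleSet

logger = logging.getLogger("feaspace")

#: numerical slack on strict sign checks of analytic/integrated fluxes
_SIGN_TOL = 1e-12


@dataclass(frozen=True)
class ConstraintConfig:
    """Configuration of the hard constraints.

    delta_total_enzyme : budget tolerance delta; the cost-weighted mean
        relative enzyme level must stay within [1-delta, 1+delta].  Default
        0.5 (a +/-50% budget, the small-pathway scenario); 0.1 is the
        conventional tight setting for generic runs.  ``inf`` disables.
    enzyme_weights : per-enzyme cost weights (reaction id -> weight > 0);
        default all 1.
    v_max : optional per-reaction flux caps (reaction id -> cap).
    dG : optional per-reaction Gibbs free energies; when given for a
        reaction, flux must satisfy sign(J)*dG <= 0.
    check_stability : require all Jacobian eigenvalues in the left half-plane.
    """

    delta_total_enzyme: float = 0.5
    enzyme_weights: Mapping[str, float] | None = None
    v_max: Mapping[str, float] | None = None
    dG: Mapping[str, float] | None = None
    check_stability: bool = True

    def __post_init__(self):
        if self.delta_total_enzyme < 0:
            raise ValueError("delta_total_enzyme must be >= 0")
        if self.enzyme_weights and any(w <= 0 for w in self.enzyme_weights.values()):
            raise ValueError("enzyme weights must be positive")

    def weights_vector(self, model: KineticModel) -> np.ndarray:
        if self.enzyme_weights is None:
            return np.ones(model.n_reactions)
        unknown = set(self.enzyme_weights) - set(model.reactions)
        if unknown:
            raise ValueError(f"weights name unknown reactions: {sorted(unknown)}")
        return np.array([self.enzyme_weights.get(rx, 1.0) for rx in model.reactions])


@dataclass
class ViabilityRecord:
    """Per-sample constraint outcome; ``viable`` is the conjunction of all
    enabled checks."""

    sample_id: int
    pass_converged: bool
    pass_thermo: bool
    pass_total_enzyme: bool
    pass_capacity: bool
    pass_stability: bool

    @property
    def viable(self) -> bool:
        return (self.pass_converged and self.pass_thermo
                and self.pass_total_enzyme and self.pass_capacity
                and self.pass_stability)


def check_thermodynamic(state: SteadyState, model: KineticModel,
                        config: ConstraintConfig | None = None) -> bool:
    """Thermodynamic viability of one steady state.

    Requires a converged state with strictly positive metabolite levels and
    non-negative flux through every irreversible reaction; when Gibbs free
    energies are supplied, each reaction's flux must additionally run down
    its thermodynamic gradient (sign(J)*dG <= 0).
    """
    if not state.converged:
        return False  # "not a steady state"
    if np.any(state.x_ss <= 0):
        return False
    mask = model.irreversible_mask
    if np.any(state.J_ss[mask] < -_SIGN_TOL):
        return False
    if config is not None and config.dG:
        for rx, dg in config.dG.items():
            J = state.J_ss[model.reaction_index(rx)]
            if np.sign(J) * dg > _SIGN_TOL:
                return False
    return True


def check_total_enzyme(r: np.ndarray, config: ConstraintConfig,
                       model: KineticModel | None = None) -> bool:
    """Total-enzyme budget: |sum(w*r)/sum(w) - 1| <= delta.

    The reference total is sum(w*1) since enzyme levels are relative, so the
    check compares the cost-weighted mean level against 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("enzyme levels must be non-negative")
    if not np.isfinite(config.delta_total_enzyme):
        return True
    w = (config.weights_vector(model) if model is not None
         else np.ones_like(r))
    rel_total = float(w @ r) / float(w.sum())
    return abs(rel_total - 1.0) <= config.delta_total_enzyme


def apply_all_constraints(samples: SampleSet,
                          config: ConstraintConfig | None = None
                          ) -> list[ViabilityRecord]:
    """Evaluate every enabled hard constraint on a mapped sample set."""
    if not samples.mapped:
        raise ValueError("sample set must be mapped before applying constraints")
    config = config or ConstraintConfig()
    model = samples.model
    vmax = None
    if config.v_max is not None:
        unknown = set(config.v_max) - set(model.reactions)
        if unknown:
            raise ValueError(f"v_max names unknown reactions: {sorted(unknown)}")
        vmax = np.array([config.v_max.get(rx, np.inf) for rx in model.reactions])
    records = []
    for sid, r, state in zip(samples.ids, samples.R, samples.states):
        conv = bool(state.converged)
        thermo = check_thermodynamic(state, model, config)
        budget = check_total_enzyme(r, config, model)
        if vmax is None:
            capacity = True
        else:
            capacity = conv and bool(np.all(state.J_ss <= vmax + _SIGN_TOL))
        stability = bool(state.stable) if config.check_stability else True
        records.append(ViabilityRecord(
            sample_id=int(sid), pass_converged=conv, pass_thermo=thermo,
            pass_total_enzyme=budget, pass_capacity=capacity,
            pass_stability=stability))
    n_viable = sum(rec.viable for rec in records)
    logger.info(
        "constraints: %d/%d viable (converged %d, thermo %d, budget %d, "
        "capacity %d, stability %d)",
        n_viable, len(records),
        sum(r.pass_converged for r in records),
        sum(r.pass_thermo for r in records),
        sum(r.pass_total_enzyme for r in records),
        sum(r.pass_capacity for r in records),
        sum(r.pass_stability for r in records))
    return records


def viability_table(records: list[ViabilityRecord]) -> pd.DataFrame:
    """Serialize viability records to the canonical table."""
    return pd.DataFrame({
        "id": [r.sample_id for r in records],
        "pass_converged": [r.pass_converged for r in records],
        "pass_thermo": [r.pass_thermo for r in records],
        "pass_total_enzyme": [r.pass_total_enzyme for r in records],
        "pass_capacity": [r.pass_capacity for r in records],
        "pass_stability": [r.pass_stability for r in records],
        "viable": [r.viable for r in records],
    })


def viable_mask(records: list[ViabilityRecord]) -> np.ndarray:
    return np.array([r.viable for r in records])
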