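"""Hierarchical vs metabolic regulation analysis of flux changes.

For a transition between two steady states, the log-change of each
reaction's flux factors into an enzyme part and a metabolic part because
rates are proportional to enzyme level, v = e * g(x, c):

    ln(J/J0) = ln(e/e0) + ln(g(x)/g(x0))
    dln_v    = dln_e    + dln_g

Dividing by dln_v defines the hierarchical and metabolic regulation
coefficients,

    rho_h = dln_e / dln_v      (change explained by enzyme level)
    rho_m = dln_g / dln_v      (change explained by metabolite action)

which sum to 1 by construction whenever the flux actually changed.
rho_h ~ 1 marks exclusively hierarchical regulation (the enzyme moved, the
metabolites compensated nothing), rho_m ~ 1 exclusively metabolic
regulation (the enzyme stayed put, the metabolites did the work).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_core import KineticModel, ReferenceState, SteadyState

#: flux log-changes below this magnitude leave the decomposition undefined
EPS_DIV = 1e-9

#: default half-width of the rho_h band for "exclusive" classification
DEFAULT_BAND = 0.05


@dataclass
class RegulationRecord:
    """Per-reaction regulation decomposition for one transition.

    Arrays are indexed by reaction: log-changes (dln_v, dln_e, dln_g),
    coefficients (rho_h, rho_m; NaN where undefined) and a per-reaction
    ``defined`` mask.  ``flux_reversal`` marks reactions whose flux changed
    sign, where the log-decomposition does not exist.
    """

    sample_id: int
    reactions: tuple[str, ...]
    dln_v: np.ndarray
    dln_e: np.ndarray
    dln_g: np.ndarray
    rho_h: np.ndarray
    rho_m: np.ndarray
    defined: np.ndarray
    flux_reversal: np.ndarray


def regulation_coefficients(model: KineticModel,
                            reference: ReferenceState | SteadyState,
                            state: SteadyState,
                            r: np.ndarray,
                            sample_id: int = -1) -> RegulationRecord:
    """Decompose the reference -> state flux change of every reaction.

    Requires both states converged and rate laws proportional to enzyme
    level (true for linlog and every shipped model), so that
    dln_g = dln_v - dln_e without evaluating g explicitly.  Reactions with
    |dln_v| <= EPS_DIV or with a flux sign reversal are flagged undefined.
    """
    if isinstance(reference, SteadyState):
        if not reference.converged:
            raise ValueError("reference state did not converge")
        J0 = reference.J_ss
    else:
        J0 = reference.J0
    if not state.converged:
        raise ValueError("cannot decompose a non-converged state")
    r = np.asarray(r, dtype=float)
    J = state.J_ss
    reversal = (np.sign(J) * np.sign(J0) < 0) | (J0 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dln_v = np.where(reversal, np.nan, np.log(np.abs(J) / np.abs(J0)))
        dln_e = np.log(r)
    dln_g = dln_v - dln_e
    defined = (~reversal) & (np.abs(dln_v) > EPS_DIV) & np.isfinite(dln_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_h = np.where(defined, dln_e / np.where(defined, dln_v, 1.0), np.nan)
        rho_m = np.where(defined, dln_g / np.where(defined, dln_v, 1.0), np.nan)
    return RegulationRecord(
        sample_id=int(sample_id), reactions=model.reactions,
        dln_v=dln_v, dln_e=dln_e, dln_g=dln_g,
        rho_h=rho_h, rho_m=rho_m, defined=defined,
        flux_reversal=reversal)


def classify_regulation(rho_h: float, band: float = DEFAULT_BAND) -> str:
    """Label one reaction's regulation mode from its rho_h.

    "hierarchical" when rho_h is within ``band`` of 1, "metabolic" when
    within ``band`` of 0, otherwise "mixed"; NaN (no flux change to
    decompose) gives "undefined".
    """
    if rho_h is None or (isinstance(rho_h, float) and np.isnan(rho_h)):
        return "undefined"
    if abs(rho_h - 1.0) <= band:
        return "hierarchical"
    if abs(rho_h) <= band:
        return "metabolic"
    return "mixed"


def regulation_table(records: list[RegulationRecord],
                     band: float = DEFAULT_BAND) -> pd.DataFrame:
    """Serialize records to the canonical long table:
    one row per (sample, reaction) with rho_h, rho_m and the class label."""
    rows = []
    for rec in records:
        for i, rx in enumerate(rec.reactions):
            rho = float(rec.rho_h[i])
            rows.append({
                "id": rec.sample_id,
                "reaction": rx,
                "dln_v": float(rec.dln_v[i]),
                "dln_e": float(rec.dln_e[i]),
                "dln_g": float(rec.dln_g[i]),
                "rho_h": rho,
                "rho_m": float(rec.rho_m[i]),
                "classification": ("flux-reversal" if rec.flux_reversal[i]
                                   else classify_regulation(rho, band)),
            })
    return pd.DataFrame(rows)
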