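"""Per-reaction consistency checks run before any simulation.

Three checks in the tradition of curation tooling for genome-scale models:

* formula balance — per-element residual of Σ coefficient × element count;
* charge balance — residual of Σ coefficient × charge;
* stoichiometric (mass) consistency — does a strictly positive molecular
  mass assignment ``m`` exist with ``Sᵀm = 0`` over internal reactions?

Exchange reactions and the biomass pseudo-reaction are unbalanced by
construction and reported as exempt; a reaction touching a compound whose
formula (or charge) is unknown is skipped, never called balanced or
unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Reaction

__all__ = [
    "BalanceReport",
    "check_formula_balance",
    "check_charge_balance",
    "check_mass_consistency",
    "check_model",
]

#: Residuals below this magnitude count as zero.
BALANCE_TOL = 1e-9

STATUS_BALANCED = "balanced"
STATUS_UNBALANCED = "unbalanced"
STATUS_SKIPPED = "skipped_unknown"
STATUS_EXEMPT = "exempt_exchange"


@dataclass
class BalanceReport:
    reaction_id: str
    check: str  # formula | charge | mass
    status: str
    detail: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status in (STATUS_BALANCED, STATUS_EXEMPT, STATUS_SKIPPED)


def _is_exempt(reaction: Reaction, model: MetabolicModel) -> bool:
    return reaction.is_exchange or reaction.id == model.biomass_reaction_id


def check_formula_balance(reaction: Reaction, model: MetabolicModel) -> BalanceReport:
    """Element-wise balance of one reaction."""
    if reaction.id not in model.reactions:
        raise ValueError(f"reaction {reaction.id!r} does not belong to the model")
    if _is_exempt(reaction, model):
        return BalanceReport(reaction.id, "formula", STATUS_EXEMPT)
    residuals: Dict[str, float] = {}
    for cid, coef in reaction.stoichiometry.items():
        formula = model.compounds[cid].formula
        if formula is None:
            return BalanceReport(reaction.id, "formula", STATUS_SKIPPED, {cid: float("nan")})
        for element, count in formula.items():
            residuals[element] = residuals.get(element, 0.0) + coef * count
    residuals = {el: r for el, r in residuals.items() if abs(r) > BALANCE_TOL}
    status = STATUS_BALANCED if not residuals else STATUS_UNBALANCED
    return BalanceReport(reaction.id, "formula", status, residuals)


def check_charge_balance(reaction: Reaction, model: MetabolicModel) -> BalanceReport:
    """Net-charge balance of one reaction."""
    if reaction.id not in model.reactions:
        raise ValueError(f"reaction {reaction.id!r} does not belong to the model")
    if _is_exempt(reaction, model):
        return BalanceReport(reaction.id, "charge", STATUS_EXEMPT)
    residual = 0.0
    for cid, coef in reaction.stoichiometry.items():
        charge = model.compounds[cid].charge
        if charge is None:
            return BalanceReport(reaction.id, "charge", STATUS_SKIPPED, {cid: float("nan")})
        residual += coef * charge
    if abs(residual) <= BALANCE_TOL:
        return BalanceReport(reaction.id, "charge", STATUS_BALANCED, {"charge": 0.0})
    return BalanceReport(reaction.id, "charge", STATUS_UNBALANCED, {"charge": residual})


def check_mass_consistency(model: MetabolicModel, tol: float = 1e-6) -> List[BalanceReport]:
    """Stoichiometric consistency over the internal network.

    Seeks a mass vector ``m >= 1`` (one positive mass per compound) with
    ``Sᵀm = 0`` over non-exchange, non-biomass reactions. When no such vector
    exists the elastic version (minimise the L1 residual of ``Sᵀm``) is
    solved and reactions with a nonzero residual are flagged unbalanced.
    """
    internal = [r for r in model.reactions.values() if not _is_exempt(r, model)]
    compound_ids = sorted(model.compounds)
    if not internal or not compound_ids:
        return [BalanceReport(r.id, "mass", STATUS_EXEMPT) for r in model.reactions.values() if _is_exempt(r, model)]
    cindex = {cid: i for i, cid in enumerate(compound_ids)}
    n_c, n_r = len(compound_ids), len(internal)
    st = np.zeros((n_r, n_c))  # rows = reactions: Sᵀ
    for j, r in enumerate(internal):
        for cid, coef in r.stoichiometry.items():
            st[j, cindex[cid]] = coef

    # Elastic LP: minimise Σ(p+q) s.t. Sᵀm + p - q = 0, m >= 1, p,q >= 0.
    n = n_c + 2 * n_r
    c = np.concatenate([np.zeros(n_c), np.ones(2 * n_r)])
    a_eq = np.hstack([st, np.eye(n_r), -np.eye(n_r)])
    bounds = [(1.0, None)] * n_c + [(0.0, None)] * (2 * n_r)
    res = linprog(c, A_eq=a_eq, b_eq=np.zeros(n_r), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"mass-consistency LP failed: {res.message}")
    residual = st @ res.x[:n_c]

    reports: List[BalanceReport] = []
    for r in model.reactions.values():
        if _is_exempt(r, model):
            reports.append(BalanceReport(r.id, "mass", STATUS_EXEMPT))
    for j, r in enumerate(internal):
        if abs(residual[j]) <= tol:
            reports.append(BalanceReport(r.id, "mass", STATUS_BALANCED, {"residual": 0.0}))
        else:
            reports.append(
                BalanceReport(r.id, "mass", STATUS_UNBALANCED, {"residual": float(residual[j])})
            )
    return reports


def check_model(
    model: MetabolicModel,
    formula: bool = True,
    charge: bool = True,
    mass: bool = True,
) -> List[BalanceReport]:
    """Run the selected checks over every reaction of the model."""
    reports: List[BalanceReport] = []
    if formula:
        reports += [check_formula_balance(r, model) for r in model.reactions.values()]
    if charge:
        reports += [check_charge_balance(r, model) for r in model.reactions.values()]
    if mass:
        reports += check_mass_consistency(model)
    return reports
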