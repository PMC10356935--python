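"""Linear-programming core: FBA, FVA and gene/complex deletions.

Flux balance analysis maximises one reaction's flux subject to steady-state
mass balance ``S·v = 0`` and the flux bounds; flux variability analysis
reports each reaction's attainable range while the objective is held at a
fraction of its optimum. Both run on the deterministic HiGHS simplex via
:func:`scipy.optimize.linprog` — only the objective value and FVA ranges are
contractual, individual fluxes of degenerate optima are solver-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .gpr import evaluate_gpr
from .medium import MediumCondition, apply_medium
from .model import MetabolicModel, ModelValidationError

__all__ = [
    "FBAResult",
    "FVAResult",
    "DeletionResult",
    "solve_fba",
    "run_fva",
    "delete_genes",
    "delete_complexes",
]

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

#: Reporting tolerance for fluxes and blocked-range decisions.
FLUX_TOL = 1e-6


@dataclass
class FBAResult:
    status: str
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL


@dataclass
class FVAResult:
    fraction_of_optimum: float
    objective_value: float
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def is_blocked(self, reaction_id: str, tol: float = FLUX_TOL) -> bool:
        lo, hi = self.ranges[reaction_id]
        return abs(lo) <= tol and abs(hi) <= tol


@dataclass
class DeletionResult:
    deleted_genes: Set[str]
    disabled_reactions: Set[str]
    biomass_wt: float
    biomass_deleted: float
    atp_synthase_wt: Optional[float] = None
    atp_synthase_deleted: Optional[float] = None
    blocked_exchanges: Set[str] = field(default_factory=set)

    @property
    def biomass_relative(self) -> float:
        return self.biomass_deleted / self.biomass_wt

    @property
    def atp_synthase_max_relative(self) -> Optional[float]:
        if self.atp_synthase_wt is None or self.atp_synthase_deleted is None:
            return None
        return self.atp_synthase_deleted / self.atp_synthase_wt


class _LP:
    """Standard-form steady-state LP over a constrained model."""

    def __init__(self, model: MetabolicModel):
        self.reaction_ids = sorted(model.reactions)
        self.compound_ids = sorted(model.compounds)
        rindex = {rid: j for j, rid in enumerate(self.reaction_ids)}
        cindex = {cid: i for i, cid in enumerate(self.compound_ids)}
        s = lil_matrix((len(self.compound_ids), len(self.reaction_ids)))
        bounds = []
        for rid in self.reaction_ids:
            r = model.reactions[rid]
            bounds.append((r.lower_bound, r.upper_bound))
            for cid, coef in r.stoichiometry.items():
                s[cindex[cid], rindex[rid]] = coef
        self.s = s.tocsr()
        self.bounds = bounds
        self.rindex = rindex

    def optimize(self, objective_id: str, maximize: bool = True) -> FBAResult:
        c = np.zeros(len(self.reaction_ids))
        c[self.rindex[objective_id]] = -1.0 if maximize else 1.0
        res = linprog(
            c,
            A_eq=self.s,
            b_eq=np.zeros(self.s.shape[0]),
            bounds=self.bounds,
            method="highs",
        )
        if res.status == 2:
            return FBAResult(STATUS_INFEASIBLE)
        if res.status == 3:
            return FBAResult(STATUS_UNBOUNDED)
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        fluxes = dict(zip(self.reaction_ids, (float(x) for x in res.x)))
        return FBAResult(STATUS_OPTIMAL, fluxes[objective_id], fluxes)

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> None:
        self.bounds[self.rindex[reaction_id]] = (lower, upper)


def _resolve_objective(model: MetabolicModel, objective: Optional[str]) -> str:
    obj = objective or model.biomass_reaction_id
    if obj is None:
        raise ModelValidationError("no objective reaction given and no biomass designated")
    if obj not in model.reactions:
        raise ModelValidationError(f"objective reaction {obj!r} not in model")
    return obj


def solve_fba(
    model: MetabolicModel,
    medium: Optional[MediumCondition] = None,
    objective: Optional[str] = None,
    maximize: bool = True,
) -> FBAResult:
    """Maximise (or minimise) one reaction's flux at steady state."""
    obj = _resolve_objective(model, objective)
    constrained = apply_medium(model, medium) if medium is not None else model
    return _LP(constrained).optimize(obj, maximize=maximize)


def run_fva(
    model: MetabolicModel,
    medium: Optional[MediumCondition] = None,
    fraction_of_optimum: float = 1.0,
    objective: Optional[str] = None,
    reactions: Optional[Iterable[str]] = None,
) -> FVAResult:
    """Per-reaction flux ranges with the objective held at a fraction of optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ModelValidationError("fraction_of_optimum must lie in [0, 1]")
    obj = _resolve_objective(model, objective)
    constrained = apply_medium(model, medium) if medium is not None else model
    lp = _LP(constrained)
    base = lp.optimize(obj)
    if not base.optimal:
        raise RuntimeError(f"base FBA problem is {base.status}")
    floor = fraction_of_optimum * base.objective_value
    lo, hi = lp.bounds[lp.rindex[obj]]
    # Tiny relaxation keeps the pinned problem feasible at fraction 1.0.
    lp.set_bounds(obj, max(lo, floor - 1e-9), hi)

    ranges: Dict[str, Tuple[float, float]] = {}
    targets = list(reactions) if reactions is not None else lp.reaction_ids
    for rid in targets:
        vmin = lp.optimize(rid, maximize=False)
        vmax = lp.optimize(rid, maximize=True)
        if not (vmin.optimal and vmax.optimal):
            raise RuntimeError(f"FVA subproblem for {rid} is not optimal")
        ranges[rid] = (vmin.objective_value, vmax.objective_value)
    return FVAResult(fraction_of_optimum, base.objective_value, ranges)


def _disabled_reactions(model: MetabolicModel, deleted: Set[str]) -> Set[str]:
    return {
        r.id
        for r in model.reactions.values()
        if r.gpr is not None and not evaluate_gpr(r.gpr, deleted)
    }


def knockout_model(model: MetabolicModel, genes: Set[str]) -> Tuple[MetabolicModel, Set[str]]:
    """Copy of the model with all reactions losing their GPR forced to zero."""
    unknown = set(genes) - set(model.genes)
    if unknown:
        raise ModelValidationError(f"unknown genes: {sorted(unknown)}")
    out = model.copy()
    disabled = _disabled_reactions(out, set(genes))
    for rid in disabled:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    return out, disabled


def delete_genes(
    model: MetabolicModel,
    medium: Optional[MediumCondition],
    genes: Set[str],
    atp_synthase_id: Optional[str] = None,
    atp_synthase_biomass_fraction: float = 0.0,
    find_blocked: bool = False,
) -> DeletionResult:
    """Simulate a gene-set knockout and report yields relative to wild type.

    The maximum ATP-synthase flux is, by default, a plain maximisation with
    no biomass requirement; pass ``atp_synthase_biomass_fraction > 0`` to
    require that fraction of the optimal biomass instead.
    """
    constrained = apply_medium(model, medium) if medium is not None else model
    wt = solve_fba(constrained)
    if not wt.optimal:
        raise ModelValidationError(f"wild-type problem is {wt.status}")
    mutant, disabled = knockout_model(constrained, genes)
    mut = solve_fba(mutant)
    biomass_mut = mut.objective_value if mut.optimal else 0.0

    atps_wt = atps_mut = None
    if atp_synthase_id is not None:
        atps_wt = _max_flux(constrained, atp_synthase_id, atp_synthase_biomass_fraction)
        atps_mut = _max_flux(mutant, atp_synthase_id, atp_synthase_biomass_fraction)

    blocked: Set[str] = set()
    if find_blocked:
        ex_ids = [r.id for r in mutant.exchanges]
        fva = run_fva(mutant, fraction_of_optimum=0.0, reactions=ex_ids)
        blocked = {rid for rid in ex_ids if fva.is_blocked(rid)}
    return DeletionResult(
        deleted_genes=set(genes),
        disabled_reactions=disabled,
        biomass_wt=wt.objective_value,
        biomass_deleted=biomass_mut,
        atp_synthase_wt=atps_wt,
        atp_synthase_deleted=atps_mut,
        blocked_exchanges=blocked,
    )


def _max_flux(model: MetabolicModel, reaction_id: str, biomass_fraction: float) -> float:
    if biomass_fraction > 0:
        fva = run_fva(model, fraction_of_optimum=biomass_fraction, reactions=[reaction_id])
        return fva.ranges[reaction_id][1]
    res = solve_fba(model, objective=reaction_id)
    return res.objective_value if res.optimal else 0.0


def delete_complexes(
    model: MetabolicModel,
    medium: Optional[MediumCondition],
    complexes: Mapping[str, Iterable[str]],
    atp_synthase_id: Optional[str] = None,
    find_blocked: bool = True,
) -> DeletionResult:
    """Knock out whole complexes (named gene sets) jointly."""
    genes: Set[str] = set()
    for name, members in complexes.items():
        members = set(members)
        if not members:
            raise ModelValidationError(f"complex {name!r} has no genes")
        genes |= members
    return delete_genes(
        model,
        medium,
        genes,
        atp_synthase_id=atp_synthase_id,
        find_blocked=find_blocked,
    )


def deletion_panel(
    model: MetabolicModel,
    medium: Optional[MediumCondition],
    complexes: Mapping[str, Iterable[str]],
    atp_synthase_id: Optional[str] = None,
) -> List[Tuple[Tuple[str, ...], DeletionResult]]:
    """WT plus every single/double/.../full combination of the named complexes.

    Mirrors a knockout panel over energy complexes: for ``n`` complexes the
    panel holds ``2^n - 1`` deletion conditions in deterministic order.
    """
    from itertools import combinations

    names = sorted(complexes)
    panel: List[Tuple[Tuple[str, ...], DeletionResult]] = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            sub = {name: complexes[name] for name in combo}
            panel.append(
                (combo, delete_complexes(model, medium, sub, atp_synthase_id=atp_synthase_id))
            )
    return panel
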