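"""Gap-filling: complete a draft network until target compounds are producible.

A target is producible when a temporary sink demand on it can carry at least
``epsilon`` flux under the medium; targets are tested one at a time so joint
producibility cannot mask a single-target gap. The filler returns a
penalty-minimal subset of a universal reaction database (ties broken
lexicographically by the sorted id tuple): exact exhaustive search below a
size threshold, LP-relaxation-guided candidate pooling plus exact search on
the pool above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .fba import _LP
from .medium import MediumCondition, apply_medium
from .model import Compound, MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "GapfillProblem",
    "UnfillableError",
    "gapfill",
    "find_blocked_targets",
    "DEFAULT_TARGETS",
    "DEFAULT_EPSILON",
]

#: Biomass precursors and essential cofactors completed by default: the
#: building blocks of the informational polymers plus NAD(P)+ and CoA.
DEFAULT_TARGETS = ("dna_prec", "rna_prec", "protein_prec", "nad", "nadp", "coa")

#: Minimum production flux for a target to count as producible.
DEFAULT_EPSILON = 1e-3

#: Below this universal-set size the search is exhaustive (provably minimal).
EXHAUSTIVE_LIMIT = 12


class UnfillableError(RuntimeError):
    def __init__(self, targets: Sequence[str]):
        self.targets = list(targets)
        super().__init__(
            "no subset of the universal database makes these targets producible: "
            + ", ".join(targets)
        )


@dataclass
class GapfillProblem:
    draft: MetabolicModel
    universal: List[Reaction] = field(default_factory=list)
    targets: Sequence[str] = DEFAULT_TARGETS
    medium: Optional[MediumCondition] = None
    penalties: Dict[str, float] = field(default_factory=dict)
    epsilon: float = DEFAULT_EPSILON
    #: Compound definitions for universal reactions introducing new species.
    universal_compounds: List[Compound] = field(default_factory=list)

    def __post_init__(self):
        known = set(self.draft.compounds) | {c.id for c in self.universal_compounds}
        for r in self.universal:
            known |= set(r.stoichiometry)
        missing = [t for t in self.targets if t not in known]
        if missing:
            raise ModelValidationError(
                f"gapfill targets absent from draft and universal: {missing}"
            )
        for rid, pen in self.penalties.items():
            if pen <= 0:
                raise ModelValidationError(f"penalty for {rid} must be positive")

    def penalty(self, reaction_id: str) -> float:
        return self.penalties.get(reaction_id, 1.0)


def _sink_stoichiometry(model: MetabolicModel, target: str) -> Dict[str, float]:
    """Demand used to probe producibility of one target.

    Plain removal would drain the conserved moiety of group- and
    electron-carrier cofactors (consuming ATP without returning ADP can
    never balance), so those targets are probed as turnover instead: ATP as
    hydrolysis to ADP + Pi, reduced carriers as re-oxidation to their
    partner. Everything else is a simple sink.
    """
    if target == "atp" and all(c in model.compounds for c in ("adp", "pi", "h", "h2o")):
        return {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0}
    pairs = {"nadph": "nadp", "nadh": "nad", "fdred": "fdox"}
    partner = pairs.get(target)
    if partner is not None and partner in model.compounds:
        return {target: -1.0, partner: 1.0}
    return {target: -1.0}


def _with_sink(model: MetabolicModel, target: str) -> Tuple[MetabolicModel, str]:
    out = model.copy()
    sink_id = f"__sink_{target}"
    out.add_reaction(
        Reaction(
            id=sink_id,
            stoichiometry=_sink_stoichiometry(out, target),
            lower_bound=0.0,
            upper_bound=1e6,
        )
    )
    return out, sink_id


def _max_production(model: MetabolicModel, target: str) -> float:
    if target not in model.compounds:
        return 0.0
    with_sink, sink_id = _with_sink(model, target)
    res = _LP(with_sink).optimize(sink_id, maximize=True)
    if res.status == "unbounded":
        return float("inf")
    return res.objective_value if res.optimal else 0.0


def find_blocked_targets(
    model: MetabolicModel,
    medium: Optional[MediumCondition],
    targets: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
) -> List[str]:
    """Targets whose maximal sink flux under the medium falls below epsilon."""
    constrained = apply_medium(model, medium) if medium is not None else model
    return [t for t in targets if _max_production(constrained, t) < epsilon]


def _extend(model: MetabolicModel, problem: GapfillProblem, subset: Iterable[Reaction]) -> MetabolicModel:
    out = model.copy()
    defs = {c.id: c for c in problem.universal_compounds}
    for r in subset:
        for cid in r.stoichiometry:
            if cid not in out.compounds:
                out.add_compound(defs.get(cid, Compound(id=cid)))
        added = r.copy()
        added.evidence = "gapfilled"
        out.add_reaction(added)
    return out


def _completes(model: MetabolicModel, problem: GapfillProblem, subset: Sequence[Reaction]) -> bool:
    extended = _extend(model, problem, subset)
    for target in problem.targets:
        if _max_production(extended, target) < problem.epsilon:
            return False
    return True


def _search_exact(
    base: MetabolicModel, problem: GapfillProblem, candidates: List[Reaction]
) -> Optional[List[str]]:
    """Penalty-minimal completing subset by ordered exhaustive search."""
    subsets = []
    for k in range(len(candidates) + 1):
        for combo in combinations(sorted(candidates, key=lambda r: r.id), k):
            ids = tuple(r.id for r in combo)
            subsets.append((sum(problem.penalty(i) for i in ids), ids, combo))
    subsets.sort(key=lambda item: (item[0], item[1]))
    for _, ids, combo in subsets:
        if _completes(base, problem, combo):
            return list(ids)
    return None


def _candidate_pool(base: MetabolicModel, problem: GapfillProblem) -> List[Reaction]:
    """LP-relaxation pool: candidates carrying flux when all are admitted."""
    everything = _extend(base, problem, problem.universal)
    pool_ids: Set[str] = set()
    for target in problem.targets:
        with_sink, sink_id = _with_sink(everything, target)
        res = _LP(with_sink).optimize(sink_id, maximize=True)
        if not res.optimal:
            continue
        for r in problem.universal:
            if abs(res.fluxes.get(r.id, 0.0)) > 1e-9:
                pool_ids.add(r.id)
    return [r for r in problem.universal if r.id in pool_ids]


def gapfill(problem: GapfillProblem) -> List[str]:
    """Minimal-penalty reaction ids completing the draft; [] if already complete.

    Raises :class:`UnfillableError` when even the full universal database
    leaves some target unproducible.
    """
    base = (
        apply_medium(problem.draft, problem.medium)
        if problem.medium is not None
        else problem.draft
    )
    if _completes(base, problem, []):
        return []
    if not problem.universal:
        raise UnfillableError(find_blocked_targets(base, None, problem.targets, problem.epsilon))
    if not _completes(base, problem, problem.universal):
        extended = _extend(base, problem, problem.universal)
        raise UnfillableError(
            find_blocked_targets(extended, None, problem.targets, problem.epsilon)
        )

    candidates = list(problem.universal)
    if len(candidates) > EXHAUSTIVE_LIMIT:
        pool = _candidate_pool(base, problem)
        if _completes(base, problem, pool):
            candidates = pool
    if len(candidates) <= EXHAUSTIVE_LIMIT:
        result = _search_exact(base, problem, candidates)
        if result is not None:
            return result
        candidates = list(problem.universal)

    # Greedy fallback for large instances: start from the (verified feasible)
    # candidate set and drop reactions most expensive first while the set
    # still completes all targets.
    keep = sorted(candidates, key=lambda r: (-problem.penalty(r.id), r.id))
    for r in list(keep):
        trial = [x for x in keep if x.id != r.id]
        if _completes(base, problem, trial):
            keep = trial
    return sorted(r.id for r in keep)
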