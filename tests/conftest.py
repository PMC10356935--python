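"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ventgem.medium import MediumCondition
from ventgem.model import Compound, MetabolicModel, Reaction
from ventgem.synth import (
    ToyModelParams,
    make_auxotrophy_model,
    make_toy_energy_model,
    toy_sulfur_medium,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return make_toy_energy_model()


@pytest.fixture(scope="session")
def sulfur_medium() -> MediumCondition:
    return toy_sulfur_medium()


@pytest.fixture(scope="session")
def no_sulfur_medium() -> MediumCondition:
    return toy_sulfur_medium(sulfur=False)


@pytest.fixture(scope="session")
def aux_model() -> MetabolicModel:
    return make_auxotrophy_model()


# ---------------------------------------------------------------------------
# independent FBA oracle: COBRApy on its own solver (GLPK), never ours
# ---------------------------------------------------------------------------


def to_cobra(model: MetabolicModel, objective: str):
    """Translate a model into a COBRApy model with the given objective."""
    import cobra

    cm = cobra.Model(model.name or "m")
    mets = {
        cid: cobra.Metabolite(cid, compartment=model.compounds[cid].compartment or "c")
        for cid in model.compounds
    }
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[cid]: coef for cid, coef in r.stoichiometry.items()}
        )
    cm.objective = cm.reactions.get_by_id(objective)
    return cm


def oracle_fba(model: MetabolicModel, objective: str):
    """(status, optimum) from the independent solver."""
    cm = to_cobra(model, objective)
    sol = cm.optimize()
    if sol.status != "optimal":
        return sol.status, None
    return "optimal", float(sol.objective_value)


# ---------------------------------------------------------------------------
# randomized small models (always feasible: zero flux admissible everywhere)
# ---------------------------------------------------------------------------


def random_small_model(rng: np.random.Generator, max_reactions: int = 8) -> MetabolicModel:
    n_compounds = int(rng.integers(2, 5))
    compounds = [Compound(id=f"c{i}") for i in range(n_compounds)]
    n_reactions = int(rng.integers(2, max_reactions + 1))
    reactions = []
    for j in range(n_reactions):
        size = int(rng.integers(1, min(3, n_compounds) + 1))
        members = rng.choice(n_compounds, size=size, replace=False)
        stoich = {}
        for cid in members:
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            stoich[f"c{cid}"] = coef
        lb, ub = [(-10.0, 10.0), (0.0, 10.0), (-10.0, 0.0)][int(rng.integers(0, 3))]
        reactions.append(
            Reaction(id=f"r{j}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    return MetabolicModel.from_lists(compounds, reactions)
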