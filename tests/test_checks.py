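"""Formula/charge balance and stoichiometric (mass) consistency checks."""

import pytest

from ventgem.checks import (
    STATUS_BALANCED,
    STATUS_EXEMPT,
    STATUS_SKIPPED,
    STATUS_UNBALANCED,
    check_charge_balance,
    check_formula_balance,
    check_mass_consistency,
    check_model,
)
from ventgem.model import Compound, MetabolicModel, Reaction


def _model(compounds, reactions, biomass=None):
    return MetabolicModel.from_lists(compounds, reactions, biomass_reaction_id=biomass)


def brute_force_residuals(reaction, model):
    """Independent element/charge summation, written apart from the package."""
    elements = {}
    charge = 0.0
    for cid, coef in reaction.stoichiometry.items():
        compound = model.compounds[cid]
        for el, n in (compound.formula or {}).items():
            elements[el] = elements.get(el, 0.0) + coef * n
        charge += coef * (compound.charge or 0)
    return {el: r for el, r in elements.items() if r != 0}, charge


class TestFormulaBalance:
    def test_identity_transport_balanced(self):
        model = _model(
            [
                Compound(id="h2o_in", formula={"H": 2, "O": 1}, charge=0, compartment="e"),
                Compound(id="h2o_out", formula={"H": 2, "O": 1}, charge=0, compartment="c"),
            ],
            [Reaction(id="t", stoichiometry={"h2o_in": -1.0, "h2o_out": 1.0})],
        )
        report = check_formula_balance(model.reactions["t"], model)
        assert report.status == STATUS_BALANCED
        assert report.detail == {}

    def test_glucose_to_lactate_missing_protons(self):
        # C6H12O6 -> 2 C3H5O3(-) leaves an H residual of -2
        model = _model(
            [
                Compound(id="glc", formula={"C": 6, "H": 12, "O": 6}, charge=0),
                Compound(id="lac", formula={"C": 3, "H": 5, "O": 3}, charge=-1),
            ],
            [Reaction(id="r", stoichiometry={"glc": -1.0, "lac": 2.0})],
        )
        report = check_formula_balance(model.reactions["r"], model)
        assert report.status == STATUS_UNBALANCED
        assert report.detail == {"H": pytest.approx(-2.0)}

    def test_exchange_reactions_exempt(self):
        model = _model(
            [Compound(id="glc", formula={"C": 6, "H": 12, "O": 6}, charge=0)],
            [Reaction(id="EX_glc", stoichiometry={"glc": -1.0})],
        )
        assert check_formula_balance(model.reactions["EX_glc"], model).status == STATUS_EXEMPT

    def test_biomass_reaction_exempt(self):
        model = _model(
            [Compound(id="a", formula={"C": 1}, charge=0), Compound(id="biomass")],
            [Reaction(id="BIOMASS", stoichiometry={"a": -1.0, "biomass": 1.0})],
            biomass="BIOMASS",
        )
        assert check_formula_balance(model.reactions["BIOMASS"], model).status == STATUS_EXEMPT

    def test_unknown_formula_skipped_never_judged(self):
        model = _model(
            [Compound(id="a", formula=None), Compound(id="b", formula={"C": 1}, charge=0)],
            [Reaction(id="r", stoichiometry={"a": -1.0, "b": 1.0})],
        )
        assert check_formula_balance(model.reactions["r"], model).status == STATUS_SKIPPED

    def test_foreign_reaction_rejected(self, toy_model):
        stranger = Reaction(id="stranger", stoichiometry={"atp": -1.0})
        with pytest.raises(ValueError):
            check_formula_balance(stranger, toy_model)


class TestChargeBalance:
    def test_atp_hydrolysis_balanced(self):
        model = _model(
            [
                Compound(id="atp", formula={"C": 10}, charge=-4),
                Compound(id="h2o", formula={"H": 2, "O": 1}, charge=0),
                Compound(id="adp", formula={"C": 10}, charge=-3),
                Compound(id="pi", formula={"P": 1}, charge=-2),
                Compound(id="h", formula={"H": 1}, charge=1),
            ],
            [
                Reaction(
                    id="atpase",
                    stoichiometry={"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0},
                )
            ],
        )
        assert check_charge_balance(model.reactions["atpase"], model).status == STATUS_BALANCED

    def test_unit_charge_residual(self):
        model = _model(
            [Compound(id="a", charge=0), Compound(id="b", charge=-1)],
            [Reaction(id="r", stoichiometry={"a": -1.0, "b": 1.0})],
        )
        report = check_charge_balance(model.reactions["r"], model)
        assert report.status == STATUS_UNBALANCED
        assert report.detail["charge"] == pytest.approx(-1.0)

    def test_unknown_charge_skipped(self):
        model = _model(
            [Compound(id="a", charge=None), Compound(id="b", charge=0)],
            [Reaction(id="r", stoichiometry={"a": -1.0, "b": 1.0})],
        )
        assert check_charge_balance(model.reactions["r"], model).status == STATUS_SKIPPED


class TestAgainstBruteForce:
    def test_toy_model_matches_independent_summation(self, toy_model):
        for reaction in toy_model.reactions.values():
            if reaction.is_exchange or reaction.id == toy_model.biomass_reaction_id:
                continue
            elements, charge = brute_force_residuals(reaction, toy_model)
            assert check_formula_balance(reaction, toy_model).status == (
                STATUS_BALANCED if not elements else STATUS_UNBALANCED
            ), reaction.id
            assert check_charge_balance(reaction, toy_model).status == (
                STATUS_BALANCED if charge == 0 else STATUS_UNBALANCED
            ), reaction.id


class TestMassConsistency:
    def test_linear_chain_consistent(self):
        model = _model(
            [Compound(id=c) for c in "abc"],
            [
                Reaction(id="r1", stoichiometry={"a": -1.0, "b": 1.0}),
                Reaction(id="r2", stoichiometry={"b": -1.0, "c": 1.0}),
            ],
        )
        reports = {r.reaction_id: r for r in check_mass_consistency(model)}
        assert reports["r1"].status == STATUS_BALANCED
        assert reports["r2"].status == STATUS_BALANCED

    def test_generation_from_nothing_flagged(self):
        # doubling loop a -> 2b, b -> a: no positive mass satisfies m_a = 2 m_a
        model = _model(
            [Compound(id="a"), Compound(id="b")],
            [
                Reaction(id="doubler", stoichiometry={"a": -1.0, "b": 2.0}),
                Reaction(id="back", stoichiometry={"b": -1.0, "a": 1.0}),
            ],
        )
        flagged = {
            r.reaction_id
            for r in check_mass_consistency(model)
            if r.status == STATUS_UNBALANCED
        }
        assert flagged and flagged <= {"doubler", "back"}

    def test_planted_violator_flagged_exactly(self):
        # 10-reaction chain with one mass-creating step planted in the middle
        compounds = [Compound(id=f"c{i}") for i in range(11)]
        reactions = []
        for i in range(10):
            coef = 2.0 if i == 5 else 1.0  # c5 -> 2 c6 violates conservation
            reactions.append(
                Reaction(id=f"r{i}", stoichiometry={f"c{i}": -1.0, f"c{i+1}": coef})
            )
        # close the loop so the violation cannot be absorbed by free ends
        reactions.append(Reaction(id="loop", stoichiometry={"c10": -1.0, "c0": 1.0}))
        model = _model(compounds, reactions)
        flagged = {
            r.reaction_id
            for r in check_mass_consistency(model)
            if r.status == STATUS_UNBALANCED
        }
        assert flagged == {"r5"}

    def test_formula_balanced_implies_mass_consistent(self, toy_model):
        # every internal toy reaction has known formulas and is balanced,
        # so the LP must find a positive mass assignment with no residual
        flagged = [
            r for r in check_mass_consistency(toy_model) if r.status == STATUS_UNBALANCED
        ]
        assert flagged == []

    def test_check_model_runs_all_three(self, toy_model):
        reports = check_model(toy_model)
        assert {r.check for r in reports} == {"formula", "charge", "mass"}
        assert all(r.ok for r in reports)
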