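"""FBA/FVA/knockout engine against hand-solved LPs and an independent solver."""

import numpy as np
import pytest

from conftest import oracle_fba, random_small_model

from ventgem.fba import delete_complexes, delete_genes, deletion_panel, run_fva, solve_fba
from ventgem.medium import MediumCondition, apply_medium
from ventgem.model import Compound, MetabolicModel, ModelValidationError, Reaction
from ventgem.synth import toy_complexes


def chain_model(uptake=10.0):
    """EX_A -(uptake)-> A -> B -> biomass, all unit coefficients."""
    return MetabolicModel.from_lists(
        [Compound(id="A"), Compound(id="B"), Compound(id="biomass")],
        [
            Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-uptake, upper_bound=0.0),
            Reaction(id="r1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0),
            Reaction(id="BIOMASS", stoichiometry={"B": -1.0, "biomass": 1.0}, lower_bound=0.0),
            Reaction(id="EX_biomass", stoichiometry={"biomass": -1.0}, lower_bound=0.0),
        ],
        biomass_reaction_id="BIOMASS",
    )


class TestSolveFBA:
    def test_linear_chain_optimum_equals_uptake_bound(self):
        res = solve_fba(chain_model(uptake=10.0))
        assert res.optimal
        assert res.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_all_uptakes_closed_yields_zero(self, toy_model):
        closed = MediumCondition("closed", {}, closed_by_default=True)
        res = solve_fba(toy_model, closed)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_objective_rejected(self, toy_model):
        with pytest.raises(ModelValidationError, match="objective"):
            solve_fba(toy_model, objective="NO_SUCH")

    def test_objective_value_deterministic(self, toy_model, sulfur_medium):
        values = {solve_fba(toy_model, sulfur_medium).objective_value for _ in range(5)}
        assert max(values) - min(values) <= 1e-9

    def test_steady_state_residual(self, toy_model, sulfur_medium):
        res = solve_fba(toy_model, sulfur_medium)
        constrained = apply_medium(toy_model, sulfur_medium)
        residual = {}
        for rid, v in res.fluxes.items():
            for cid, coef in constrained.reactions[rid].stoichiometry.items():
                residual[cid] = residual.get(cid, 0.0) + coef * v
        assert max(abs(r) for r in residual.values()) <= 1e-6

    def test_matches_independent_solver_on_random_models(self):
        """Optimum agrees with the second solver on 40 random <=8-reaction LPs."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            model = random_small_model(rng)
            objective = sorted(model.reactions)[int(rng.integers(len(model.reactions)))]
            ours = solve_fba(model, objective=objective)
            status, reference = oracle_fba(model, objective)
            assert ours.status == status
            if reference is not None:
                assert ours.objective_value == pytest.approx(reference, abs=1e-6)


class TestRunFVA:
    def test_linear_chain_has_no_freedom(self):
        model = chain_model()
        fva = run_fva(model, fraction_of_optimum=1.0)
        fba = solve_fba(model)
        for rid, (lo, hi) in fva.ranges.items():
            assert lo == pytest.approx(hi, abs=1e-6)
            assert lo == pytest.approx(fba.fluxes[rid], abs=1e-6)

    def test_parallel_routes_span_full_range(self):
        # two equivalent A->B routes, each bounded at 10, demand fixed at 10
        model = MetabolicModel.from_lists(
            [Compound(id="A"), Compound(id="B")],
            [
                Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-10.0, upper_bound=0.0),
                Reaction(id="route1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
                Reaction(id="route2", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
                Reaction(id="demand", stoichiometry={"B": -1.0}, lower_bound=10.0, upper_bound=10.0),
            ],
        )
        fva = run_fva(model, objective="demand", fraction_of_optimum=1.0)
        assert fva.ranges["route1"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))
        assert fva.ranges["route2"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))

    def test_sandwich_contains_fba_fluxes(self, toy_model, sulfur_medium):
        fba = solve_fba(toy_model, sulfur_medium)
        fva = run_fva(toy_model, sulfur_medium, fraction_of_optimum=1.0)
        for rid, v in fba.fluxes.items():
            lo, hi = fva.ranges[rid]
            assert lo - 1e-6 <= v <= hi + 1e-6, rid
            assert lo <= hi + 1e-9, rid

    def test_objective_range_contains_fraction_of_optimum(self, toy_model, sulfur_medium):
        fva = run_fva(toy_model, sulfur_medium, fraction_of_optimum=0.5)
        lo, hi = fva.ranges[toy_model.biomass_reaction_id]
        floor = 0.5 * fva.objective_value
        assert lo >= floor - 1e-6 and hi >= floor - 1e-6

    def test_atp_synthase_max_cross_checked_by_swapped_objective(
        self, toy_model, sulfur_medium
    ):
        fva = run_fva(toy_model, sulfur_medium, fraction_of_optimum=1.0, reactions=["ATPS"])
        pinned = apply_medium(toy_model, sulfur_medium)
        biomass = solve_fba(pinned)
        pinned.reactions[pinned.biomass_reaction_id].lower_bound = (
            biomass.objective_value - 1e-9
        )
        swapped = solve_fba(pinned, objective="ATPS")
        assert fva.ranges["ATPS"][1] == pytest.approx(swapped.objective_value, abs=1e-5)

    def test_bad_fraction_rejected(self, toy_model):
        with pytest.raises(ModelValidationError):
            run_fva(toy_model, fraction_of_optimum=1.5)


class TestApplyMedium:
    def test_uptake_sign_convention(self, toy_model):
        medium = MediumCondition("m", {"EX_glc": (1.667, 5.0)})
        constrained = apply_medium(toy_model, medium)
        assert constrained.reactions["EX_glc"].lower_bound == pytest.approx(-1.667)
        assert constrained.reactions["EX_glc"].upper_bound == pytest.approx(5.0)

    def test_closed_by_default_blocks_unlisted_uptakes(self, toy_model):
        constrained = apply_medium(toy_model, MediumCondition("empty", {}))
        for reaction in constrained.exchanges:
            assert reaction.lower_bound == 0.0
            assert reaction.upper_bound > 0.0  # secretion stays open

    def test_idempotent(self, toy_model, sulfur_medium):
        once = apply_medium(toy_model, sulfur_medium)
        twice = apply_medium(once, sulfur_medium)
        for rid in once.reactions:
            assert once.reactions[rid].lower_bound == twice.reactions[rid].lower_bound
            assert once.reactions[rid].upper_bound == twice.reactions[rid].upper_bound

    def test_non_exchange_id_rejected(self, toy_model):
        with pytest.raises(ModelValidationError):
            apply_medium(toy_model, MediumCondition("m", {"PFOR": (1.0, 1.0)}))

    def test_negative_bound_magnitude_rejected(self):
        with pytest.raises(ModelValidationError):
            MediumCondition("m", {"EX_glc": (-1.0, 0.0)})


class TestDeletions:
    def test_redundant_isozyme_deletion_is_noop(self):
        from ventgem.gpr import parse_gpr

        model = chain_model()
        model.reactions["r1"].gpr = parse_gpr("iso1 or iso2")
        result = delete_genes(model, None, {"iso1"})
        assert result.disabled_reactions == set()
        assert result.biomass_relative == pytest.approx(1.0, abs=1e-9)

    def test_unknown_gene_rejected(self, toy_model, sulfur_medium):
        with pytest.raises(ModelValidationError, match="unknown genes"):
            delete_genes(toy_model, sulfur_medium, {"ghost_gene"})

    def test_single_complex_deletions_reduce_growth(self, toy_model, sulfur_medium):
        wt = solve_fba(toy_model, sulfur_medium).objective_value
        for name, genes in toy_complexes().items():
            result = delete_genes(toy_model, sulfur_medium, genes)
            assert 0.0 <= result.biomass_relative <= 1.0 + 1e-9, name
            assert result.biomass_wt == pytest.approx(wt, abs=1e-9)

    def test_disabled_reactions_have_gprs(self, toy_model, sulfur_medium):
        result = delete_complexes(toy_model, sulfur_medium, toy_complexes())
        for rid in result.disabled_reactions:
            assert toy_model.reactions[rid].gpr is not None

    def test_nested_deletions_monotone(self, toy_model, sulfur_medium):
        """Adding constraints (more deleted genes) never raises the optimum."""
        rng = np.random.default_rng(11)
        genes = sorted(toy_model.genes)
        for _ in range(20):
            chain_length = int(rng.integers(2, 4))
            picks = rng.choice(len(genes), size=chain_length, replace=False)
            deleted = set()
            previous = np.inf
            for g in picks:
                deleted.add(genes[g])
                value = delete_genes(toy_model, sulfur_medium, set(deleted)).biomass_deleted
                assert value <= previous + 1e-6
                previous = value

    def test_panel_covers_all_combinations(self, toy_model, sulfur_medium):
        panel = deletion_panel(toy_model, sulfur_medium, toy_complexes(), atp_synthase_id="ATPS")
        assert len(panel) == 7  # 3 singles + 3 doubles + 1 triple
        by_combo = {combo: res for combo, res in panel}
        triple = by_combo[("MBS", "Nfn2", "SH1")]
        for combo, res in panel:
            assert triple.biomass_deleted <= res.biomass_deleted + 1e-6
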