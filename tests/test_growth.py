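"""Growth protocols: carbon normalisation, growth calls, essentiality, rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ventgem.growth import (
    AMINO_ACIDS,
    GrowthCurve,
    PathwayDefinition,
    classify_growth,
    electron_acceptor_scan,
    essential_aas_from_genome,
    growth_rate,
    growth_rate_regression,
    leave_one_out_scan,
    make_carbon_medium,
)
from ventgem.medium import MediumCondition
from ventgem.model import Compound, MetabolicModel, ModelValidationError, Reaction
from ventgem.synth import (
    DEFAULT_ESSENTIAL_AAS,
    auxotrophy_medium,
    auxotrophy_pathways,
    make_auxotrophy_model,
    make_growth_curve,
)


class TestMakeCarbonMedium:
    def test_one_carbon_compound_gets_full_budget(self, toy_model):
        model = toy_model.copy()
        model.add_compound(Compound(id="formate", formula={"C": 1, "H": 1, "O": 2}, charge=-1))
        model.add_reaction(Reaction(id="EX_formate", stoichiometry={"formate": -1.0}))
        medium = make_carbon_medium(MediumCondition("base", {}), "formate", model)
        assert medium.exchange_bounds["EX_formate"][0] == pytest.approx(10.0)

    def test_glucose_scaled_by_six_carbons(self, toy_model):
        medium = make_carbon_medium(MediumCondition("base", {}), "glc", toy_model)
        assert medium.exchange_bounds["EX_glc"][0] == pytest.approx(10.0 / 6.0)

    def test_twelve_carbon_sugar_scaled(self, toy_model):
        model = toy_model.copy()
        model.add_compound(
            Compound(id="sucrose", formula={"C": 12, "H": 22, "O": 11}, charge=0)
        )
        model.add_reaction(Reaction(id="EX_sucrose", stoichiometry={"sucrose": -1.0}))
        medium = make_carbon_medium(MediumCondition("base", {}), "sucrose", model)
        assert medium.exchange_bounds["EX_sucrose"][0] == pytest.approx(10.0 / 12.0)

    def test_essential_amino_acids_ride_along(self, toy_model):
        medium = make_carbon_medium(
            MediumCondition("base", {}), "glc", toy_model, essential_aas=["ala"]
        )
        assert medium.exchange_bounds["EX_ala"][0] == pytest.approx(1.0)

    def test_carbon_free_compound_rejected(self, toy_model):
        with pytest.raises(ModelValidationError, match="carbon-free"):
            make_carbon_medium(MediumCondition("base", {}), "s0", toy_model)

    def test_unknown_formula_rejected(self, toy_model):
        with pytest.raises(ModelValidationError, match="formula"):
            make_carbon_medium(MediumCondition("base", {}), "biomass", toy_model)


class TestClassifyGrowth:
    def test_zero_yield_is_no_growth(self):
        assert classify_growth(0.0, 5.0) == "-"

    def test_exact_threshold_is_inclusive(self):
        assert classify_growth(7.5, 5.0) == "++"  # ratio exactly 1.5

    def test_parity_with_reference_is_plus(self):
        assert classify_growth(5.0, 5.0) == "+"

    def test_below_reference_but_growing_is_plus(self):
        assert classify_growth(1.0, 5.0) == "+"

    def test_dead_reference_rejected(self):
        with pytest.raises(ModelValidationError):
            classify_growth(1.0, 0.0)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_total_deterministic_partition(self, value):
        call = classify_growth(value, 5.0)
        assert call in ("-", "+", "++")
        assert call == classify_growth(value, 5.0)


class TestLeaveOneOut:
    def test_planted_auxotrophies_recovered_exactly(self, aux_model):
        calls = leave_one_out_scan(aux_model, auxotrophy_medium())
        assert set(calls) == set(AMINO_ACIDS)
        negatives = {aa for aa, call in calls.items() if call == "-"}
        assert negatives == set(DEFAULT_ESSENTIAL_AAS)

    def test_synthesisable_amino_acid_scores_plus(self, aux_model):
        calls = leave_one_out_scan(aux_model, auxotrophy_medium())
        assert calls["gly"] == "+"

    def test_forced_auxotrophy_scores_minus(self):
        model = make_auxotrophy_model(essential={"ala"})
        calls = leave_one_out_scan(model, auxotrophy_medium())
        assert calls["ala"] == "-"

    def test_infeasible_baseline_rejected(self, aux_model):
        dead = MediumCondition("dead", {}, closed_by_default=True)
        with pytest.raises(ModelValidationError, match="baseline"):
            leave_one_out_scan(aux_model, dead)


class TestGenomicEssentiality:
    def _pathway(self, aa, n):
        return PathwayDefinition(aa, frozenset(f"{aa}_step{i}" for i in range(n)))

    def _model_with(self, reaction_ids):
        return MetabolicModel.from_lists(
            [Compound(id="x")],
            [Reaction(id=rid, stoichiometry={"x": 1.0}) for rid in reaction_ids],
        )

    def test_complete_pathway_nonessential(self):
        pathway = self._pathway("gly", 4)
        model = self._model_with(pathway.reaction_ids)
        assert essential_aas_from_genome(model, [pathway]) == set()

    def test_fully_absent_pathway_essential(self):
        assert essential_aas_from_genome(self._model_with([]), [self._pathway("his", 4)]) == {"his"}

    def test_exact_half_missing_is_essential(self):
        pathway = self._pathway("trp", 6)
        present = sorted(pathway.reaction_ids)[:3]  # 3 of 6 absent: exactly 50%
        model = self._model_with(present)
        assert essential_aas_from_genome(model, [pathway]) == {"trp"}

    def test_empty_pathway_rejected(self):
        with pytest.raises(ModelValidationError):
            PathwayDefinition("gly", frozenset())

    def test_monotone_under_reaction_removal(self, aux_model):
        pathways = auxotrophy_pathways()
        full = essential_aas_from_genome(aux_model, pathways)
        pruned = aux_model.copy()
        for rid in [r for r in pruned.reactions if r.startswith("SYN_gly")]:
            del pruned.reactions[rid]
        shrunk = essential_aas_from_genome(pruned, pathways)
        assert full <= shrunk
        assert "gly" in shrunk and "gly" not in full

    def test_agrees_with_fba_scan_on_planted_model(self, aux_model):
        genomic = essential_aas_from_genome(aux_model, auxotrophy_pathways())
        calls = leave_one_out_scan(aux_model, auxotrophy_medium())
        fba_negatives = {aa for aa, call in calls.items() if call == "-"}
        assert genomic == fba_negatives


class TestElectronAcceptorScan:
    def test_sulfur_strictly_stimulates(self, toy_model, no_sulfur_medium):
        yields = electron_acceptor_scan(toy_model, no_sulfur_medium, ["s0"])
        assert yields[None] > 1e-6  # fermentative growth without an acceptor
        assert yields["s0"] > yields[None] + 1e-6

    def test_unusable_acceptor_equals_no_acceptor(self, toy_model, no_sulfur_medium):
        # nothing in the network consumes imported acetate as an acceptor
        yields = electron_acceptor_scan(toy_model, no_sulfur_medium, ["s0", "ac"])
        assert yields["ac"] == pytest.approx(yields[None], abs=1e-6)

    def test_ordering_follows_input(self, toy_model, no_sulfur_medium):
        yields = electron_acceptor_scan(toy_model, no_sulfur_medium, ["s0", "ac"])
        assert list(yields) == [None, "s0", "ac"]


class TestGrowthRates:
    def test_doubling_in_one_hour(self):
        curve = GrowthCurve([0.0, 1.0], [0.1, 0.2])
        assert growth_rate(curve, 0.0, 1.0) == pytest.approx(np.log(2.0))

    def test_flat_curve_zero_rate(self):
        curve = GrowthCurve([0.0, 2.0], [0.1, 0.1])
        assert growth_rate(curve, 0.0, 2.0) == 0.0

    def test_equal_times_rejected(self):
        curve = GrowthCurve([0.0, 1.0], [0.1, 0.2])
        with pytest.raises(ModelValidationError):
            growth_rate(curve, 1.0, 1.0)

    def test_noiseless_regression_is_exact(self):
        curve = make_growth_curve(0.5, times=[0, 1, 2, 3, 4])
        assert growth_rate_regression(curve, window=5) == pytest.approx(0.5, abs=1e-12)

    def test_constant_curve_zero_slope(self):
        curve = make_growth_curve(0.0, times=[0, 1, 2, 3])
        assert growth_rate_regression(curve, window=4) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_ten_percent(self):
        curve = make_growth_curve(0.3, noise_sigma=0.02, times=[0, 1, 2, 3, 4, 5], seed=7)
        mu = growth_rate_regression(curve, window=6)
        assert abs(mu - 0.3) / 0.3 <= 0.10

    @pytest.mark.parametrize("window", [3, 7])
    def test_window_outside_four_to_six_rejected(self, window):
        curve = make_growth_curve(0.3, times=list(range(8)))
        with pytest.raises(ModelValidationError):
            growth_rate_regression(curve, window=window)

    def test_curve_invariants(self):
        with pytest.raises(ModelValidationError):
            GrowthCurve([0.0, 0.0], [0.1, 0.2])  # not strictly increasing
        with pytest.raises(ModelValidationError):
            GrowthCurve([0.0, 1.0], [0.1, -0.2])  # nonpositive OD
        with pytest.raises(ModelValidationError):
            GrowthCurve([0.0], [0.1])  # too short
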