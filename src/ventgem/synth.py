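"""Seeded generators for every input class the pipeline consumes.

Three families of fixtures, all pure functions of their parameters and seed:

* a small anaerobic energy-metabolism network built around the motif of a
  sulfur-reducing thermophile: ferredoxin/NAD(P)H redox pools, a
  hydrogen-evolving membrane complex (MBH) pumping sodium, a sulfur-reducing
  membrane complex (MBS) pumping more sodium per electron pair, soluble
  hydrogenase (SH1), the electron-bifurcating transhydrogenase Nfn2, a
  Na⁺-driven ATP synthase, amino-acid and sugar catabolism and a biomass
  reaction — every internal reaction element- and charge-balanced by
  construction;
* gene-family copy-number tables with a planted ancestral reaction set,
  wired through the shipped KO→reaction snapshot;
* exponential OD600 curves with multiplicative lognormal noise.

The toy network encodes the qualitative structure only — sodium pumped per
MBS turnover exceeds MBH's, so sulfur respiration outperforms hydrogen
fermentation — and is not a calibration of any genome-scale model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .growth import AMINO_ACIDS, GrowthCurve, PathwayDefinition
from .medium import MediumCondition
from .model import (
    BiomassComposition,
    Compound,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    build_biomass_reaction,
)

__all__ = [
    "ToyModelParams",
    "make_toy_energy_model",
    "toy_sulfur_medium",
    "toy_complexes",
    "make_auxotrophy_model",
    "auxotrophy_pathways",
    "auxotrophy_medium",
    "DEFAULT_ESSENTIAL_AAS",
    "make_gene_family_table",
    "make_growth_curve",
    "balanced_synthesis",
    "AA_FORMULAS",
]

# --------------------------------------------------------------------------
# shared chemistry
# --------------------------------------------------------------------------

#: Physiological formulas/charges of the 20 canonical amino acids.
AA_FORMULAS: Dict[str, Tuple[Dict[str, int], int]] = {
    "ala": ({"C": 3, "H": 7, "N": 1, "O": 2}, 0),
    "arg": ({"C": 6, "H": 15, "N": 4, "O": 2}, 1),
    "asn": ({"C": 4, "H": 8, "N": 2, "O": 3}, 0),
    "asp": ({"C": 4, "H": 6, "N": 1, "O": 4}, -1),
    "cys": ({"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}, 0),
    "gln": ({"C": 5, "H": 10, "N": 2, "O": 3}, 0),
    "glu": ({"C": 5, "H": 8, "N": 1, "O": 4}, -1),
    "gly": ({"C": 2, "H": 5, "N": 1, "O": 2}, 0),
    "his": ({"C": 6, "H": 9, "N": 3, "O": 2}, 0),
    "ile": ({"C": 6, "H": 13, "N": 1, "O": 2}, 0),
    "leu": ({"C": 6, "H": 13, "N": 1, "O": 2}, 0),
    "lys": ({"C": 6, "H": 15, "N": 2, "O": 2}, 1),
    "met": ({"C": 5, "H": 11, "N": 1, "O": 2, "S": 1}, 0),
    "phe": ({"C": 9, "H": 11, "N": 1, "O": 2}, 0),
    "pro": ({"C": 5, "H": 9, "N": 1, "O": 2}, 0),
    "ser": ({"C": 3, "H": 7, "N": 1, "O": 3}, 0),
    "thr": ({"C": 4, "H": 9, "N": 1, "O": 3}, 0),
    "trp": ({"C": 11, "H": 12, "N": 2, "O": 2}, 0),
    "tyr": ({"C": 9, "H": 11, "N": 1, "O": 3}, 0),
    "val": ({"C": 5, "H": 11, "N": 1, "O": 2}, 0),
}

_CORE_COMPOUNDS = [
    ("glc", "D-glucose", {"C": 6, "H": 12, "O": 6}, 0, "c"),
    ("pyr", "pyruvate", {"C": 3, "H": 3, "O": 3}, -1, "c"),
    ("lac", "L-lactate", {"C": 3, "H": 5, "O": 3}, -1, "c"),
    ("ac", "acetate", {"C": 2, "H": 3, "O": 2}, -1, "c"),
    ("co2", "carbon dioxide", {"C": 1, "O": 2}, 0, "c"),
    ("nh4", "ammonium", {"H": 4, "N": 1}, 1, "c"),
    ("h2o", "water", {"H": 2, "O": 1}, 0, "c"),
    ("h", "proton", {"H": 1}, 1, "c"),
    ("h2", "dihydrogen", {"H": 2}, 0, "c"),
    ("s0", "elemental sulfur", {"S": 1}, 0, "c"),
    ("h2s", "hydrogen sulfide", {"H": 2, "S": 1}, 0, "c"),
    ("fdox", "oxidised ferredoxin", {"Fe": 8, "S": 8}, 0, "c"),
    ("fdred", "reduced ferredoxin", {"Fe": 8, "S": 8}, -1, "c"),
    ("nad", "NAD+", {"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}, -1, "c"),
    ("nadh", "NADH", {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}, -2, "c"),
    ("nadp", "NADP+", {"C": 21, "H": 25, "N": 7, "O": 17, "P": 3}, -3, "c"),
    ("nadph", "NADPH", {"C": 21, "H": 26, "N": 7, "O": 17, "P": 3}, -4, "c"),
    ("atp", "ATP", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, -4, "c"),
    ("adp", "ADP", {"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, -3, "c"),
    ("pi", "phosphate", {"H": 1, "O": 4, "P": 1}, -2, "c"),
    ("na_c", "sodium (cytosol)", {"Na": 1}, 1, "c"),
    ("na_p", "sodium (periplasm)", {"Na": 1}, 1, "p"),
]


def _core_compound_objects(extra: Iterable[Tuple] = ()) -> List[Compound]:
    rows = list(_CORE_COMPOUNDS) + list(extra)
    return [
        Compound(id=cid, name=name, formula=dict(formula), charge=charge, compartment=comp)
        for cid, name, formula, charge, comp in rows
    ]


def balanced_synthesis(
    target_id: str,
    formula: Dict[str, int],
    charge: int,
    product_id: Optional[str] = None,
) -> Dict[str, float]:
    """Element- and charge-balanced lumped synthesis of a C/H/N/O/S compound.

    Builds the target from pyruvate, ammonium and sulfide, using CO2, water
    and protons to close the light-atom books and the ferredoxin pair to
    close the electron count. Coefficients are solved exactly, so the
    resulting reaction passes formula and charge checks by construction.
    """
    for el in formula:
        if el not in ("C", "H", "N", "O", "S"):
            raise ModelValidationError(f"{target_id}: cannot synthesise element {el}")
    c_t, h_t = formula.get("C", 0), formula.get("H", 0)
    n_t, o_t, s_t = formula.get("N", 0), formula.get("O", 0), formula.get("S", 0)
    if c_t < 1:
        raise ModelValidationError(f"{target_id}: carbon-free synthesis target")
    a = math.ceil(c_t / 3)  # pyruvate consumed
    c = c_t - 3 * a  # CO2 consumed (negative: produced)
    w = o_t - 3 * a - 2 * c  # water consumed
    p = h_t - 3 * a - 4 * n_t - 2 * s_t - 2 * w  # protons consumed
    e = -a + n_t + p - charge  # ferredoxin electron pairs consumed
    consumed = {"pyr": a, "nh4": n_t, "h2s": s_t, "co2": c, "h2o": w, "h": p, "fdred": e}
    stoich: Dict[str, float] = {(product_id or target_id): 1.0}
    for cid, amount in consumed.items():
        if amount:
            stoich[cid] = stoich.get(cid, 0.0) - float(amount)
    if e:
        stoich["fdox"] = stoich.get("fdox", 0.0) + float(e)
    return stoich


def _exchange(cid: str, uptake: float = 0.0, secretion: float = 1000.0) -> Reaction:
    return Reaction(
        id=f"EX_{cid}",
        name=f"{cid} exchange",
        stoichiometry={cid: -1.0},
        lower_bound=-uptake,
        upper_bound=secretion,
        evidence="exchange",
    )


# --------------------------------------------------------------------------
# toy energy-metabolism model
# --------------------------------------------------------------------------


@dataclass
class ToyModelParams:
    """Parameters of the toy energy network (all fluxes mmol·gDW⁻¹·h⁻¹)."""

    uptake_aa: float = 10.0
    uptake_glc: float = 1.0
    uptake_s0: float = 20.0
    uptake_h2: float = 10.0
    na_per_mbs: int = 3
    na_per_mbh: int = 1
    na_per_atp: int = 3
    biomass_aa: float = 1.0
    biomass_nadph: float = 2.0
    biomass_atp: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("na_per_mbs", "na_per_mbh", "na_per_atp"):
            if getattr(self, name) <= 0:
                raise ModelValidationError(f"{name} must be a positive integer")
        if self.na_per_mbs < self.na_per_mbh:
            raise ModelValidationError(
                "MBS must pump at least as much sodium per turnover as MBH"
            )
        for name in ("biomass_aa", "biomass_nadph", "biomass_atp"):
            if getattr(self, name) <= 0:
                raise ModelValidationError(f"{name} must be positive")
        for name in ("uptake_aa", "uptake_glc", "uptake_s0", "uptake_h2"):
            if getattr(self, name) < 0:
                raise ModelValidationError(f"{name} must be non-negative")


def make_toy_energy_model(params: Optional[ToyModelParams] = None) -> MetabolicModel:
    """The ≤25-reaction anaerobic energy-metabolism toy model.

    Amino-acid catabolism is represented by alanine (Fd-linked oxidative
    deamination then Fd-linked pyruvate oxidation with substrate-level
    phosphorylation); sugar catabolism by a lumped NAD-linked glycolysis.
    MBS and MBH compete for reduced ferredoxin with different Na⁺ yields;
    SH1 and Nfn2 are the only NADPH sources, and biomass requires NADPH,
    alanine and ATP. Deterministic: identical params give identical models.
    """
    params = params or ToyModelParams()
    p = params
    compounds = _core_compound_objects(
        extra=[("ala", "L-alanine", dict(AA_FORMULAS["ala"][0]), AA_FORMULAS["ala"][1], "c")]
    )
    reactions = [
        Reaction(
            id="AADH",
            name="alanine oxidative deamination (Fd)",
            stoichiometry={"ala": -1, "h2o": -1, "fdox": -2, "pyr": 1, "nh4": 1, "fdred": 2, "h": 2},
            lower_bound=0.0,
            gpr="aadh1",
        ),
        Reaction(
            id="GLYC",
            name="glycolysis (lumped)",
            stoichiometry={
                "glc": -1, "nad": -2, "adp": -2, "pi": -2,
                "pyr": 2, "nadh": 2, "atp": 2, "h2o": 2, "h": 2,
            },
            lower_bound=0.0,
            gpr="gap1 and pyk1",
        ),
        Reaction(
            id="PFOR",
            name="pyruvate:ferredoxin oxidoreductase + acetate kinase (lumped)",
            stoichiometry={
                "pyr": -1, "fdox": -2, "adp": -1, "pi": -1,
                "ac": 1, "co2": 1, "atp": 1, "fdred": 2, "h": 1,
            },
            lower_bound=0.0,
            gpr="por1",
        ),
        Reaction(
            id="LDH",
            name="lactate dehydrogenase",
            stoichiometry={"pyr": -1, "nadh": -1, "h": -1, "lac": 1, "nad": 1},
            lower_bound=0.0,
            gpr="ldh1",
        ),
        Reaction(
            id="MBH",
            name="membrane-bound hydrogenase (H2-evolving, Na+ pumping)",
            stoichiometry={
                "fdred": -2, "h": -2, "na_c": -float(p.na_per_mbh),
                "fdox": 2, "h2": 1, "na_p": float(p.na_per_mbh),
            },
            lower_bound=0.0,
            gpr="mbh",
        ),
        Reaction(
            id="MBS",
            name="membrane-bound sulfur reductase (S0 -> H2S, Na+ pumping)",
            stoichiometry={
                "fdred": -2, "h": -2, "s0": -1, "na_c": -float(p.na_per_mbs),
                "fdox": 2, "h2s": 1, "na_p": float(p.na_per_mbs),
            },
            lower_bound=0.0,
            gpr="mbs",
        ),
        Reaction(
            id="SH1",
            name="soluble hydrogenase I (H2 + NADP+ <-> NADPH)",
            stoichiometry={"h2": -1, "nadp": -1, "nadph": 1, "h": 1},
            gpr="sh1",
        ),
        Reaction(
            id="NFN2",
            name="NADP-dependent ferredoxin oxidoreductase II (bifurcating)",
            stoichiometry={
                "nadh": -1, "fdred": -2, "nadp": -2, "h": -1,
                "nad": 1, "fdox": 2, "nadph": 2,
            },
            gpr="nfn2",
        ),
        Reaction(
            id="ATPS",
            name="Na+-driven ATP synthase",
            stoichiometry={
                "adp": -1, "pi": -1, "h": -1, "na_p": -float(p.na_per_atp),
                "atp": 1, "h2o": 1, "na_c": float(p.na_per_atp),
            },
            lower_bound=0.0,
            gpr="atps",
        ),
    ]
    exchanges = [
        _exchange("ala", p.uptake_aa),
        _exchange("glc", p.uptake_glc),
        _exchange("s0", p.uptake_s0),
        _exchange("h2", p.uptake_h2),
        _exchange("ac"),
        _exchange("lac"),
        _exchange("co2"),
        _exchange("nh4"),
        _exchange("h2s"),
        _exchange("h2o", 1000.0),
        _exchange("h", 1000.0),
        _exchange("pi", 1000.0),
        _exchange("biomass"),
    ]
    model = MetabolicModel.from_lists(
        compounds + [Compound(id="biomass", name="biomass", formula=None, charge=None)],
        reactions + exchanges,
        name="toy_energy_model",
        metadata={"generator": "make_toy_energy_model", "seed": str(p.seed)},
    )
    build_biomass_reaction(
        BiomassComposition(
            building_blocks={"ala": p.biomass_aa, "nadph": p.biomass_nadph},
            energy_cost=p.biomass_atp,
        ),
        model,
        add_to_model=True,
    )
    model.validate()
    return model


def toy_sulfur_medium(params: Optional[ToyModelParams] = None, sulfur: bool = True) -> MediumCondition:
    """The toy model's culture condition, with or without elemental sulfur."""
    p = params or ToyModelParams()
    bounds = {
        "EX_ala": (p.uptake_aa, 1000.0),
        "EX_glc": (p.uptake_glc, 1000.0),
        "EX_s0": (p.uptake_s0 if sulfur else 0.0, 1000.0),
        "EX_h2": (p.uptake_h2, 1000.0),
        "EX_h2o": (1000.0, 1000.0),
        "EX_h": (1000.0, 1000.0),
        "EX_pi": (1000.0, 1000.0),
    }
    return MediumCondition("sulfur" if sulfur else "no_sulfur", bounds, closed_by_default=True)


def toy_complexes() -> Dict[str, Set[str]]:
    """The archaea-derived energy complexes of the toy model, by gene set."""
    return {"MBS": {"mbs"}, "Nfn2": {"nfn2"}, "SH1": {"sh1"}}


# --------------------------------------------------------------------------
# 20-amino-acid auxotrophy model
# --------------------------------------------------------------------------

#: The 11 amino acids planted as auxotrophies by default, matching the
#: essentiality pattern observed experimentally in the modelled organism.
DEFAULT_ESSENTIAL_AAS = frozenset(
    {"arg", "cys", "his", "leu", "lys", "met", "phe", "pro", "thr", "trp", "tyr"}
)

_PATHWAY_STEPS = 3


def auxotrophy_pathways() -> List[PathwayDefinition]:
    """Whole-pathway definitions (3 steps per amino acid) for the aux model."""
    return [
        PathwayDefinition(
            amino_acid=aa,
            reaction_ids=frozenset(f"SYN_{aa}_{i}" for i in range(1, _PATHWAY_STEPS + 1)),
        )
        for aa in AMINO_ACIDS
    ]


def make_auxotrophy_model(
    essential: Iterable[str] = DEFAULT_ESSENTIAL_AAS,
    biomass_aa: float = 0.1,
    biomass_atp: float = 5.0,
) -> MetabolicModel:
    """A 20-amino-acid model with planted auxotrophies.

    Biomass consumes every amino acid. Non-essential amino acids carry their
    complete 3-step biosynthesis pathway (a balanced lumped synthesis from
    pyruvate/ammonium/sulfide followed by two isomerisations); planted
    essential ones retain only the middle step, so both the genomic
    ≥50%-missing rule and a leave-one-out FBA scan call exactly them.
    """
    essential = set(essential)
    unknown = essential - set(AMINO_ACIDS)
    if unknown:
        raise ModelValidationError(f"unknown amino acids: {sorted(unknown)}")

    compounds = _core_compound_objects(
        extra=[(aa, aa, dict(AA_FORMULAS[aa][0]), AA_FORMULAS[aa][1], "c") for aa in AMINO_ACIDS]
    )
    reactions: List[Reaction] = [
        Reaction(
            id="GLYC",
            name="glycolysis (lumped)",
            stoichiometry={
                "glc": -1, "nad": -2, "adp": -2, "pi": -2,
                "pyr": 2, "nadh": 2, "atp": 2, "h2o": 2, "h": 2,
            },
            lower_bound=0.0,
            gpr="gap1 and pyk1",
        ),
        Reaction(
            id="PFOR",
            name="pyruvate oxidation (lumped)",
            stoichiometry={
                "pyr": -1, "fdox": -2, "adp": -1, "pi": -1,
                "ac": 1, "co2": 1, "atp": 1, "fdred": 2, "h": 1,
            },
            lower_bound=0.0,
            gpr="por1",
        ),
        Reaction(
            id="LDH",
            name="lactate dehydrogenase",
            stoichiometry={"pyr": -1, "nadh": -1, "h": -1, "lac": 1, "nad": 1},
            lower_bound=0.0,
            gpr="ldh1",
        ),
        Reaction(
            id="HYD",
            name="soluble Fd hydrogenase",
            stoichiometry={"fdred": -2, "h": -2, "fdox": 2, "h2": 1},
            lower_bound=0.0,
            gpr="hyd1",
        ),
        Reaction(
            id="HYDN",
            name="NADH-dependent hydrogenase",
            stoichiometry={"nadh": -1, "h": -1, "nad": 1, "h2": 1},
            lower_bound=0.0,
            gpr="hyd2",
        ),
    ]

    for aa in AMINO_ACIDS:
        formula, charge = AA_FORMULAS[aa]
        pre1, pre2 = f"pre1_{aa}", f"pre2_{aa}"
        compounds += [
            Compound(id=pre1, name=f"{aa} precursor 1", formula=dict(formula), charge=charge),
            Compound(id=pre2, name=f"{aa} precursor 2", formula=dict(formula), charge=charge),
        ]
        steps = [
            Reaction(
                id=f"SYN_{aa}_1",
                name=f"{aa} synthesis step 1",
                stoichiometry=balanced_synthesis(aa, formula, charge, product_id=pre1),
                lower_bound=0.0,
                gpr=f"syn_{aa}_1",
            ),
            Reaction(
                id=f"SYN_{aa}_2",
                name=f"{aa} synthesis step 2",
                stoichiometry={pre1: -1.0, pre2: 1.0},
                lower_bound=0.0,
                gpr=f"syn_{aa}_2",
            ),
            Reaction(
                id=f"SYN_{aa}_3",
                name=f"{aa} synthesis step 3",
                stoichiometry={pre2: -1.0, aa: 1.0},
                lower_bound=0.0,
                gpr=f"syn_{aa}_3",
            ),
        ]
        if aa in essential:
            reactions.append(steps[1])  # 1 of 3 steps present: >= 50% missing
        else:
            reactions.extend(steps)

    exchanges = [_exchange(aa, 1.0) for aa in AMINO_ACIDS] + [
        _exchange("glc", 10.0),
        _exchange("nh4", 10.0),
        _exchange("h2s", 2.0),
        _exchange("ac"),
        _exchange("lac"),
        _exchange("co2"),
        _exchange("h2"),
        _exchange("h2o", 1000.0),
        _exchange("h", 1000.0),
        _exchange("pi", 1000.0),
        _exchange("biomass"),
    ]
    model = MetabolicModel.from_lists(
        compounds + [Compound(id="biomass", name="biomass", formula=None, charge=None)],
        reactions + exchanges,
        name="auxotrophy_model",
        metadata={"generator": "make_auxotrophy_model"},
    )
    build_biomass_reaction(
        BiomassComposition(
            building_blocks={aa: biomass_aa for aa in AMINO_ACIDS},
            energy_cost=biomass_atp,
        ),
        model,
        add_to_model=True,
    )
    model.validate()
    return model


def auxotrophy_medium() -> MediumCondition:
    """Base condition for the auxotrophy model (amino acids set by the scan)."""
    return MediumCondition(
        "aux_base",
        {
            "EX_glc": (10.0, 1000.0),
            "EX_nh4": (10.0, 1000.0),
            "EX_h2s": (2.0, 1000.0),
            "EX_h2o": (1000.0, 1000.0),
            "EX_h": (1000.0, 1000.0),
            "EX_pi": (1000.0, 1000.0),
        },
        closed_by_default=True,
    )


# --------------------------------------------------------------------------
# gene-family tables and growth curves
# --------------------------------------------------------------------------


def make_gene_family_table(
    truth: Sequence[str],
    n_noise_families: int = 0,
    noise_copy_range: Tuple[float, float] = (0.01, 0.29),
    seed: int = 0,
    node: str = "CCTB",
    copy_threshold: float = 0.3,
):
    """ALE-style family table with a planted ancestral reaction set.

    Families backing ``truth`` reactions get copy number 1.0 and the KO term
    that maps to their reaction in the shipped KO→reaction snapshot; noise
    families get unmapped KO terms and copy numbers drawn uniformly from
    ``noise_copy_range``, which must exclude the filter threshold.
    """
    from .ancestor import GeneFamilyRecord, load_ko_reaction_db

    lo, hi = noise_copy_range
    if lo > hi or (lo <= copy_threshold <= hi):
        raise ModelValidationError(
            f"noise copy range {noise_copy_range} must exclude the threshold {copy_threshold}"
        )
    ko_by_reaction: Dict[str, str] = {}
    reactions_by_ko, _ = load_ko_reaction_db()
    for ko, rxns in reactions_by_ko.items():
        for r in rxns:
            ko_by_reaction.setdefault(r.id, ko)
    missing = [rid for rid in truth if rid not in ko_by_reaction]
    if missing:
        raise ModelValidationError(
            f"truth reactions absent from the KO snapshot: {missing}"
        )

    rng = np.random.default_rng(seed)
    records = [
        GeneFamilyRecord(
            family_id=f"FAM_{rid}",
            ko_terms=frozenset({ko_by_reaction[rid]}),
            copy_number=1.0,
            node=node,
        )
        for rid in truth
    ]
    for i in range(n_noise_families):
        records.append(
            GeneFamilyRecord(
                family_id=f"NOISE_{i:04d}",
                ko_terms=frozenset({f"K9{i:04d}"}),
                copy_number=float(rng.uniform(lo, hi)),
                node=node,
            )
        )
    return records


def make_growth_curve(
    mu: float,
    od0: float = 0.02,
    times: Sequence[float] = (0, 1, 2, 3, 4, 5),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential OD600 curve with multiplicative lognormal noise.

    ``OD(t) = od0 · exp(mu·t) · exp(ε_t)`` with ``ε_t ~ N(0, σ²)``.
    """
    if od0 <= 0:
        raise ModelValidationError("initial OD must be positive")
    if noise_sigma < 0:
        raise ModelValidationError("noise sigma must be non-negative")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sigma, size=len(times)) if noise_sigma > 0 else np.zeros(len(times))
    od = od0 * np.exp(mu * times) * np.exp(eps)
    return GrowthCurve(times=times, od600=od)
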