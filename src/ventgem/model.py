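"""Domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a bag of :class:`Compound` and :class:`Reaction`
objects with one designated biomass objective. Conventions:

* stoichiometric coefficients are signed floats — negative consumes,
  positive produces;
* exchange reactions touch exactly one compound and cross the system
  boundary; uptake is a negative flux, so a maximum uptake ``U`` is encoded
  as ``lower_bound = -U``;
* an unknown chemical formula is ``None``, distinct from ``{}`` (a species
  genuinely free of tracked elements); an unknown charge is ``None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional

from .gpr import GPR, format_gpr, gpr_genes, parse_gpr

__all__ = [
    "Compound",
    "Reaction",
    "MetabolicModel",
    "BiomassComposition",
    "ModelValidationError",
    "build_biomass_reaction",
    "parse_formula",
    "format_formula",
    "DEFAULT_BOUND",
    "EVIDENCE_TAGS",
    "BIOMASS_COMPOUND_ID",
]

#: Default magnitude used for an effectively unconstrained flux bound.
DEFAULT_BOUND = 1000.0

EVIDENCE_TAGS = ("ortholog_mapping", "literature", "gapfilled", "biomass", "exchange")

#: Pseudo-compound produced by biomass reactions (formula unknown by design).
BIOMASS_COMPOUND_ID = "biomass"

#: Redox cofactors consumed by anabolism; the biomass builder returns the
#: oxidised partner one-for-one so the pool closes at steady state.
REDOX_PAIRS = {"nadph": "nadp", "nadh": "nad", "fdred": "fdox"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """A model or model fragment violates a structural invariant."""


def parse_formula(text: Optional[str]) -> Optional[Dict[str, int]]:
    """Parse ``C6H12O6``-style formulas into an element-count map.

    Empty string / ``None`` / ``?`` mean unknown. The literal ``-`` denotes a
    known, element-free formula (used for abstract bookkeeping species).
    """
    if text is None:
        return None
    text = text.strip()
    if text in ("", "?"):
        return None
    if text == "-":
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ModelValidationError(f"malformed formula {text!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ModelValidationError(f"malformed formula {text!r}")
    return counts


def format_formula(formula: Optional[Dict[str, int]]) -> str:
    if formula is None:
        return ""
    if not formula:
        return "-"
    # Hill-ish ordering: C, H, then alphabetical.
    def key(el: str):
        return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

    parts = []
    for el in sorted(formula, key=key):
        n = formula[el]
        if n < 0:
            raise ModelValidationError(f"negative element count for {el}")
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


@dataclass
class Compound:
    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("compound id must be non-empty")
        if self.formula is not None:
            for el, n in self.formula.items():
                if not isinstance(n, int) or n < 0:
                    raise ModelValidationError(
                        f"compound {self.id}: element count {el}={n} must be a "
                        "non-negative integer"
                    )


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = None
    evidence: Optional[str] = None
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for cid, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id}: zero coefficient for {cid}"
                )
        if self.evidence is not None and self.evidence not in EVIDENCE_TAGS:
            raise ModelValidationError(
                f"reaction {self.id}: unknown evidence tag {self.evidence!r}"
            )
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions touching exactly one compound."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> frozenset:
        return gpr_genes(self.gpr)

    @property
    def gpr_string(self) -> str:
        return format_gpr(self.gpr)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    compounds: Dict[str, Compound] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: Optional[str] = None
    name: str = ""
    metadata: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_lists(
        cls,
        compounds: Iterable[Compound],
        reactions: Iterable[Reaction],
        biomass_reaction_id: Optional[str] = None,
        name: str = "",
        metadata: Optional[Dict[str, str]] = None,
    ) -> "MetabolicModel":
        cmap: Dict[str, Compound] = {}
        for c in compounds:
            if c.id in cmap:
                raise ModelValidationError(f"duplicate compound id {c.id!r}")
            cmap[c.id] = c
        rmap: Dict[str, Reaction] = {}
        for r in reactions:
            if r.id in rmap:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            rmap[r.id] = r
        model = cls(
            compounds=cmap,
            reactions=rmap,
            biomass_reaction_id=biomass_reaction_id,
            name=name,
            metadata=dict(metadata or {}),
        )
        model.validate()
        return model

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for r in self.reactions.values():
            out |= r.genes
        return frozenset(out)

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def exchange_for(self, compound_id: str) -> Optional[Reaction]:
        """The exchange reaction moving ``compound_id`` over the boundary."""
        for r in self.reactions.values():
            if r.is_exchange and compound_id in r.stoichiometry:
                return r
        return None

    def validate(self) -> None:
        for r in self.reactions.values():
            for cid in r.stoichiometry:
                if cid not in self.compounds:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown compound {cid!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: inverted bounds"
                )
        if self.biomass_reaction_id is not None:
            if self.biomass_reaction_id not in self.reactions:
                raise ModelValidationError(
                    f"biomass reaction {self.biomass_reaction_id!r} not in model"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            compounds=dict(self.compounds),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            name=self.name,
            metadata=dict(self.metadata),
        )

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        for cid in reaction.stoichiometry:
            if cid not in self.compounds:
                raise ModelValidationError(
                    f"reaction {reaction.id} references unknown compound {cid!r}"
                )
        self.reactions[reaction.id] = reaction

    def add_compound(self, compound: Compound) -> None:
        if compound.id in self.compounds:
            raise ModelValidationError(f"duplicate compound id {compound.id!r}")
        self.compounds[compound.id] = compound


@dataclass
class BiomassComposition:
    """Dry-weight composition driving the biomass pseudo-reaction.

    ``macromolecule_fractions`` are mass fractions of cell dry weight for the
    DNA/RNA/protein/other pools (the three informational polymers account for
    roughly 0.8 of dry weight in the organisms modelled here);
    ``building_blocks`` maps compound ids to mmol required per gram dry
    weight; ``energy_cost`` is the growth-associated maintenance in mmol ATP
    hydrolysed per gram dry weight.
    """

    macromolecule_fractions: Dict[str, float] = field(
        default_factory=lambda: {"protein": 0.55, "RNA": 0.205, "DNA": 0.045, "other": 0.2}
    )
    building_blocks: Dict[str, float] = field(default_factory=dict)
    energy_cost: float = 0.0

    def __post_init__(self):
        total = 0.0
        for key, frac in self.macromolecule_fractions.items():
            if frac < 0:
                raise ModelValidationError(f"negative mass fraction for {key}")
            total += frac
        if total > 1.0 + 1e-9:
            raise ModelValidationError(f"mass fractions sum to {total:.3f} > 1")
        for cid, coef in self.building_blocks.items():
            if coef < 0:
                raise ModelValidationError(f"negative building-block coefficient for {cid}")
        if self.energy_cost < 0:
            raise ModelValidationError("negative biomass energy cost")

    @property
    def polymer_fraction(self) -> float:
        """DNA + RNA + protein mass fraction of dry weight."""
        return sum(
            self.macromolecule_fractions.get(k, 0.0) for k in ("DNA", "RNA", "protein")
        )


def build_biomass_reaction(
    composition: BiomassComposition,
    model: MetabolicModel,
    reaction_id: str = "BIOMASS",
    add_to_model: bool = False,
) -> Reaction:
    """Assemble the irreversible biomass pseudo-reaction.

    Building blocks are consumed at their mmol/gDW coefficients; the ATP
    maintenance cost is charged as ``ATP + H2O -> ADP + Pi + H+``; redox
    cofactors among the building blocks return their oxidised partner; one
    unit of the ``biomass`` pseudo-compound is produced. The result carries
    ``evidence='biomass'`` and is exempt from balance checking (the
    pseudo-compound has no formula by design).
    """
    missing = [cid for cid in composition.building_blocks if cid not in model.compounds]
    g = composition.energy_cost
    if g > 0:
        missing += [c for c in ("atp", "h2o", "adp", "pi", "h") if c not in model.compounds]
    if missing:
        raise ModelValidationError(
            "biomass building blocks absent from model: " + ", ".join(sorted(set(missing)))
        )

    stoich: Dict[str, float] = {}
    for cid, coef in composition.building_blocks.items():
        if coef == 0:
            continue
        stoich[cid] = stoich.get(cid, 0.0) - coef
        partner = REDOX_PAIRS.get(cid)
        if partner is not None and partner in model.compounds:
            stoich[partner] = stoich.get(partner, 0.0) + coef
    if g > 0:
        stoich["atp"] = stoich.get("atp", 0.0) - g
        stoich["h2o"] = stoich.get("h2o", 0.0) - g
        stoich["adp"] = stoich.get("adp", 0.0) + g
        stoich["pi"] = stoich.get("pi", 0.0) + g
        stoich["h"] = stoich.get("h", 0.0) + g
    stoich[BIOMASS_COMPOUND_ID] = stoich.get(BIOMASS_COMPOUND_ID, 0.0) + 1.0
    stoich = {cid: coef for cid, coef in stoich.items() if coef != 0.0}

    reaction = Reaction(
        id=reaction_id,
        name="biomass assembly",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        evidence="biomass",
    )
    if add_to_model:
        if BIOMASS_COMPOUND_ID not in model.compounds:
            model.add_compound(
                Compound(id=BIOMASS_COMPOUND_ID, name="biomass", formula=None, charge=None)
            )
        model.add_reaction(reaction)
        model.biomass_reaction_id = reaction_id
    return reaction
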