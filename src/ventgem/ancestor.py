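"""Ancestral-model assembly from gene-family copy-number tables.

The input is reconciliation output (one row per gene family with KO terms
and the average copy number inferred at a named internal node of the
species tree — reconciliation itself is upstream and not reproduced here).
Families passing the copy-number filter are mapped to reactions through a
frozen offline KO→reaction snapshot, a template biomass is attached, the
network is gap-filled to biomass producibility, and a hydrothermal-vent
medium supplies H2, CO2, elemental sulfur, ammonium and phosphate.

Amino acids whose biosynthesis pathway is at least half missing from the
assembled network are treated as environmentally supplied: their uptake
exchanges are granted at a 1 mM-equivalent bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from .gapfill import GapfillProblem, find_blocked_targets, gapfill
from .gpr import parse_gpr
from .growth import PathwayDefinition, essential_aas_from_genome
from .io.tables import parse_equation
from .medium import MediumCondition, apply_medium
from .model import (
    BiomassComposition,
    Compound,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    build_biomass_reaction,
    parse_formula,
)

__all__ = [
    "GeneFamilyRecord",
    "AncestorConfig",
    "filter_families",
    "map_kos_to_reactions",
    "assemble_ancestor_model",
    "vent_medium",
    "load_ko_reaction_db",
    "load_biomass_template",
    "read_family_table",
    "write_family_table",
]

DEFAULT_NODE = "CCTB"
DEFAULT_COPY_THRESHOLD = 0.3


@dataclass(frozen=True)
class GeneFamilyRecord:
    """One gene family at one internal tree node (reconciliation output)."""

    family_id: str
    ko_terms: frozenset
    copy_number: float
    node: str = DEFAULT_NODE

    def __post_init__(self):
        if self.copy_number < 0:
            raise ModelValidationError(
                f"family {self.family_id}: negative copy number"
            )


@dataclass
class AncestorConfig:
    copy_threshold: float = DEFAULT_COPY_THRESHOLD
    node: str = DEFAULT_NODE
    biomass_template: Optional[BiomassComposition] = None
    medium: Optional[MediumCondition] = None

    def __post_init__(self):
        if self.copy_threshold < 0:
            raise ModelValidationError("copy threshold must be non-negative")


def filter_families(
    table: Iterable[GeneFamilyRecord], config: Optional[AncestorConfig] = None
) -> List[GeneFamilyRecord]:
    """Families at the configured node with copy number strictly above threshold.

    The inequality is strict — a family sitting exactly on the threshold is
    excluded. Order-stable and idempotent.
    """
    config = config or AncestorConfig()
    rows = list(table)
    nodes = {r.node for r in rows}
    if rows and config.node not in nodes:
        raise ModelValidationError(
            f"node {config.node!r} absent from table (nodes seen: {sorted(nodes)})"
        )
    return [
        r for r in rows if r.node == config.node and r.copy_number > config.copy_threshold
    ]


# --------------------------------------------------------------------------
# KO→reaction snapshot
# --------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("ventgem").joinpath("data", name)


def load_ko_reaction_db(
    reactions_path=None, compounds_path=None
) -> Tuple[Dict[str, List[Reaction]], Dict[str, Compound]]:
    """Load the offline KO→reaction snapshot and its compound registry.

    Returns ``(reactions_by_ko, compounds_by_id)``. The shipped default is a
    small synthetic snapshot covering the toy energy network's chemistry.
    """
    rpath = reactions_path or _data_path("ko_reactions.tsv")
    cpath = compounds_path or _data_path("ko_compounds.tsv")
    rdf = pd.read_csv(rpath, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cdf = pd.read_csv(cpath, sep="\t", comment="#", dtype=str, keep_default_na=False)

    compounds = {
        row.id: Compound(
            id=row.id,
            name=row.name,
            formula=parse_formula(row.formula),
            charge=None if row.charge == "" else int(row.charge),
            compartment=row.compartment or "c",
        )
        for row in cdf.itertuples()
    }
    by_ko: Dict[str, List[Reaction]] = {}
    for row in rdf.itertuples():
        reversible = row.reversibility.strip().lower() == "reversible"
        reaction = Reaction(
            id=row.reaction_id,
            name=getattr(row, "name", row.reaction_id),
            stoichiometry=parse_equation(row.equation),
            lower_bound=-1000.0 if reversible else 0.0,
            upper_bound=1000.0,
        )
        by_ko.setdefault(row.ko, []).append(reaction)
    return by_ko, compounds


def map_kos_to_reactions(
    families: Iterable[GeneFamilyRecord],
    ko_reaction_db: Optional[Dict[str, List[Reaction]]] = None,
) -> Tuple[List[Reaction], List[str]]:
    """Union of reactions mapped by any retained KO term.

    Duplicate reactions are merged by id and their GPR becomes an OR over
    all contributing family ids (``evidence='ortholog_mapping'``). KO terms
    absent from the snapshot are returned in the unmapped report rather
    than raising.
    """
    if ko_reaction_db is None:
        ko_reaction_db, _ = load_ko_reaction_db()
    merged: Dict[str, Reaction] = {}
    contributors: Dict[str, Set[str]] = {}
    unmapped: List[str] = []
    for record in families:
        for ko in sorted(record.ko_terms):
            hits = ko_reaction_db.get(ko)
            if not hits:
                unmapped.append(ko)
                continue
            for reaction in hits:
                merged.setdefault(reaction.id, reaction.copy())
                contributors.setdefault(reaction.id, set()).add(record.family_id)
    out: List[Reaction] = []
    for rid in sorted(merged):
        reaction = merged[rid]
        reaction.gpr = parse_gpr(" or ".join(sorted(contributors[rid])))
        reaction.evidence = "ortholog_mapping"
        out.append(reaction)
    return out, sorted(set(unmapped))


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------


def load_biomass_template(path=None) -> BiomassComposition:
    """The shipped ancestor biomass template (DNA+RNA+protein ≈ 0.8 of DW)."""
    with open(path or _data_path("biomass_template.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return BiomassComposition(
        macromolecule_fractions={k: float(v) for k, v in raw["macromolecule_fractions"].items()},
        building_blocks={k: float(v) for k, v in raw["building_blocks"].items()},
        energy_cost=float(raw["energy_cost"]),
    )


def vent_medium(overrides: Optional[Dict[str, Tuple[float, float]]] = None) -> MediumCondition:
    """The default hydrothermal-vent condition (H2/CO2/S0/NH4/Pi uptake,
    organic carbon from the vent food web, sulfide and fermentation products
    secreted), merged with any overrides."""
    df = pd.read_csv(_data_path("vent_medium.tsv"), sep="\t", comment="#")
    bounds = {
        str(row.exchange_id): (float(row.max_uptake), float(row.max_secretion))
        for row in df.itertuples()
    }
    bounds.update(overrides or {})
    return MediumCondition("vent", bounds, closed_by_default=True)


def assemble_ancestor_model(
    reactions: Sequence[Reaction],
    config: Optional[AncestorConfig] = None,
    compound_db: Optional[Dict[str, Compound]] = None,
    universal: Optional[Sequence[Reaction]] = None,
    pathways: Optional[Sequence[PathwayDefinition]] = None,
    aa_uptake: float = 1.0,
) -> MetabolicModel:
    """Build a runnable ancestor model from KO-mapped reactions.

    Adds the mapped reactions, an exchange reaction per medium compound
    (medium bounds applied, so the returned model carries its culture
    condition in its own bounds), the template biomass, and — when a
    pathway table is given — uptake grants for amino acids whose pathway is
    at least half missing. When a universal database is supplied the model
    is gap-filled until every biomass building block is producible.
    """
    if not reactions:
        raise ModelValidationError("no reactions to assemble")
    config = config or AncestorConfig()
    if compound_db is None:
        _, compound_db = load_ko_reaction_db()
    medium = config.medium if config.medium is not None else vent_medium()
    template = config.biomass_template or load_biomass_template()

    compounds: Dict[str, Compound] = {}

    def ensure_compound(cid: str):
        if cid not in compounds:
            compounds[cid] = compound_db.get(cid, Compound(id=cid))

    for r in reactions:
        for cid in r.stoichiometry:
            ensure_compound(cid)
    for cid in template.building_blocks:
        ensure_compound(cid)
    for cid in ("atp", "adp", "pi", "h", "h2o", "biomass"):
        ensure_compound(cid)

    model_reactions: Dict[str, Reaction] = {r.id: r.copy() for r in reactions}
    for ex_id in medium.exchange_bounds:
        if not ex_id.startswith("EX_"):
            raise ModelValidationError(
                f"medium entry {ex_id!r} is not an EX_-prefixed exchange id"
            )
        cid = ex_id[3:]
        ensure_compound(cid)
        if ex_id not in model_reactions:
            model_reactions[ex_id] = Reaction(
                id=ex_id,
                name=f"{cid} exchange",
                stoichiometry={cid: -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                evidence="exchange",
            )

    model = MetabolicModel.from_lists(
        compounds.values(),
        model_reactions.values(),
        name=f"ancestor_{config.node}",
        metadata={"node": config.node, "copy_threshold": str(config.copy_threshold)},
    )
    build_biomass_reaction(template, model, add_to_model=True)

    # Environmental amino-acid grants per the half-missing-pathway rule.
    if pathways:
        for aa in sorted(essential_aas_from_genome(model, pathways)):
            if aa not in model.compounds:
                continue
            ex_id = f"EX_{aa}"
            if ex_id not in model.reactions:
                model.add_reaction(
                    Reaction(
                        id=ex_id,
                        name=f"{aa} exchange (essential amino-acid grant)",
                        stoichiometry={aa: -1.0},
                        lower_bound=-aa_uptake,
                        upper_bound=1000.0,
                        evidence="exchange",
                    )
                )
            medium = medium.with_bounds(
                ex_id, aa_uptake, medium.exchange_bounds.get(ex_id, (0.0, 1000.0))[1]
            )

    model = apply_medium(model, medium)

    targets = [cid for cid in template.building_blocks if cid in model.compounds]
    if universal:
        blocked = find_blocked_targets(model, None, targets)
        if blocked:
            problem = GapfillProblem(
                draft=model, universal=list(universal), targets=targets, medium=None
            )
            added = gapfill(problem)
            by_id = {r.id: r for r in universal}
            for rid in added:
                reaction = by_id[rid].copy()
                reaction.evidence = "gapfilled"
                for cid in reaction.stoichiometry:
                    if cid not in model.compounds:
                        model.add_compound(compound_db.get(cid, Compound(id=cid)))
                model.add_reaction(reaction)
    model.validate()
    return model


# --------------------------------------------------------------------------
# family-table I/O
# --------------------------------------------------------------------------


def read_family_table(path) -> List[GeneFamilyRecord]:
    """Read a TSV with columns family_id, node, copy_number, ko_terms
    (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"family_id", "node", "copy_number", "ko_terms"}
    if not required.issubset(df.columns):
        raise ModelValidationError(f"family table needs columns {sorted(required)}")
    return [
        GeneFamilyRecord(
            family_id=row.family_id,
            ko_terms=frozenset(k for k in row.ko_terms.split(";") if k),
            copy_number=float(row.copy_number),
            node=row.node,
        )
        for row in df.itertuples()
    ]


def write_family_table(records: Iterable[GeneFamilyRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "node": r.node,
                "copy_number": r.copy_number,
                "ko_terms": ";".join(sorted(r.ko_terms)),
            }
            for r in records
        ],
        columns=["family_id", "node", "copy_number", "ko_terms"],
    )
    df.to_csv(path, sep="\t", index=False)
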