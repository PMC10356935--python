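"""Human-editable YAML+TSV model dialect.

Layout mirrors how curated models are distributed as spreadsheets:

* ``model.yaml`` — name, biomass reaction id, file references, metadata;
* ``compounds.tsv`` — id, name, formula, charge, compartment;
* ``reactions.tsv`` — id, name, equation, lower, upper, gpr, evidence.

Equations use the common text form ``0.5 a + b => c`` / ``a <=> b``; the
arrow is cosmetic (reversibility lives in the bounds columns) but is written
consistently with the bounds.
"""

from __future__ import annotations

import math
import os
import re
from typing import Dict, Tuple

import pandas as pd
import yaml

from ..model import (
    Compound,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    format_formula,
    parse_formula,
)

__all__ = ["read_yaml_tsv", "write_yaml_tsv", "parse_equation", "format_equation"]

_ARROWS = ("<=>", "=>", "<-", "->", "<->")


def parse_equation(text: str) -> Dict[str, float]:
    """Parse ``a + 2 b => c`` into a signed stoichiometry map."""
    for arrow in ("<=>", "<->", "=>", "->"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ModelValidationError(f"equation {text!r} has no arrow")
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelValidationError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, cid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelValidationError(
                        f"bad coefficient {parts[0]!r} in equation {text!r}"
                    ) from exc
                cid = parts[1]
            else:
                raise ModelValidationError(f"bad term {term!r} in equation {text!r}")
            stoich[cid] = stoich.get(cid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {cid: c for cid, c in stoich.items() if c != 0.0}


def _coef_str(coef: float) -> str:
    if coef == int(coef):
        return str(int(coef))
    return repr(coef)


def format_equation(stoich: Dict[str, float], reversible: bool = False) -> str:
    lhs = [(cid, -c) for cid, c in sorted(stoich.items()) if c < 0]
    rhs = [(cid, c) for cid, c in sorted(stoich.items()) if c > 0]

    def side(terms):
        return " + ".join(
            cid if coef == 1 else f"{_coef_str(coef)} {cid}" for cid, coef in terms
        )

    arrow = "<=>" if reversible else "=>"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def _model_dir(path) -> Tuple[str, str]:
    path = str(path)
    if os.path.isdir(path):
        return path, os.path.join(path, "model.yaml")
    return os.path.dirname(path) or ".", path


def read_yaml_tsv(path) -> MetabolicModel:
    base, yaml_path = _model_dir(path)
    with open(yaml_path) as fh:
        header = yaml.safe_load(fh) or {}
    compounds_file = os.path.join(base, header.get("compounds", "compounds.tsv"))
    reactions_file = os.path.join(base, header.get("reactions", "reactions.tsv"))

    compounds = []
    cdf = pd.read_csv(compounds_file, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for row in cdf.itertuples():
        try:
            charge = None if row.charge == "" else int(row.charge)
        except ValueError as exc:
            raise ModelValidationError(
                f"compound {row.id}: bad charge {row.charge!r}"
            ) from exc
        compounds.append(
            Compound(
                id=row.id,
                name=getattr(row, "name", ""),
                formula=parse_formula(row.formula),
                charge=charge,
                compartment=getattr(row, "compartment", "c") or "c",
            )
        )

    reactions = []
    rdf = pd.read_csv(reactions_file, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for row in rdf.itertuples():
        try:
            lower = float(row.lower)
            upper = float(row.upper)
        except ValueError as exc:
            raise ModelValidationError(f"reaction {row.id}: bad bounds") from exc
        if math.isnan(lower) or math.isnan(upper):
            raise ModelValidationError(f"reaction {row.id}: bad bounds")
        reactions.append(
            Reaction(
                id=row.id,
                name=getattr(row, "name", ""),
                stoichiometry=parse_equation(row.equation),
                lower_bound=lower,
                upper_bound=upper,
                gpr=row.gpr or None,
                evidence=(row.evidence or None),
            )
        )

    return MetabolicModel.from_lists(
        compounds,
        reactions,
        biomass_reaction_id=header.get("biomass") or None,
        name=header.get("name", ""),
        metadata={str(k): str(v) for k, v in (header.get("metadata") or {}).items()},
    )


def write_yaml_tsv(model: MetabolicModel, path) -> None:
    """Write the model as a directory holding model.yaml + two TSVs."""
    base, yaml_path = _model_dir(path) if os.path.isdir(str(path)) or str(path).endswith(
        (".yaml", ".yml")
    ) else (str(path), os.path.join(str(path), "model.yaml"))
    os.makedirs(base, exist_ok=True)

    header = {
        "name": model.name,
        "biomass": model.biomass_reaction_id,
        "compounds": "compounds.tsv",
        "reactions": "reactions.tsv",
        "metadata": dict(model.metadata),
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=False)

    cdf = pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "formula": format_formula(c.formula),
                "charge": "" if c.charge is None else c.charge,
                "compartment": c.compartment,
            }
            for c in sorted(model.compounds.values(), key=lambda c: c.id)
        ],
        columns=["id", "name", "formula", "charge", "compartment"],
    )
    cdf.to_csv(os.path.join(base, "compounds.tsv"), sep="\t", index=False)

    rdf = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lower": r.lower_bound,
                "upper": r.upper_bound,
                "gpr": r.gpr_string,
                "evidence": r.evidence or "",
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
        columns=["id", "name", "equation", "lower", "upper", "gpr", "evidence"],
    )
    rdf.to_csv(os.path.join(base, "reactions.tsv"), sep="\t", index=False)
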