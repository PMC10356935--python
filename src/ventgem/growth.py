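"""Simulation protocols on top of the FBA engine, plus OD-curve rate fits.

Carbon-source scans normalise every substrate to the same total carbon (10
mM-equivalents split over the carbon atoms of the formula) so that yields
are comparable across substrates; essential amino acids ride along at 1
mM-equivalent uptake each. Growth outcomes are reported on the three-level
scale used for plate/bottle phenotyping: ``-`` no growth, ``+`` growth
comparable to the all-amino-acid reference, ``++`` at least 1.5-fold above
it. Specific growth rates come from ln-OD differences or an ordinary
least-squares fit of ln(OD) against time over 4-6 exponential-phase points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
from scipy import stats

from .fba import solve_fba
from .medium import MediumCondition
from .model import MetabolicModel, ModelValidationError

__all__ = [
    "AMINO_ACIDS",
    "GrowthCall",
    "PathwayDefinition",
    "GrowthCurve",
    "make_carbon_medium",
    "classify_growth",
    "leave_one_out_scan",
    "essential_aas_from_genome",
    "electron_acceptor_scan",
    "load_pathways_tsv",
    "growth_rate",
    "growth_rate_regression",
]

#: The 20 canonical amino acids, by the compound ids used throughout.
AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: Yields below this are "no growth" (solver noise floor, objective units).
ZERO_TOL = 1e-6

#: Fold-change over the reference required for a "++" call (inclusive).
FOLD_THRESHOLD = 1.5

GrowthCall = str  # one of "-", "+", "++"


@dataclass(frozen=True)
class PathwayDefinition:
    """The reaction set composing one amino acid's whole biosynthesis pathway."""

    amino_acid: str
    reaction_ids: frozenset

    def __post_init__(self):
        if self.amino_acid not in AMINO_ACIDS:
            raise ModelValidationError(f"unknown amino acid {self.amino_acid!r}")
        if not self.reaction_ids:
            raise ModelValidationError(f"empty pathway for {self.amino_acid}")


@dataclass
class GrowthCurve:
    """Timestamped OD600 readings (times in hours, strictly increasing)."""

    times: Sequence[float]
    od600: Sequence[float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if len(self.times) != len(self.od600) or len(self.times) < 2:
            raise ModelValidationError("curve needs >= 2 paired (time, OD) points")
        if not np.all(np.diff(self.times) > 0):
            raise ModelValidationError("times must be strictly increasing")
        if not np.all(self.od600 > 0):
            raise ModelValidationError("OD600 values must be positive")


def _exchange_id(model: MetabolicModel, compound_id: str) -> str:
    reaction = model.exchange_for(compound_id)
    if reaction is None:
        raise ModelValidationError(f"no exchange reaction for compound {compound_id!r}")
    return reaction.id


def make_carbon_medium(
    base: MediumCondition,
    carbon_source: str,
    model: MetabolicModel,
    essential_aas: Iterable[str] = (),
    total_carbon: float = 10.0,
    aa_uptake: float = 1.0,
) -> MediumCondition:
    """Condition with one carbon source normalised to fixed total carbon.

    The source's maximum uptake is ``total_carbon / (carbon atoms in its
    formula)``, removing the trivial advantage of bigger molecules; each
    essential amino acid gets ``aa_uptake``; everything else follows the
    base condition.
    """
    compound = model.compounds.get(carbon_source)
    if compound is None:
        raise ModelValidationError(f"unknown compound {carbon_source!r}")
    if compound.formula is None:
        raise ModelValidationError(f"{carbon_source}: unknown formula, cannot normalise carbon")
    n_carbon = compound.formula.get("C", 0)
    if n_carbon < 1:
        raise ModelValidationError(f"{carbon_source}: carbon-free compound")

    medium = base.with_bounds(
        _exchange_id(model, carbon_source), total_carbon / n_carbon,
        base.exchange_bounds.get(_exchange_id(model, carbon_source), (0.0, 1000.0))[1],
    )
    for aa in essential_aas:
        ex = _exchange_id(model, aa)
        medium = medium.with_bounds(ex, aa_uptake, medium.exchange_bounds.get(ex, (0.0, 1000.0))[1])
    medium.name = f"{base.name}+{carbon_source}"
    return medium


def classify_growth(
    yield_test: float,
    yield_reference: float,
    fold_threshold: float = FOLD_THRESHOLD,
    zero_tol: float = ZERO_TOL,
) -> GrowthCall:
    """Three-level growth call against a reference yield (total partition)."""
    if yield_reference <= zero_tol:
        raise ModelValidationError("reference yield is itself no-growth")
    if yield_test <= zero_tol:
        return "-"
    if yield_test / yield_reference >= fold_threshold:
        return "++"
    return "+"


def leave_one_out_scan(
    model: MetabolicModel,
    base: MediumCondition,
    amino_acids: Sequence[str] = AMINO_ACIDS,
    aa_uptake: float = 1.0,
) -> Dict[str, GrowthCall]:
    """Remove each amino acid in turn from an all-amino-acid condition.

    The baseline supplies every listed amino acid at ``aa_uptake``; each scan
    closes one uptake and classifies the new yield against the baseline. An
    amino acid scoring ``-`` is an auxotrophy: biomass needs it and the
    network cannot synthesise it.
    """
    medium = base
    for aa in amino_acids:
        ex = _exchange_id(model, aa)
        medium = medium.with_bounds(ex, aa_uptake, medium.exchange_bounds.get(ex, (0.0, 1000.0))[1])
    baseline = solve_fba(model, medium)
    if not baseline.optimal or baseline.objective_value <= ZERO_TOL:
        raise ModelValidationError("baseline all-amino-acid condition does not grow")

    calls: Dict[str, GrowthCall] = {}
    for aa in amino_acids:
        res = solve_fba(model, medium.without(_exchange_id(model, aa)))
        value = res.objective_value if res.optimal else 0.0
        calls[aa] = classify_growth(value, baseline.objective_value)
    return calls


def essential_aas_from_genome(
    model: MetabolicModel,
    pathways: Iterable[PathwayDefinition],
    missing_fraction: float = 0.5,
) -> Set[str]:
    """Genome-level essentiality call from pathway completeness.

    An amino acid is essential when the model is missing at least
    ``missing_fraction`` (default half, boundary inclusive) of the reactions
    of its whole biosynthesis pathway.
    """
    essential: Set[str] = set()
    for pathway in pathways:
        absent = sum(1 for rid in pathway.reaction_ids if rid not in model.reactions)
        if absent / len(pathway.reaction_ids) >= missing_fraction:
            essential.add(pathway.amino_acid)
    return essential


def electron_acceptor_scan(
    model: MetabolicModel,
    base: MediumCondition,
    acceptors: Sequence[str],
    acceptor_uptake: float = 10.0,
) -> Dict[Optional[str], float]:
    """Biomass yield per electron-acceptor condition, plus a no-acceptor one.

    Each condition opens one acceptor's uptake and closes the others'; the
    ``None`` key is the acceptor-free (fermentative) condition. Ordering of
    the result follows the input sequence.
    """
    yields: Dict[Optional[str], float] = {}

    def run(open_acceptor: Optional[str]) -> float:
        medium = base
        for acc in acceptors:
            ex = _exchange_id(model, acc)
            secretion = medium.exchange_bounds.get(ex, (0.0, 1000.0))[1]
            uptake = acceptor_uptake if acc == open_acceptor else 0.0
            medium = medium.with_bounds(ex, uptake, secretion)
        res = solve_fba(model, medium)
        return res.objective_value if res.optimal else 0.0

    yields[None] = run(None)
    for acc in acceptors:
        yields[acc] = run(acc)
    return yields


def load_pathways_tsv(path) -> List[PathwayDefinition]:
    """Read pathway definitions: columns amino_acid, reaction_ids (semicolon)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return [
        PathwayDefinition(
            amino_acid=row.amino_acid,
            reaction_ids=frozenset(r for r in row.reaction_ids.split(";") if r),
        )
        for row in df.itertuples()
    ]


def growth_rate(curve: GrowthCurve, t1: float, t2: float) -> float:
    """Two-point specific growth rate μ = ln(OD(t2)/OD(t1)) / (t2 - t1)."""
    if t1 >= t2:
        raise ModelValidationError("t1 must be earlier than t2")
    times = list(curve.times)
    for t in (t1, t2):
        if t not in times:
            raise ModelValidationError(f"time {t} not in curve")
    od1 = curve.od600[times.index(t1)]
    od2 = curve.od600[times.index(t2)]
    return float(np.log(od2 / od1) / (t2 - t1))


def growth_rate_regression(
    curve: GrowthCurve, start: int = 0, window: Optional[int] = None
) -> float:
    """OLS slope of ln(OD) against time over a 4-6 point window.

    ``window`` defaults to the whole curve if that holds 4-6 points.
    """
    n = len(curve.times)
    if window is None:
        window = n
    if not 4 <= window <= 6:
        raise ModelValidationError("regression window must span 4 to 6 points")
    if start < 0 or start + window > n:
        raise ModelValidationError("window exceeds the curve")
    t = curve.times[start : start + window]
    log_od = np.log(curve.od600[start : start + window])
    fit = stats.linregress(t, log_od)
    return float(fit.slope)
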