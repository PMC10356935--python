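"""Culture conditions as exchange-bound assignments.

A :class:`MediumCondition` encodes one culture condition: for each exchange
reaction a maximum uptake and maximum secretion (both non-negative,
mmol·gDW⁻¹·h⁻¹). Applying it sets ``lower_bound = -max_uptake`` and
``upper_bound = max_secretion``. With ``closed_by_default`` every unlisted
exchange is closed for uptake but left open for secretion, mirroring a
defined medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .model import DEFAULT_BOUND, MetabolicModel, ModelValidationError

__all__ = ["MediumCondition", "apply_medium", "read_medium_tsv", "write_medium_tsv"]


@dataclass
class MediumCondition:
    name: str = "medium"
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    closed_by_default: bool = True

    def __post_init__(self):
        for ex_id, (uptake, secretion) in self.exchange_bounds.items():
            if uptake < 0 or secretion < 0:
                raise ModelValidationError(
                    f"medium {self.name}: negative bound for {ex_id} "
                    "(uptake and secretion are magnitudes)"
                )

    def with_bounds(self, ex_id: str, uptake: float, secretion: float) -> "MediumCondition":
        """A copy with one exchange's bounds replaced."""
        bounds = dict(self.exchange_bounds)
        bounds[ex_id] = (uptake, secretion)
        return MediumCondition(self.name, bounds, self.closed_by_default)

    def without(self, ex_id: str) -> "MediumCondition":
        """A copy with one exchange closed for uptake (secretion stays open)."""
        return self.with_bounds(ex_id, 0.0, self.exchange_bounds.get(ex_id, (0.0, DEFAULT_BOUND))[1])


def apply_medium(model: MetabolicModel, medium: MediumCondition) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set per the medium.

    Idempotent: applying the same condition twice yields the same bounds.
    """
    out = model.copy()
    for ex_id, (uptake, secretion) in medium.exchange_bounds.items():
        reaction = out.reactions.get(ex_id)
        if reaction is None or not reaction.is_exchange:
            raise ModelValidationError(
                f"medium {medium.name}: {ex_id!r} is not an exchange reaction of the model"
            )
        reaction.lower_bound = -uptake
        reaction.upper_bound = secretion
    if medium.closed_by_default:
        for reaction in out.reactions.values():
            if reaction.is_exchange and reaction.id not in medium.exchange_bounds:
                reaction.lower_bound = 0.0
                reaction.upper_bound = DEFAULT_BOUND
    return out


def read_medium_tsv(path, name: Optional[str] = None, closed_by_default: bool = True) -> MediumCondition:
    """Read a medium table with columns exchange_id, max_uptake, max_secretion."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"exchange_id", "max_uptake", "max_secretion"}
    if not required.issubset(df.columns):
        raise ModelValidationError(
            f"medium table {path} must have columns {sorted(required)}"
        )
    bounds = {
        str(row.exchange_id): (float(row.max_uptake), float(row.max_secretion))
        for row in df.itertuples()
    }
    return MediumCondition(name or str(path), bounds, closed_by_default)


def write_medium_tsv(medium: MediumCondition, path) -> None:
    df = pd.DataFrame(
        [
            {"exchange_id": ex, "max_uptake": up, "max_secretion": sec}
            for ex, (up, sec) in sorted(medium.exchange_bounds.items())
        ]
    )
    df.to_csv(path, sep="\t", index=False)
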