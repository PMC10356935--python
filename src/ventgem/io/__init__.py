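"""Model readers/writers: SBML Level 3 + FBC, and a YAML+TSV dialect."""

from __future__ import annotations

import os

from ..model import MetabolicModel, ModelValidationError
from . import sbml, tables
from .tables import format_equation, parse_equation

__all__ = ["load_model", "save_model", "parse_equation", "format_equation"]

FORMATS = ("sbml_fbc", "yaml_tsv")


def _guess_format(path: str) -> str:
    if str(path).endswith((".xml", ".sbml")):
        return "sbml_fbc"
    if str(path).endswith((".yaml", ".yml")) or os.path.isdir(path):
        return "yaml_tsv"
    raise ModelValidationError(f"cannot guess model format for {path!r}; pass format=")


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (``sbml_fbc``) or the YAML+TSV dialect.

    For ``yaml_tsv`` the path may be the ``model.yaml`` file or its
    directory. Round-trips with :func:`save_model` are identity up to
    ordering.
    """
    fmt = format or _guess_format(path)
    if fmt == "sbml_fbc":
        return sbml.read_sbml(path)
    if fmt == "yaml_tsv":
        return tables.read_yaml_tsv(path)
    raise ModelValidationError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, format: str | None = None) -> None:
    fmt = format or _guess_format(path)
    if fmt == "sbml_fbc":
        sbml.write_sbml(model, path)
    elif fmt == "yaml_tsv":
        tables.write_yaml_tsv(model, path)
    else:
        raise ModelValidationError(f"unknown model format {fmt!r}")
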