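"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers that states which gene
products enable a reaction: ``and`` joins obligate subunits of one complex,
``or`` joins isozymes or alternative complexes. The grammar is infix with
``and`` binding tighter than ``or``, parentheses allowed, keywords
case-insensitive. A reaction with an empty GPR is constitutive — it is never
disabled by gene deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterator, Union

__all__ = ["Gene", "And", "Or", "GPR", "parse_gpr", "gpr_genes", "evaluate_gpr", "format_gpr"]


@dataclass(frozen=True)
class Gene:
    id: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


#: A GPR node: a gene leaf, a conjunction, a disjunction, or None (empty rule).
GPR = Union[Gene, And, Or, None]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


def _tokenize(text: str) -> Iterator[str]:
    for match in _TOKEN.finditer(text):
        yield match.group(0)


class _Parser:
    def __init__(self, tokens):
        self.tokens = list(tokens)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_or(self) -> GPR:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> GPR:
        factors = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom(self) -> GPR:
        tok = self.next()
        if tok is None:
            raise GPRSyntaxError("unexpected end of GPR expression")
        if tok == "(":
            inner = self.parse_or()
            if self.next() != ")":
                raise GPRSyntaxError("unbalanced parentheses in GPR")
            return inner
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR")
        return Gene(tok)


def parse_gpr(text: str | None) -> GPR:
    """Parse a GPR string; empty/None/whitespace yields ``None`` (no rule)."""
    if text is None or not text.strip():
        return None
    parser = _Parser(_tokenize(text))
    tree = parser.parse_or()
    if parser.peek() is not None:
        raise GPRSyntaxError(f"trailing token {parser.peek()!r} in GPR")
    return tree


def gpr_genes(node: GPR) -> FrozenSet[str]:
    """All gene ids appearing as leaves of the rule."""
    if node is None:
        return frozenset()
    if isinstance(node, Gene):
        return frozenset({node.id})
    out: set = set()
    for child in node.children:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(node: GPR, deleted: set) -> bool:
    """Evaluate the rule with the given genes knocked out.

    Returns True when the reaction remains catalysed. An empty rule is
    always True.
    """
    if node is None:
        return True
    if isinstance(node, Gene):
        return node.id not in deleted
    if isinstance(node, And):
        return all(evaluate_gpr(c, deleted) for c in node.children)
    return any(evaluate_gpr(c, deleted) for c in node.children)


def format_gpr(node: GPR) -> str:
    """Render the rule back to infix text (lossless modulo whitespace)."""
    if node is None:
        return ""
    if isinstance(node, Gene):
        return node.id
    if isinstance(node, And):
        return " and ".join(
            f"({format_gpr(c)})" if isinstance(c, (Or, And)) else format_gpr(c)
            for c in node.children
        )
    return " or ".join(
        f"({format_gpr(c)})" if isinstance(c, Or) else format_gpr(c)
        for c in node.children
    )
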