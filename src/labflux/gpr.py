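"""Boolean gene-protein-reaction (GPR) expressions.

A GPR links a reaction to the genes whose products catalyze it: ``or`` joins
isozymes (any one suffices), ``and`` joins subunits of a complex (all are
required). Expressions are parsed into an immutable tree of :class:`GeneRef`,
:class:`And` and :class:`Or` nodes; an empty/absent expression marks a
spontaneous or literature-based reaction with no gene association.

The parser uses conventional precedence (``and`` binds tighter than ``or``)
and flattens nested runs of the same operator, so ``a and b and c`` is a
single three-way :class:`And`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .errors import GPRSyntaxError

GPRNode = Union["GeneRef", "And", "Or"]

__all__ = ["GeneRef", "And", "Or", "GPRNode", "parse_gpr", "gpr_to_string", "gpr_genes"]


@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class And:
    terms: tuple[GPRNode, ...]


@dataclass(frozen=True)
class Or:
    terms: tuple[GPRNode, ...]


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GPRSyntaxError(
                    f"unexpected character {text[pos]!r} at position {pos} in {text!r}"
                )
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.text = text
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of expression in {self.text!r}")
        self.pos += 1
        return tok

    # grammar: or_expr := and_expr ("or" and_expr)*
    #          and_expr := atom ("and" atom)*
    #          atom := gene | "(" or_expr ")"
    def or_expr(self) -> GPRNode:
        terms = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.and_expr())
        if len(terms) == 1:
            return terms[0]
        flat: list[GPRNode] = []
        for t in terms:
            flat.extend(t.terms if isinstance(t, Or) else [t])
        return Or(tuple(flat))

    def and_expr(self) -> GPRNode:
        terms = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.atom())
        if len(terms) == 1:
            return terms[0]
        flat: list[GPRNode] = []
        for t in terms:
            flat.extend(t.terms if isinstance(t, And) else [t])
        return And(tuple(flat))

    def atom(self) -> GPRNode:
        tok = self.next()
        if tok == "(":
            node = self.or_expr()
            closing = self.next()
            if closing != ")":
                raise GPRSyntaxError(f"expected ')' in {self.text!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in {self.text!r}")
        return GeneRef(tok)


def parse_gpr(text: str | None) -> GPRNode | None:
    """Parse a GPR string; ``None``/empty/whitespace yields ``None``."""
    if text is None or not text.strip():
        return None
    parser = _Parser(_tokenize(text), text)
    node = parser.or_expr()
    if parser.peek() is not None:
        raise GPRSyntaxError(f"trailing token {parser.peek()!r} in {text!r}")
    return node


def gpr_to_string(node: GPRNode | None) -> str:
    """Render a GPR tree to its canonical infix string (empty for ``None``)."""
    if node is None:
        return ""
    if isinstance(node, GeneRef):
        return node.gene
    if isinstance(node, And):
        parts = [
            f"({gpr_to_string(t)})" if isinstance(t, Or) else gpr_to_string(t)
            for t in node.terms
        ]
        return " and ".join(parts)
    parts = [
        f"({gpr_to_string(t)})" if isinstance(t, And) else gpr_to_string(t)
        for t in node.terms
    ]
    return " or ".join(parts)


def gpr_genes(node: GPRNode | None) -> frozenset[str]:
    """All gene ids referenced anywhere in the expression."""
    if node is None:
        return frozenset()
    if isinstance(node, GeneRef):
        return frozenset([node.gene])
    out: set[str] = set()
    for t in node.terms:
        out |= gpr_genes(t)
    return frozenset(out)
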