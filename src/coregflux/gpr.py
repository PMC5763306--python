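"""Parsing and continuous evaluation of gene-protein-reaction (GPR) rules.

Boolean GPR strings ("(G1 and G2) or G3") are parsed into flat n-ary trees
and evaluated continuously over real-valued gene activities: AND (enzyme
complex) becomes min, OR (isoenzymes) becomes max.  Genes whose activity is
unavailable are discarded from the rule at every nesting level before
evaluation; a rule whose leaves are all discarded evaluates to ``None`` and
the reaction keeps its default bounds downstream.
"""

from __future__ import annotations

import re
from typing import Mapping

from .types import GPRAnd, GPRLeaf, GPRNode, GPROr

__all__ = ["GPRParseError", "parse_gpr", "evaluate_gpr"]


class GPRParseError(ValueError):
    """Malformed GPR string; message carries the token position."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(rule)]


class _Parser:
    # grammar: expr := term ("or" term)* ; term := factor ("and" factor)* ;
    # factor := IDENT | "(" expr ")".  AND binds tighter than OR.

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.pos = 0

    def _peek(self) -> str | None:
        if self.pos < len(self.tokens):
            return self.tokens[self.pos][0]
        return None

    def _err(self, msg: str) -> GPRParseError:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.rule)
        return GPRParseError(f"{msg} at position {at} in {self.rule!r}")

    def parse(self) -> GPRNode:
        if not self.tokens:
            raise GPRParseError(f"empty GPR rule: {self.rule!r}")
        node = self._expr()
        if self.pos != len(self.tokens):
            raise self._err(f"unexpected token {self._peek()!r}")
        return node

    def _expr(self) -> GPRNode:
        children = [self._term()]
        while self._peek() is not None and self._peek().lower() == "or":
            self.pos += 1
            children.append(self._term())
        return _flatten(GPROr, children)

    def _term(self) -> GPRNode:
        children = [self._factor()]
        while self._peek() is not None and self._peek().lower() == "and":
            self.pos += 1
            children.append(self._factor())
        return _flatten(GPRAnd, children)

    def _factor(self) -> GPRNode:
        tok = self._peek()
        if tok is None:
            raise self._err("missing operand")
        if tok == "(":
            self.pos += 1
            node = self._expr()
            if self._peek() != ")":
                raise self._err("unbalanced parentheses: expected ')'")
            self.pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise self._err(f"expected identifier, got {tok!r}")
        self.pos += 1
        return GPRLeaf(tok)


def _flatten(cls: type, children: list[GPRNode]) -> GPRNode:
    """Collapse chained same-operator nodes into one flat n-ary node."""
    if len(children) == 1:
        return children[0]
    flat: list[GPRNode] = []
    for child in children:
        if isinstance(child, cls):
            flat.extend(child.children)
        else:
            flat.append(child)
    return cls(children=tuple(flat))


def parse_gpr(rule: str) -> GPRNode:
    """Parse a boolean GPR string into a canonical tree.

    Identifiers are any whitespace/parenthesis-delimited tokens other than
    the (case-insensitive) keywords ``and`` / ``or``; AND binds tighter
    than OR.

    Raises
    ------
    GPRParseError
        On empty input, unbalanced parentheses or a missing operand, with
        the character position in the message.
    """
    return _Parser(rule).parse()


def evaluate_gpr(tree: GPRNode, activities: Mapping[str, float]) -> float | None:
    """Evaluate a GPR tree continuously over per-gene activity values.

    OR nodes return the max of their remaining children, AND nodes the min.
    Leaves whose gene is absent from ``activities`` (or maps to NaN) are
    discarded; a branch whose children are all discarded is itself
    discarded.  Returns ``None`` when the whole tree is discarded.
    """
    if isinstance(tree, GPRLeaf):
        val = activities.get(tree.gene)
        if val is None or val != val:  # NaN-aware missingness
            return None
        return float(val)
    values = [evaluate_gpr(c, activities) for c in tree.children]
    values = [v for v in values if v is not None]
    if not values:
        return None
    return min(values) if isinstance(tree, GPRAnd) else max(values)
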