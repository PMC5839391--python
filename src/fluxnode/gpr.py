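"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene products catalyse a reaction: ``and`` joins
subunits of a complex, ``or`` joins isozymes.  To convert protein abundances
into a per-reaction score the rule is evaluated arithmetically: ``or``
operands are summed (isozyme capacities add) and the minimum is taken over
``and`` operands (a complex is limited by its scarcest subunit).

Genes without a measurement are *undefined*: they are dropped from their
operator rather than scored as zero, so a single unmeasured complex subunit
does not silently block the reaction.  A rule whose leaves are all undefined
evaluates to ``None`` and the reaction is left unconstrained downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Union

__all__ = ["GPRError", "Gene", "BoolOp", "GPRRule", "parse_gpr", "evaluate_gpr"]


class GPRError(ValueError):
    """Raised for a malformed GPR rule string; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (token {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    name: str

    def genes(self) -> frozenset:
        return frozenset({self.name})

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    operands: tuple

    def genes(self) -> frozenset:
        out: frozenset = frozenset()
        for o in self.operands:
            out |= o.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for o in self.operands:
            s = o.to_string()
            if isinstance(o, BoolOp):  # keep nesting explicit so reparse is exact
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


GPRRule = Union[Gene, BoolOp]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list:
    return _TOKEN.findall(text)


class _Parser:
    """Recursive descent over  expr := term ('or' term)* ;
    term := factor ('and' factor)* ;  factor := '(' expr ')' | gene.
    ``and`` therefore binds tighter than ``or``."""

    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRError("unexpected end of rule", self.pos + 1)
        self.pos += 1
        return tok

    def expr(self) -> GPRRule:
        operands = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            operands.append(self.term())
        if len(operands) == 1:
            return operands[0]
        return BoolOp("or", tuple(operands))

    def term(self) -> GPRRule:
        operands = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            operands.append(self.factor())
        if len(operands) == 1:
            return operands[0]
        return BoolOp("and", tuple(operands))

    def factor(self) -> GPRRule:
        tok = self.peek()
        if tok is None:
            raise GPRError("expected gene or '('", self.pos + 1)
        if tok == "(":
            self.next()
            node = self.expr()
            if self.peek() != ")":
                raise GPRError("expected ')'", self.pos + 1)
            self.next()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRError(f"unexpected token {tok!r}", self.pos + 1)
        return Gene(self.next())


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR rule string into an expression tree.

    Raises :class:`GPRError` (with 1-based token position) on malformed input.
    """
    if not text or not text.strip():
        raise GPRError("empty rule", 1)
    p = _Parser(_tokenize(text))
    node = p.expr()
    if p.peek() is not None:
        raise GPRError(f"trailing token {p.peek()!r}", p.pos + 1)
    return node


def evaluate_gpr(rule: GPRRule, expression: Mapping[str, float]) -> Optional[float]:
    """Arithmetic rule value: OR -> sum, AND -> min, over *defined* operands.

    Genes absent from ``expression`` are undefined and dropped; returns
    ``None`` when every leaf is undefined.  Values must be non-negative.
    """
    if isinstance(rule, Gene):
        v = expression.get(rule.name)
        if v is None:
            return None
        if v < 0:
            raise ValueError(f"negative expression for gene {rule.name!r}")
        return float(v)
    vals = [evaluate_gpr(o, expression) for o in rule.operands]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return float(sum(vals)) if rule.op == "or" else float(min(vals))
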