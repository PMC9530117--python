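"""Algebraic target functions for qualitative-network variables.

A target function maps the current levels of a variable's regulators to the
level the variable moves toward.  Functions are written in a small infix
grammar::

    expr   := term (('+' | '-') term)*
    term   := unary ('*' unary)*
    unary  := '-' unary | atom
    atom   := INT | IDENT | IDENT '(' expr (',' expr)* ')' | '(' expr ')'

with the functions ``min``, ``max``, ``avg`` (n-ary) and ``floor``, ``ceil``
(unary).  Evaluation is exact rational arithmetic; the network engine rounds
(half-up) and clips the result to the variable's range.

Each variable reference carries a polarity — positive if raising the
referenced level can only raise the target, negative if it can only lower it
— used to check that every reference is backed by an interaction edge of the
matching sign (activator for positive, inhibitor for negative).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, Set, Tuple, Union


class ExpressionError(ValueError):
    """Raised for syntax or semantic errors in a target expression."""


@dataclass(frozen=True)
class Const:
    value: int


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class BinOp:
    op: str  # '+', '-', '*'
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Neg:
    operand: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    args: Tuple["Node", ...]


Node = Union[Const, Var, BinOp, Neg, Call]

_FUNCTIONS = {"min", "max", "avg", "floor", "ceil"}
_UNARY_FUNCTIONS = {"floor", "ceil"}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<int>\d+)|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<sym>[-+*(),]))"
)


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(
                f"unexpected character {text[pos:].strip()[0]!r} in expression {text!r}"
            )
        if m.group("int") is not None:
            tokens.append(("int", int(m.group("int"))))
        elif m.group("ident") is not None:
            tokens.append(("ident", m.group("ident")))
        else:
            tokens.append(("sym", m.group("sym")))
        pos = m.end()
    tokens.append(("end", None))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_sym(self, sym: str):
        kind, val = self.next()
        if kind != "sym" or val != sym:
            raise ExpressionError(f"expected {sym!r} in expression {self.text!r}")

    def parse(self) -> Node:
        node = self.expr()
        if self.peek()[0] != "end":
            raise ExpressionError(f"trailing tokens in expression {self.text!r}")
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek() == ("sym", "+") or self.peek() == ("sym", "-"):
            _, op = self.next()
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek() == ("sym", "*"):
            self.next()
            node = BinOp("*", node, self.unary())
        return node

    def unary(self) -> Node:
        if self.peek() == ("sym", "-"):
            self.next()
            return Neg(self.unary())
        return self.atom()

    def atom(self) -> Node:
        kind, val = self.next()
        if kind == "int":
            return Const(val)
        if kind == "ident":
            if self.peek() == ("sym", "("):
                if val not in _FUNCTIONS:
                    raise ExpressionError(
                        f"unknown function {val!r}; supported: {sorted(_FUNCTIONS)}"
                    )
                self.next()
                args = [self.expr()]
                while self.peek() == ("sym", ","):
                    self.next()
                    args.append(self.expr())
                self.expect_sym(")")
                if val in _UNARY_FUNCTIONS and len(args) != 1:
                    raise ExpressionError(f"{val} takes exactly one argument")
                return Call(val, tuple(args))
            return Var(val)
        if kind == "sym" and val == "(":
            node = self.expr()
            self.expect_sym(")")
            return node
        raise ExpressionError(f"unexpected token in expression {self.text!r}")


def _evaluate(node: Node, lookup: Callable[[str], int]) -> Fraction:
    if isinstance(node, Const):
        return Fraction(node.value)
    if isinstance(node, Var):
        return Fraction(lookup(node.name))
    if isinstance(node, Neg):
        return -_evaluate(node.operand, lookup)
    if isinstance(node, BinOp):
        a = _evaluate(node.left, lookup)
        b = _evaluate(node.right, lookup)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        return a * b
    if isinstance(node, Call):
        vals = [_evaluate(a, lookup) for a in node.args]
        if node.func == "min":
            return min(vals)
        if node.func == "max":
            return max(vals)
        if node.func == "avg":
            return sum(vals, Fraction(0)) / len(vals)
        if node.func == "floor":
            return Fraction(math.floor(vals[0]))
        return Fraction(math.ceil(vals[0]))
    raise TypeError(f"unknown node {node!r}")


def _references(node: Node, out: Set[str]) -> None:
    if isinstance(node, Var):
        out.add(node.name)
    elif isinstance(node, Neg):
        _references(node.operand, out)
    elif isinstance(node, BinOp):
        _references(node.left, out)
        _references(node.right, out)
    elif isinstance(node, Call):
        for a in node.args:
            _references(a, out)


def _const_value(node: Node) -> Fraction | None:
    """Value of a reference-free subexpression, else None."""
    refs: Set[str] = set()
    _references(node, refs)
    if refs:
        return None
    return _evaluate(node, lambda n: 0)


def _polarities(node: Node, sign: int, out: Dict[str, Set[int]]) -> None:
    if isinstance(node, Const):
        return
    if isinstance(node, Var):
        out.setdefault(node.name, set()).add(sign)
        return
    if isinstance(node, Neg):
        _polarities(node.operand, -sign, out)
        return
    if isinstance(node, BinOp):
        if node.op == "*":
            lc = _const_value(node.left)
            rc = _const_value(node.right)
            if lc is not None and rc is None:
                _polarities(node.right, sign if lc >= 0 else -sign, out)
            elif rc is not None and lc is None:
                _polarities(node.left, sign if rc >= 0 else -sign, out)
            else:
                # variable * variable: both raise the product (levels are >= 0)
                _polarities(node.left, sign, out)
                _polarities(node.right, sign, out)
            return
        _polarities(node.left, sign, out)
        _polarities(node.right, -sign if node.op == "-" else sign, out)
        return
    if isinstance(node, Call):
        for a in node.args:
            _polarities(a, sign, out)
        return
    raise TypeError(f"unknown node {node!r}")


@dataclass(frozen=True)
class TargetExpression:
    """A parsed target function; keeps its source text for lossless I/O."""

    source: str
    ast: Node

    @classmethod
    def parse(cls, text: str) -> "TargetExpression":
        return cls(source=text, ast=_Parser(text).parse())

    def evaluate(self, lookup: Callable[[str], int]) -> Fraction:
        return _evaluate(self.ast, lookup)

    def references(self) -> Set[str]:
        out: Set[str] = set()
        _references(self.ast, out)
        return out

    def polarities(self) -> Dict[str, Set[int]]:
        """Map variable name -> subset of {+1, -1} polarities it occurs with."""
        out: Dict[str, Set[int]] = {}
        _polarities(self.ast, +1, out)
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.source
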