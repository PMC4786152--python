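"""Restricted predicate mini-language for subsetting and indicator columns.

Plot specifications name row subsets ("patients with a valid CD4 count") and
binary indicators ("CD4 < 200 at enrollment") as expressions over table
columns.  Executing arbitrary host-language code from a config file is
unsafe, so the dialect here is closed: column references, numeric / quoted
text / ISO-date literals, the comparisons ``== != < <= > >=``, membership
``in (…)``, the unary test ``missing(col)``, and ``and`` / ``or`` / ``not``
(``&`` ``|`` ``!`` accepted as aliases).  ``table$col`` prefixes are accepted
and stripped to the bare column name.  Nothing else parses — in particular
no function calls, assignment or arithmetic.

Evaluation is three-valued (Kleene): a comparison against a missing cell is
missing, ``missing(col)`` itself is always true/false, and callers that
subset treat a missing result as false.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import EvaluationError, ExpressionError
from .hicdep_io import MISSING_TOKENS, parse_date

# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Col:
    name: str


@dataclass(frozen=True)
class Lit:
    value: float | str


@dataclass(frozen=True)
class Compare:
    op: str  # one of == != < <= > >=
    left: "Col | Lit"
    right: "Col | Lit"


@dataclass(frozen=True)
class InList:
    operand: "Col | Lit"
    values: tuple


@dataclass(frozen=True)
class IsMissing:
    column: str


@dataclass(frozen=True)
class Not:
    item: "Node"


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    items: tuple


Node = Compare | InList | IsMissing | Not | BoolOp | Col | Lit


@dataclass(frozen=True)
class Predicate:
    """A parsed expression plus the columns it references."""

    ast: Node
    text: str
    referenced_columns: frozenset

    def unparse(self) -> str:
        return _unparse(self.ast)


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>-?\d+(\.\d+)?([eE][+-]?\d+)?)
  | (?P<string>'[^']*'|"[^"]*")
  | (?P<op>==|!=|<=|>=|<|>|&&|\|\||&|\||!|%in%)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<comma>,)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*(\$[A-Za-z_][A-Za-z0-9_.]*)?)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "in", "missing"}
_OP_ALIASES = {"&": "and", "&&": "and", "|": "or", "||": "or", "!": "not", "%in%": "in"}


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            if kind == "op" and value in _OP_ALIASES:
                word = _OP_ALIASES[value]
                tokens.append(_Token("keyword", word, pos))
            elif kind == "ident" and value.lower() in _KEYWORDS:
                tokens.append(_Token("keyword", value.lower(), pos))
            else:
                tokens.append(_Token(kind, value, pos))
        pos = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.peek()
        if tok.kind != kind:
            raise ExpressionError(f"expected {what}", tok.pos)
        return self.next()

    def parse(self) -> Node:
        node = self.parse_or()
        tok = self.peek()
        if tok.kind != "eof":
            raise ExpressionError(f"unexpected {tok.value!r}", tok.pos)
        return node

    def parse_or(self) -> Node:
        items = [self.parse_and()]
        while self.peek().kind == "keyword" and self.peek().value == "or":
            self.next()
            items.append(self.parse_and())
        return items[0] if len(items) == 1 else BoolOp("or", tuple(items))

    def parse_and(self) -> Node:
        items = [self.parse_not()]
        while self.peek().kind == "keyword" and self.peek().value == "and":
            self.next()
            items.append(self.parse_not())
        return items[0] if len(items) == 1 else BoolOp("and", tuple(items))

    def parse_not(self) -> Node:
        tok = self.peek()
        if tok.kind == "keyword" and tok.value == "not":
            self.next()
            return Not(self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self) -> Node:
        left = self.parse_operand()
        tok = self.peek()
        if tok.kind == "op":
            op = self.next().value
            right = self.parse_operand()
            return Compare(op, left, right)
        if tok.kind == "keyword" and tok.value == "in":
            self.next()
            self.expect("lparen", "'(' after 'in'")
            values = [self._literal_value(self.parse_operand_literal())]
            while self.peek().kind == "comma":
                self.next()
                values.append(self._literal_value(self.parse_operand_literal()))
            self.expect("rparen", "')'")
            return InList(left, tuple(values))
        return left  # bare column / literal used as a truth value

    def parse_operand(self) -> Col | Lit | Node:
        tok = self.peek()
        if tok.kind == "keyword" and tok.value == "missing":
            self.next()
            self.expect("lparen", "'(' after 'missing'")
            col = self.expect("ident", "column name")
            self.expect("rparen", "')'")
            return IsMissing(_strip_table(col.value))
        if tok.kind == "lparen":
            self.next()
            inner = self.parse_or()
            self.expect("rparen", "')'")
            return inner
        return self.parse_operand_literal()

    def parse_operand_literal(self) -> Col | Lit:
        tok = self.peek()
        if tok.kind == "number":
            self.next()
            return Lit(float(tok.value))
        if tok.kind == "string":
            self.next()
            return Lit(tok.value[1:-1])
        if tok.kind == "ident":
            self.next()
            return Col(_strip_table(tok.value))
        raise ExpressionError("expected a column, number or quoted text", tok.pos)

    @staticmethod
    def _literal_value(operand: Col | Lit):
        if isinstance(operand, Lit):
            return operand.value
        # allow bare words inside in(...) lists, treated as text
        return operand.name


def _strip_table(ident: str) -> str:
    return ident.split("$", 1)[1] if "$" in ident else ident


def _collect_columns(node: Node, out: set) -> None:
    if isinstance(node, Col):
        out.add(node.name)
    elif isinstance(node, IsMissing):
        out.add(node.column)
    elif isinstance(node, Compare):
        _collect_columns(node.left, out)
        _collect_columns(node.right, out)
    elif isinstance(node, InList):
        _collect_columns(node.operand, out)
    elif isinstance(node, Not):
        _collect_columns(node.item, out)
    elif isinstance(node, BoolOp):
        for item in node.items:
            _collect_columns(item, out)


def parse_expression(text: str) -> Predicate:
    """Parse predicate text into a :class:`Predicate`; errors carry positions."""
    if not text or not text.strip():
        raise ExpressionError("empty expression", 0)
    ast = _Parser(text).parse()
    cols: set = set()
    _collect_columns(ast, cols)
    return Predicate(ast=ast, text=text, referenced_columns=frozenset(cols))


def _unparse(node: Node) -> str:
    if isinstance(node, Col):
        return node.name
    if isinstance(node, Lit):
        if isinstance(node.value, str):
            return f"'{node.value}'"
        return f"{node.value:g}"
    if isinstance(node, Compare):
        return f"{_unparse(node.left)} {node.op} {_unparse(node.right)}"
    if isinstance(node, InList):
        vals = ", ".join(f"'{v}'" if isinstance(v, str) else f"{v:g}" for v in node.values)
        return f"{_unparse(node.operand)} in ({vals})"
    if isinstance(node, IsMissing):
        return f"missing({node.column})"
    if isinstance(node, Not):
        return f"not {_unparse_atom(node.item)}"
    if isinstance(node, BoolOp):
        return f" {node.op} ".join(_unparse_atom(i) for i in node.items)
    raise TypeError(f"cannot unparse {node!r}")


def _unparse_atom(node: Node) -> str:
    if isinstance(node, BoolOp):
        return f"({_unparse(node)})"
    return _unparse(node)


# ---------------------------------------------------------------------------
# Evaluation


def _infer_typed_column(series: Iterable) -> list:
    """Type a text column: ISO dates, else numbers, else text (per column)."""
    cells = list(series)
    present = [c for c in cells if c is not None and not (isinstance(c, str) and c.strip() in MISSING_TOKENS)]
    if not present:
        return [None] * len(cells)
    if all(isinstance(c, dt.date) for c in present):
        return [c if isinstance(c, dt.date) else None for c in cells]
    if all(isinstance(c, (int, float)) for c in present):
        return [float(c) if isinstance(c, (int, float)) else None for c in cells]

    def as_date(c):
        try:
            return parse_date(c) if isinstance(c, str) else None
        except Exception:
            return None

    if all(as_date(c) is not None for c in present):
        return [as_date(c) if c is not None else None for c in cells]

    def as_num(c):
        try:
            return float(c)
        except (TypeError, ValueError):
            return None

    if all(as_num(c) is not None for c in present):
        return [as_num(c) for c in cells]
    out = []
    for c in cells:
        if c is None or (isinstance(c, str) and c.strip() in MISSING_TOKENS):
            out.append(None)
        else:
            out.append(str(c))
    return out


_CMP = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def _coerce_pair(a, b):
    """Bring two non-missing operands onto a comparable type, or None."""
    if isinstance(a, dt.date) and isinstance(b, str):
        try:
            return a, parse_date(b)
        except Exception:
            return None
    if isinstance(b, dt.date) and isinstance(a, str):
        try:
            return parse_date(a), b
        except Exception:
            return None
    if isinstance(a, float) and isinstance(b, str):
        try:
            return a, float(b)
        except ValueError:
            return None
    if isinstance(b, float) and isinstance(a, str):
        try:
            return float(a), b
        except ValueError:
            return None
    if type(a) is type(b) or (isinstance(a, float) and isinstance(b, float)):
        return a, b
    if isinstance(a, str) and isinstance(b, str):
        return a, b
    return None


def _truth(value) -> bool | None:
    if value is None:
        return None
    if isinstance(value, bool):
        return value
    if isinstance(value, float):
        return value != 0.0
    if isinstance(value, str):
        return value.lower() in {"1", "true", "t", "y", "yes"}
    return None


def _eval_node(node: Node, row: dict) -> bool | None:
    if isinstance(node, IsMissing):
        return row[node.column] is None
    if isinstance(node, Not):
        inner = _eval_node(node.item, row)
        return None if inner is None else not inner
    if isinstance(node, BoolOp):
        vals = [_eval_node(item, row) for item in node.items]
        if node.op == "and":
            if any(v is False for v in vals):
                return False
            return None if any(v is None for v in vals) else True
        if any(v is True for v in vals):
            return True
        return None if any(v is None for v in vals) else False
    if isinstance(node, Compare):
        a = _operand_value(node.left, row)
        b = _operand_value(node.right, row)
        if a is None or b is None:
            return None
        pair = _coerce_pair(a, b)
        if pair is None:
            return None
        return _CMP[node.op](*pair)
    if isinstance(node, InList):
        a = _operand_value(node.operand, row)
        if a is None:
            return None
        for v in node.values:
            pair = _coerce_pair(a, v)
            if pair is not None and pair[0] == pair[1]:
                return True
        return False
    if isinstance(node, (Col, Lit)):
        return _truth(_operand_value(node, row))
    raise TypeError(f"cannot evaluate {node!r}")


def _operand_value(node: Col | Lit, row: dict):
    if isinstance(node, Lit):
        return node.value
    return row[node.name]


def evaluate(pred: Predicate, table: pd.DataFrame) -> pd.array:
    """Evaluate a predicate row-wise over a DataFrame.

    Returns a pandas nullable-boolean array: ``pd.NA`` where the predicate is
    missing under three-valued logic.  Raises :class:`EvaluationError` if any
    referenced column is absent — detectable before touching a single row.
    """
    missing_cols = sorted(pred.referenced_columns - set(table.columns))
    if missing_cols:
        raise EvaluationError(f"unknown column(s) {missing_cols} in predicate {pred.text!r}")
    typed = {c: _infer_typed_column(table[c]) for c in pred.referenced_columns}
    n = len(table)
    out = []
    for i in range(n):
        row = {c: typed[c][i] for c in typed}
        out.append(_eval_node(pred.ast, row))
    return pd.array([pd.NA if v is None else v for v in out], dtype="boolean")


def subset_mask(pred: Predicate, table: pd.DataFrame) -> pd.Series:
    """Boolean mask for row subsetting: missing evaluates to False."""
    vals = evaluate(pred, table)
    return pd.Series(vals.to_numpy(dtype=object, na_value=False).astype(bool), index=table.index)
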