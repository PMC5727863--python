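"""Condition expressions over patient context, with Kleene three-valued logic.

The expression language is deliberately small: field references, literals
(number, text, boolean, ISO date), the six comparison operators, AND / OR /
NOT, and a presence test ``EXISTS field``. There is no arithmetic — every
clinical condition the engine targets is a threshold or boolean test; richer
algebra is a documented extension point.

Missing data never silently coerces to false: a comparison touching an
absent field evaluates to ``UNKNOWN``, and the connectives follow Kleene's
strong three-valued logic (``true AND unknown = unknown`` etc.). Only
``EXISTS`` is immune — it is precisely the question "is this field present".
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass
from typing import Iterator

from .context import ContextSchema, PatientContext, value_kind
from .errors import ParseError, TypeMismatchError


class TruthValue(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:
        # Guard against accidental 2-valued use: `if tv:` would treat
        # FALSE and UNKNOWN both as truthy (enum default). Force explicitness.
        raise TypeError("TruthValue is three-valued; compare explicitly")

    @staticmethod
    def of(b: bool) -> "TruthValue":
        return TruthValue.TRUE if b else TruthValue.FALSE


def kleene_and(a: TruthValue, b: TruthValue) -> TruthValue:
    if TruthValue.FALSE in (a, b):
        return TruthValue.FALSE
    if TruthValue.UNKNOWN in (a, b):
        return TruthValue.UNKNOWN
    return TruthValue.TRUE


def kleene_or(a: TruthValue, b: TruthValue) -> TruthValue:
    if TruthValue.TRUE in (a, b):
        return TruthValue.TRUE
    if TruthValue.UNKNOWN in (a, b):
        return TruthValue.UNKNOWN
    return TruthValue.FALSE


def kleene_not(a: TruthValue) -> TruthValue:
    if a is TruthValue.UNKNOWN:
        return TruthValue.UNKNOWN
    return TruthValue.of(a is TruthValue.FALSE)


# ---------------------------------------------------------------------------
# AST


class Expression:
    """Abstract base of expression nodes."""

    def fields(self) -> set[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover
        return f"<{type(self).__name__} {self.to_text()!r}>"

    def __eq__(self, other):
        return type(self) is type(other) and self.to_text() == other.to_text()

    def __hash__(self):
        return hash((type(self).__name__, self.to_text()))


@dataclass(frozen=True, eq=False)
class FieldRef(Expression):
    name: str

    def fields(self):
        return {self.name}

    def to_text(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Literal(Expression):
    value: object  # bool | int | float | str | datetime.date

    def fields(self):
        return set()

    @property
    def kind(self) -> str:
        return value_kind(self.value)

    def to_text(self):
        v = self.value
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, _dt.date):
            return v.isoformat()
        if isinstance(v, str):
            return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
        return repr(v)


_CMP_OPS = ("<", "<=", ">", ">=", "==", "!=")


@dataclass(frozen=True, eq=False)
class Comparison(Expression):
    op: str
    left: Expression
    right: Expression

    def __post_init__(self):
        if self.op not in _CMP_OPS:
            raise ValueError(f"bad comparison operator {self.op!r}")

    def fields(self):
        return self.left.fields() | self.right.fields()

    def to_text(self):
        return f"{self.left.to_text()} {self.op} {self.right.to_text()}"


@dataclass(frozen=True, eq=False)
class And(Expression):
    left: Expression
    right: Expression

    def fields(self):
        return self.left.fields() | self.right.fields()

    def to_text(self):
        return f"({self.left.to_text()} AND {self.right.to_text()})"


@dataclass(frozen=True, eq=False)
class Or(Expression):
    left: Expression
    right: Expression

    def fields(self):
        return self.left.fields() | self.right.fields()

    def to_text(self):
        return f"({self.left.to_text()} OR {self.right.to_text()})"


@dataclass(frozen=True, eq=False)
class Not(Expression):
    operand: Expression

    def fields(self):
        return self.operand.fields()

    def to_text(self):
        return f"(NOT {self.operand.to_text()})"


@dataclass(frozen=True, eq=False)
class Exists(Expression):
    field_name: str

    def fields(self):
        return {self.field_name}

    def to_text(self):
        return f"EXISTS {self.field_name}"


# ---------------------------------------------------------------------------
# Static typing against a field catalogue


def type_errors(expr: Expression, schema: ContextSchema) -> list[str]:
    """Well-typedness check; returns human-readable problems (empty = OK)."""
    errors: list[str] = []

    def kind_of(node: Expression) -> str | None:
        if isinstance(node, Literal):
            return node.kind
        if isinstance(node, FieldRef):
            t = schema.type_of(node.name)
            if t is None:
                errors.append(f"unknown field {node.name!r}")
            return t
        errors.append("comparison operand must be a field or a literal")
        return None

    def walk(node: Expression) -> None:
        if isinstance(node, (And, Or)):
            walk(node.left)
            walk(node.right)
        elif isinstance(node, Not):
            walk(node.operand)
        elif isinstance(node, Exists):
            if node.field_name not in schema:
                errors.append(f"unknown field {node.field_name!r}")
        elif isinstance(node, Comparison):
            lk, rk = kind_of(node.left), kind_of(node.right)
            if lk and rk:
                if lk != rk:
                    errors.append(
                        f"comparison {node.to_text()!r} mixes {lk} and {rk}"
                    )
                elif lk == "boolean" and node.op not in ("==", "!="):
                    errors.append(
                        f"boolean operands only support == and != ({node.to_text()!r})"
                    )
        elif isinstance(node, FieldRef):
            # bare field used as a condition: must be boolean
            t = schema.type_of(node.name)
            if t is None:
                errors.append(f"unknown field {node.name!r}")
            elif t != "boolean":
                errors.append(f"bare field {node.name!r} used as condition is {t}, not boolean")
        elif isinstance(node, Literal):
            if node.kind != "boolean":
                errors.append(f"literal {node.to_text()} is not a condition")
        else:  # pragma: no cover - closed AST
            errors.append(f"unknown node {node!r}")

    walk(expr)
    return errors


# ---------------------------------------------------------------------------
# Evaluation


def eval_expression(
    expr: Expression,
    ctx: PatientContext,
    schema: ContextSchema | None = None,
) -> TruthValue:
    """Evaluate ``expr`` against one patient record, three-valued.

    Any comparison (or bare boolean field) touching a missing field yields
    ``UNKNOWN``; ``EXISTS`` always yields TRUE or FALSE. When ``schema`` is
    given, a present value whose runtime type contradicts the declared field
    type raises :class:`TypeMismatchError`.
    """
    if schema is not None:
        ctx.check_against(schema)

    def operand(node: Expression):
        """Return (value, present). Literals are always present."""
        if isinstance(node, Literal):
            return node.value, True
        if isinstance(node, FieldRef):
            if not ctx.has(node.name):
                return None, False
            return ctx.get(node.name), True
        raise TypeMismatchError(f"cannot evaluate operand {node!r}")

    def ev(node: Expression) -> TruthValue:
        if isinstance(node, And):
            return kleene_and(ev(node.left), ev(node.right))
        if isinstance(node, Or):
            return kleene_or(ev(node.left), ev(node.right))
        if isinstance(node, Not):
            return kleene_not(ev(node.operand))
        if isinstance(node, Exists):
            return TruthValue.of(ctx.has(node.field_name))
        if isinstance(node, Comparison):
            lv, lp = operand(node.left)
            rv, rp = operand(node.right)
            if not (lp and rp):
                return TruthValue.UNKNOWN
            lk, rk = value_kind(lv), value_kind(rv)
            if lk != rk:
                raise TypeMismatchError(
                    f"cannot compare {lk} with {rk} in {node.to_text()!r}"
                )
            if lk == "boolean" and node.op not in ("==", "!="):
                raise TypeMismatchError(
                    f"ordering comparison on booleans in {node.to_text()!r}"
                )
            op = node.op
            if op == "==":
                return TruthValue.of(lv == rv)
            if op == "!=":
                return TruthValue.of(lv != rv)
            if op == "<":
                return TruthValue.of(lv < rv)
            if op == "<=":
                return TruthValue.of(lv <= rv)
            if op == ">":
                return TruthValue.of(lv > rv)
            return TruthValue.of(lv >= rv)
        if isinstance(node, FieldRef):
            if not ctx.has(node.name):
                return TruthValue.UNKNOWN
            v = ctx.get(node.name)
            if not isinstance(v, bool):
                raise TypeMismatchError(
                    f"bare condition field {node.name!r} holds non-boolean {v!r}"
                )
            return TruthValue.of(v)
        if isinstance(node, Literal):
            if isinstance(node.value, bool):
                return TruthValue.of(node.value)
            raise TypeMismatchError(f"literal {node.to_text()} is not a condition")
        raise TypeMismatchError(f"unknown node {node!r}")  # pragma: no cover

    return ev(expr)


# ---------------------------------------------------------------------------
# Parser (shared by the rule DSL and BPMN conditionExpression bodies)

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<date>\d{4}-\d{2}-\d{2})
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<op><=|>=|==|!=|<|>)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "exists", "true", "false"}


@dataclass(frozen=True)
class Token:
    kind: str
    text: str
    line: int
    column: int


def tokenize(text: str, line0: int = 1, col0: int = 1) -> Iterator[Token]:
    """Tokenize expression text, reporting 1-based positions."""
    line, col = line0, col0
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        tok = m.group()
        if kind != "ws":
            k = kind
            if kind == "ident" and tok.lower() in _KEYWORDS:
                k = tok.lower()
            yield Token(k, tok, line, col)
        nl = tok.count("\n")
        if nl:
            line += nl
            col = len(tok) - tok.rfind("\n")
        else:
            col += len(tok)
        pos = m.end()
    yield Token("eof", "", line, col)


def _unquote(s: str) -> str:
    body = s[1:-1]
    return re.sub(r"\\(.)", lambda m: m.group(1), body)


class _ExprParser:
    """Recursive-descent parser; precedence OR < AND < NOT < comparison."""

    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        t = self.cur
        self.i += 1
        return t

    def fail(self, msg: str):
        t = self.cur
        raise ParseError(msg, t.line, t.column)

    def parse(self) -> Expression:
        e = self.or_expr()
        if self.cur.kind != "eof":
            self.fail(f"trailing input {self.cur.text!r}")
        return e

    def or_expr(self) -> Expression:
        e = self.and_expr()
        while self.cur.kind == "or":
            self.advance()
            e = Or(e, self.and_expr())
        return e

    def and_expr(self) -> Expression:
        e = self.not_expr()
        while self.cur.kind == "and":
            self.advance()
            e = And(e, self.not_expr())
        return e

    def not_expr(self) -> Expression:
        if self.cur.kind == "not":
            self.advance()
            return Not(self.not_expr())
        return self.cmp_expr()

    def cmp_expr(self) -> Expression:
        left = self.primary()
        if self.cur.kind == "op":
            op = self.advance().text
            right = self.primary()
            return Comparison(op, left, right)
        return left

    def primary(self) -> Expression:
        t = self.cur
        if t.kind == "lparen":
            self.advance()
            e = self.or_expr()
            if self.cur.kind != "rparen":
                self.fail("expected ')'")
            self.advance()
            return e
        if t.kind == "exists":
            self.advance()
            if self.cur.kind != "ident":
                self.fail("EXISTS requires a field name")
            return Exists(self.advance().text)
        if t.kind == "true":
            self.advance()
            return Literal(True)
        if t.kind == "false":
            self.advance()
            return Literal(False)
        if t.kind == "number":
            self.advance()
            return Literal(float(t.text) if "." in t.text else int(t.text))
        if t.kind == "date":
            self.advance()
            try:
                return Literal(_dt.date.fromisoformat(t.text))
            except ValueError:
                raise ParseError(f"bad date literal {t.text!r}", t.line, t.column)
        if t.kind == "string":
            self.advance()
            return Literal(_unquote(t.text))
        if t.kind == "ident":
            self.advance()
            return FieldRef(t.text)
        found = repr(t.text) if t.text else "end of input"
        self.fail(f"expected an expression, found {found}")


def parse_expression(text: str, line0: int = 1, col0: int = 1) -> Expression:
    """Parse expression text; raises :class:`ParseError` with position."""
    tokens = list(tokenize(text, line0, col0))
    return _ExprParser(tokens).parse()
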