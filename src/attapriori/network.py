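"""Synchronous Boolean networks and the BoolNet-style ``targets, factors`` dialect.

A Boolean network is a set of nodes ``x_1 … x_n``, each carrying a value in
{0, 1}, together with one Boolean update function per node.  Updates are
synchronous: every node recomputes its value from the *same* current global
state.  Global states are represented as tuples of bits in node order; the
equivalent integer encoding places the *last* node ``x_n`` in the least
significant bit, so that within a fixed number of 1-bits the numeric order of
states matches the conventional enumeration 000, 001, 010, 100, …

The text dialect is a compatible subset of the BoolNet network format::

    targets, factors
    x1, x3
    x2, x1 & ! x3
    x3, x1 & ! x2

Operators are ``&`` (AND), ``|`` (OR), ``!`` (NOT), parentheses, and the
constants ``0``/``1``.  ``#`` starts a comment.  Node names are case-sensitive
and may contain letters, digits and ``_ . / -`` (biological models routinely
use slashes and dots in species names).  BoolNet extensions beyond this subset
(probabilistic rules, ``all()``) are rejected with a clear error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Expression",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "BooleanNetwork",
    "NetworkFormatError",
    "State",
    "state_to_int",
    "int_to_state",
    "parse_network",
    "parse_expression",
    "serialize_network",
    "expression_to_str",
    "evaluate",
    "step",
    "truth_table",
]

#: A global network state: one bit per node, in declaration order.
State = tuple[int, ...]

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_./-]*")


class NetworkFormatError(ValueError):
    """Raised for syntax errors, undeclared variables or duplicate nodes."""


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Expression:
    """Base class for Boolean expression nodes."""

    def variables(self) -> tuple[str, ...]:
        """Variables referenced, in order of first appearance."""
        seen: dict[str, None] = {}
        _collect_vars(self, seen)
        return tuple(seen)


@dataclass(frozen=True)
class Var(Expression):
    name: str


@dataclass(frozen=True)
class Not(Expression):
    operand: Expression


@dataclass(frozen=True)
class And(Expression):
    operands: tuple[Expression, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("AND requires at least two operands")


@dataclass(frozen=True)
class Or(Expression):
    operands: tuple[Expression, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("OR requires at least two operands")


@dataclass(frozen=True)
class Const(Expression):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("constant must be 0 or 1")


def _collect_vars(expr: Expression, seen: dict[str, None]) -> None:
    if isinstance(expr, Var):
        seen.setdefault(expr.name, None)
    elif isinstance(expr, Not):
        _collect_vars(expr.operand, seen)
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            _collect_vars(op, seen)


def evaluate(expr: Expression, assignment: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a full variable assignment.

    Raises ``KeyError`` (unbound variable) if a referenced variable is
    missing from the assignment.
    """
    if isinstance(expr, Var):
        return assignment[expr.name] & 1
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, assignment)
    if isinstance(expr, And):
        for op in expr.operands:
            if not evaluate(op, assignment):
                return 0
        return 1
    if isinstance(expr, Or):
        for op in expr.operands:
            if evaluate(op, assignment):
                return 1
        return 0
    raise TypeError(f"unknown expression node {expr!r}")


def _compile_source(expr: Expression, index: Mapping[str, int]) -> str:
    # Python source over a bit sequence `b`; `and`/`or`/`not` short-circuit
    # and return ints via the outer `1 if … else 0` only where needed.
    if isinstance(expr, Var):
        return f"b[{index[expr.name]}]"
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        return f"(1 - ({_compile_source(expr.operand, index)}))"
    if isinstance(expr, And):
        return "(" + " and ".join(_compile_source(o, index) for o in expr.operands) + ")"
    if isinstance(expr, Or):
        return "(" + " or ".join(_compile_source(o, index) for o in expr.operands) + ")"
    raise TypeError(f"unknown expression node {expr!r}")


def expression_to_str(expr: Expression) -> str:
    """Render an expression in the dialect's concrete syntax."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        inner = expression_to_str(expr.operand)
        if isinstance(expr.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = []
        for op in expr.operands:
            s = expression_to_str(op)
            if isinstance(op, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(expression_to_str(op) for op in expr.operands)
    raise TypeError(f"unknown expression node {expr!r}")


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser for rule expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_./-]*)|(?P<const>[01])"
    r"|(?P<op>[&|!()])|(?P<bad>\S))"
)


def _tokenize(text: str, lineno: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        elif m.group("const") is not None:
            tokens.append(("const", m.group("const")))
        elif m.group("op") is not None:
            tokens.append(("op", m.group("op")))
        else:
            raise NetworkFormatError(
                f"line {lineno}: unexpected character {m.group('bad')!r}"
            )
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], lineno: int) -> None:
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise NetworkFormatError(f"line {self.lineno}: unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Expression:
        expr = self.parse_or()
        if self.peek() is not None:
            raise NetworkFormatError(
                f"line {self.lineno}: trailing tokens after expression"
            )
        return expr

    def parse_or(self) -> Expression:
        operands = [self.parse_and()]
        while self.peek() == ("op", "|"):
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and(self) -> Expression:
        operands = [self.parse_unary()]
        while self.peek() == ("op", "&"):
            self.next()
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_unary(self) -> Expression:
        tok = self.next()
        kind, value = tok
        if tok == ("op", "!"):
            return Not(self.parse_unary())
        if tok == ("op", "("):
            expr = self.parse_or()
            if self.next() != ("op", ")"):
                raise NetworkFormatError(f"line {self.lineno}: expected ')'")
            return expr
        if kind == "const":
            return Const(int(value))
        if kind == "name":
            if value == "all" and self.peek() == ("op", "("):
                raise NetworkFormatError(
                    f"line {self.lineno}: the BoolNet 'all()' extension is not supported"
                )
            return Var(value)
        raise NetworkFormatError(f"line {self.lineno}: unexpected token {value!r}")


def parse_expression(text: str, lineno: int = 0) -> Expression:
    """Parse a single rule expression (right-hand side of a rule line)."""
    tokens = _tokenize(text, lineno)
    if not tokens:
        raise NetworkFormatError(f"line {lineno}: empty expression")
    return _Parser(tokens, lineno).parse()


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """A synchronous Boolean network.

    Attributes
    ----------
    node_names:
        Node identifiers in declaration order; node i is ``x_{i+1}``.
    functions:
        One update expression per node, aligned with ``node_names``.
    """

    node_names: tuple[str, ...]
    functions: tuple[Expression, ...]
    _compiled: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        self.functions = tuple(self.functions)
        if len(self.node_names) != len(self.functions):
            raise ValueError("one update function required per node")
        if len(set(self.node_names)) != len(self.node_names):
            raise NetworkFormatError("duplicate node name")
        if not self.node_names:
            raise ValueError("network must have at least one node")
        declared = set(self.node_names)
        for name, fn in zip(self.node_names, self.functions):
            for v in fn.variables():
                if v not in declared:
                    raise NetworkFormatError(
                        f"rule for {name!r} references undeclared variable {v!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.node_names)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.node_names)}

    @property
    def input_sets(self) -> tuple[tuple[str, ...], ...]:
        """IN(x_i): nodes referenced by each update rule, in appearance order."""
        return tuple(fn.variables() for fn in self.functions)

    @property
    def indegrees(self) -> tuple[int, ...]:
        """k_i = |IN(x_i)| per node."""
        return tuple(len(s) for s in self.input_sets)

    def _compile(self):
        if self._compiled is None:
            idx = self.index
            codes = tuple(
                compile(_compile_source(fn, idx), "<rule>", "eval")
                for fn in self.functions
            )
            object.__setattr__(self, "_compiled", codes)
        return self._compiled


def state_to_int(bits: Sequence[int]) -> int:
    """Integer view of a state; the last node ``x_n`` is the least significant bit."""
    v = 0
    for b in bits:
        v = (v << 1) | (b & 1)
    return v


def int_to_state(value: int, n: int) -> State:
    """Inverse of :func:`state_to_int` for an ``n``-node network."""
    if value < 0 or value >= (1 << n):
        raise ValueError(f"integer {value} out of range for {n} bits")
    return tuple((value >> (n - 1 - i)) & 1 for i in range(n))


def step(net: BooleanNetwork, s: State) -> State:
    """One synchronous update: every node recomputes from the same state ``s``."""
    if len(s) != net.n:
        raise ValueError(f"state length {len(s)} != network size {net.n}")
    codes = net._compile()
    scope = {"b": s}
    return tuple(1 if eval(code, {"__builtins__": {}}, scope) else 0 for code in codes)


def truth_table(net: BooleanNetwork, node: int) -> tuple[int, ...]:
    """Output column of node ``node``'s function over all input combinations.

    Inputs are enumerated in the order of ``input_sets[node]`` with the last
    input as the least significant bit (row ``r`` assigns input ``j`` the bit
    ``(r >> (k-1-j)) & 1``).  Used for semantic (round-trip) comparisons.
    """
    inputs = net.input_sets[node]
    k = len(inputs)
    fn = net.functions[node]
    rows = []
    for r in range(1 << k):
        assignment = {
            name: (r >> (k - 1 - j)) & 1 for j, name in enumerate(inputs)
        }
        rows.append(evaluate(fn, assignment))
    return tuple(rows)


# ---------------------------------------------------------------------------
# Dialect reader / writer
# ---------------------------------------------------------------------------

def parse_network(text: str) -> BooleanNetwork:
    """Parse the ``targets, factors`` dialect into a :class:`BooleanNetwork`.

    Errors (undeclared variable, duplicate node, syntax error) are reported
    with the offending line number.
    """
    lines = text.splitlines()
    header_seen = False
    names: list[str] = []
    exprs: list[Expression] = []
    rule_lines: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            normalized = re.sub(r"\s+", "", line.lower())
            if normalized != "targets,factors":
                raise NetworkFormatError(
                    f"line {lineno}: expected header 'targets, factors', got {line!r}"
                )
            header_seen = True
            continue
        if "," not in line:
            raise NetworkFormatError(f"line {lineno}: expected 'name, expression'")
        target, _, rhs = line.partition(",")
        target = target.strip()
        if not NAME_RE.fullmatch(target):
            raise NetworkFormatError(f"line {lineno}: invalid node name {target!r}")
        if "," in rhs:
            raise NetworkFormatError(
                f"line {lineno}: extra comma — probabilistic BoolNet rules are not supported"
            )
        if target in names:
            raise NetworkFormatError(f"line {lineno}: duplicate node name {target!r}")
        names.append(target)
        exprs.append(parse_expression(rhs, lineno))
        rule_lines.append(lineno)
    if not header_seen:
        raise NetworkFormatError("missing 'targets, factors' header")
    if not names:
        raise NetworkFormatError("no rule lines found")
    try:
        return BooleanNetwork(tuple(names), tuple(exprs))
    except NetworkFormatError as exc:
        raise NetworkFormatError(str(exc)) from None


def serialize_network(net: BooleanNetwork) -> str:
    """Write a network back to the dialect; ``parse_network`` round-trips it."""
    lines = ["targets, factors"]
    for name, fn in zip(net.node_names, net.functions):
        lines.append(f"{name}, {expression_to_str(fn)}")
    return "\n".join(lines) + "\n"


#: The three-node network used as the running worked example: f1 = x3,
#: f2 = x1 & !x3, f3 = x1 & !x2.  It has two point attractors, (0,0,0) and
#: (1,0,1), and one periodic attractor of period 2, {(0,1,1),(1,0,0)}.
EXAMPLE_NETWORK_TEXT = """\
targets, factors
x1, x3
x2, x1 & ! x3
x3, x1 & ! x2
"""


def example_network() -> BooleanNetwork:
    """The bundled 3-node worked-example network."""
    return parse_network(EXAMPLE_NETWORK_TEXT)
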