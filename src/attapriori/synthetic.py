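"""Seeded generators for benchmark inputs: random N-K networks, prior-perturbed
guesses, AND/OR functional mutants and random states.

An N-K network assigns every node exactly K distinct input nodes drawn
uniformly at random and an independent uniformly random truth table over the
2^K input rows — the classical random-Boolean-network ensemble.  Truth
tables are stored as equivalent expressions via minterm expansion (an OR of
ANDs of literals), so generated networks serialize losslessly through the
text dialect.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import And, BooleanNetwork, Const, Expression, Not, Or, State, Var

__all__ = [
    "NKConfig",
    "MutationConfig",
    "generate_nk",
    "perturb_state",
    "mutate_functions",
    "random_state",
    "derive_seed",
]

AND_TO_OR = "AND_TO_OR"
OR_TO_AND = "OR_TO_AND"


def derive_seed(master: int, label: str, *indices: int) -> int:
    """A stable sub-seed below 2^31 derived from a master seed and a label.

    Fixed labeled offsets keep every generator in an experiment harness
    reproducible end-to-end from one master seed.
    """
    import zlib

    key = f"{master}:{label}:" + ":".join(map(str, indices))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class NKConfig:
    """Random N-K network ensemble parameters: N nodes, exact indegree K."""

    n: int
    k: int
    seed: int
    allow_self_inputs: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        limit = self.n if self.allow_self_inputs else self.n - 1
        if not 1 <= self.k <= limit:
            raise ValueError(
                f"k={self.k} invalid for n={self.n} "
                f"(self-inputs {'allowed' if self.allow_self_inputs else 'disallowed'})"
            )


@dataclass(frozen=True)
class MutationConfig:
    """Operator-swap mutation: each targeted AND or OR flips with probability rate."""

    rate: float
    direction: str
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0, 1]")
        if self.direction not in (AND_TO_OR, OR_TO_AND):
            raise ValueError(f"direction must be {AND_TO_OR} or {OR_TO_AND}")


def _minterm_expression(inputs: tuple[str, ...], table: np.ndarray) -> Expression:
    """OR-of-ANDs expression with the given truth table.

    Row r assigns input j the bit (r >> (k-1-j)) & 1, matching
    :func:`attapriori.network.truth_table`.
    """
    k = len(inputs)
    ones = [r for r in range(1 << k) if table[r]]
    if not ones:
        return Const(0)
    if len(ones) == 1 << k:
        return Const(1)
    minterms: list[Expression] = []
    for r in ones:
        literals: list[Expression] = []
        for j, name in enumerate(inputs):
            bit = (r >> (k - 1 - j)) & 1
            literals.append(Var(name) if bit else Not(Var(name)))
        minterms.append(literals[0] if len(literals) == 1 else And(tuple(literals)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


def generate_nk(cfg: NKConfig) -> BooleanNetwork:
    """A random N-K network: K uniform distinct inputs and a uniform random
    truth table per node, fully reproducible from the config seed."""
    rng = np.random.default_rng(cfg.seed)
    names = tuple(f"x{i + 1}" for i in range(cfg.n))
    functions: list[Expression] = []
    for i in range(cfg.n):
        pool = np.arange(cfg.n)
        if not cfg.allow_self_inputs:
            pool = np.delete(pool, i)
        chosen = rng.choice(pool, size=cfg.k, replace=False)
        inputs = tuple(names[j] for j in sorted(chosen))
        table = rng.integers(0, 2, size=1 << cfg.k)
        functions.append(_minterm_expression(inputs, table))
    return BooleanNetwork(names, tuple(functions))


def perturb_state(s: State, p: float, seed: int) -> State:
    """Flip each bit independently with probability 1-p (the prior's error rate).

    This is how benchmark guesses are made from a target attractor state:
    the guess agrees with the target on each bit with probability p.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(s)) < (1 - p)
    return tuple(int(b ^ f) for b, f in zip(s, flips))


def random_state(n: int, seed: int) -> State:
    """A uniform random state: each bit an independent fair coin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return tuple(int(b) for b in rng.integers(0, 2, size=n))


def _mutate_expr(expr: Expression, direction: str, rng: np.random.Generator, rate: float) -> Expression:
    if isinstance(expr, (Var, Const)):
        return expr
    if isinstance(expr, Not):
        return Not(_mutate_expr(expr.operand, direction, rng, rate))
    if isinstance(expr, And):
        operands = tuple(_mutate_expr(o, direction, rng, rate) for o in expr.operands)
        if direction == AND_TO_OR and rng.random() < rate:
            return Or(operands)
        return And(operands)
    if isinstance(expr, Or):
        operands = tuple(_mutate_expr(o, direction, rng, rate) for o in expr.operands)
        if direction == OR_TO_AND and rng.random() < rate:
            return And(operands)
        return Or(operands)
    raise TypeError(f"unknown expression node {expr!r}")


def mutate_functions(net: BooleanNetwork, cfg: MutationConfig) -> BooleanNetwork:
    """Swap AND->OR (functional promiscuity) or OR->AND (functional restriction).

    Each operator node of the targeted kind is independently swapped with
    probability ``cfg.rate``; inputs, negations and everything else are
    untouched, and the original network is not modified.
    """
    rng = np.random.default_rng(cfg.seed)
    functions = tuple(
        _mutate_expr(fn, cfg.direction, rng, cfg.rate) for fn in net.functions
    )
    return BooleanNetwork(net.node_names, functions)
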