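"""Prior-guided attractor search (the ATTapriori algorithm).

The search is driven by per-node *a priori* information: a guess bit ``b_i``
for the node's value in some state of the target attractor, and a confidence
``p_i`` that the guess is right.  Start vectors are tried from the most
plausible outward — first the guess itself, then all vectors one flip away,
then two, and so on — so that an informative prior turns the 2^n sweep into
a short walk around the guess.

Confidences below 0.5 are canonicalized away by exchanging the roles of 0
and 1 for that node (guessing 1 with confidence 0.3 is guessing 0 with
confidence 0.7).  After canonicalization nodes fall into confidence classes:
probability-1 bits are never flipped, probability-0.5 bits are uninformed
(enumerated innermost in a seeded random order), and each distinct informed
confidence forms its own class whose flips are rationed by likelihood.

For a single informed class the position of any start vector in the stream
has a closed form: a vector at Hamming distance k from the guess is trial
number ``S(n, k) + rank + 1`` where ``S(n, k)`` counts all vectors at
smaller distances and ``rank`` is the colexicographic rank of the flip
pattern among weight-k patterns (numeric order with x_n least significant).
That rank is O(n) big-integer arithmetic, never enumeration — which is what
makes trial counts of order 10^10 measurable.
"""

from __future__ import annotations

import heapq
import itertools
import math
import random
import time
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .dynamics import Attractor, extract_attractor, simulate_to_attractor
from .network import BooleanNetwork, State
from .theory import prefix_count

__all__ = [
    "PriorSpec",
    "PriorClass",
    "AttractorCriteria",
    "SearchConfig",
    "SearchResult",
    "UnreachableTargetError",
    "canonicalize_prior",
    "rank_start_vector",
    "unrank_start_vector",
    "trial_index_of_target",
    "iterate_start_vectors",
    "attapriori_search",
    "uniform_prior",
]


class UnreachableTargetError(ValueError):
    """Target conflicts with a probability-1 bit of the prior."""


@dataclass(frozen=True)
class PriorClass:
    """Nodes sharing one confidence value; positions are network indices."""

    confidence: float
    positions: tuple[int, ...]

    @property
    def uninformed(self) -> bool:
        return self.confidence == 0.5

    @property
    def fixed(self) -> bool:
        return self.confidence == 1.0


@dataclass(frozen=True)
class PriorSpec:
    """Canonicalized per-node prior: guess bits and confidences in [0.5, 1].

    ``classes`` partition the node positions by distinct confidence, ordered
    by descending confidence (fixed bits first, uninformed last).
    """

    node_names: tuple[str, ...]
    guess: State
    confidence: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.node_names) == len(self.guess) == len(self.confidence)):
            raise ValueError("prior fields must have equal length")
        for p in self.confidence:
            if not 0.5 <= p <= 1.0:
                raise ValueError(f"canonical confidence {p} outside [0.5, 1]")

    @property
    def n(self) -> int:
        return len(self.guess)

    @property
    def classes(self) -> tuple[PriorClass, ...]:
        groups: dict[float, list[int]] = {}
        for i, p in enumerate(self.confidence):
            groups.setdefault(p, []).append(i)
        return tuple(
            PriorClass(p, tuple(pos))
            for p, pos in sorted(groups.items(), key=lambda kv: -kv[0])
        )

    @property
    def flippable_positions(self) -> tuple[int, ...]:
        """Positions that the enumeration may ever change (confidence < 1)."""
        return tuple(i for i, p in enumerate(self.confidence) if p < 1.0)

    @property
    def informed_classes(self) -> tuple[PriorClass, ...]:
        return tuple(c for c in self.classes if not c.fixed and not c.uninformed)

    @property
    def uninformed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.confidence) if p == 0.5)


def canonicalize_prior(
    node_names: Sequence[str],
    guesses: Sequence[int],
    probabilities: Sequence[float],
) -> PriorSpec:
    """Build a :class:`PriorSpec`, exchanging 0/1 roles where probability < 0.5.

    Raw probabilities must lie in (0, 1]; a node guessed ``g`` with
    probability q < 0.5 becomes guess ``1-g`` with confidence 1-q.
    """
    if not (len(node_names) == len(guesses) == len(probabilities)):
        raise ValueError("node_names, guesses and probabilities must align")
    guess: list[int] = []
    conf: list[float] = []
    for name, g, q in zip(node_names, guesses, probabilities):
        if g not in (0, 1):
            raise ValueError(f"guess bit for {name!r} must be 0 or 1")
        if not 0 < q <= 1:
            raise ValueError(f"probability {q} for {name!r} outside (0, 1]")
        if q < 0.5:
            guess.append(1 - g)
            conf.append(1.0 - q)
        else:
            guess.append(g)
            conf.append(float(q))
    return PriorSpec(tuple(node_names), tuple(guess), tuple(conf))


def uniform_prior(node_names: Sequence[str], guess: Sequence[int], p: float) -> PriorSpec:
    """Convenience: the same confidence ``p`` on every node."""
    return canonicalize_prior(node_names, tuple(guess), (p,) * len(guess))


# ---------------------------------------------------------------------------
# Closed-form rank / unrank for a single informed class
# ---------------------------------------------------------------------------

def _require_single_class(prior: PriorSpec) -> tuple[int, ...]:
    flippable = prior.flippable_positions
    confs = {prior.confidence[i] for i in flippable}
    if len(confs) > 1:
        raise ValueError(
            "closed-form ranking requires a single confidence class on flippable bits"
        )
    return flippable

def _colex_rank(cells: Sequence[int]) -> int:
    """Rank of a k-subset of {0,1,…} in colexicographic (numeric) order."""
    return sum(math.comb(c, i + 1) for i, c in enumerate(sorted(cells)))


def _colex_unrank(rank: int, k: int) -> list[int]:
    """Inverse of :func:`_colex_rank` for weight ``k``."""
    cells: list[int] = []
    r = rank
    for i in range(k, 0, -1):
        c = i - 1
        while math.comb(c + 1, i) <= r:
            c += 1
        cells.append(c)
        r -= math.comb(c, i)
    return cells[::-1]


def rank_start_vector(prior: PriorSpec, v: State) -> int:
    """1-based trial index of start vector ``v`` under a single-class prior.

    Computed combinatorially as ``S(m, k) + colex_rank + 1`` over the m
    flippable bits — O(n) arithmetic on big integers, no enumeration.
    """
    flippable = _require_single_class(prior)
    if len(v) != prior.n:
        raise ValueError("state length mismatch")
    fixed_conflicts = [
        prior.node_names[i]
        for i in range(prior.n)
        if prior.confidence[i] == 1.0 and v[i] != prior.guess[i]
    ]
    if fixed_conflicts:
        raise UnreachableTargetError(
            f"target conflicts with probability-1 bits: {fixed_conflicts}"
        )
    m = len(flippable)
    n = prior.n
    # reduced significance: order flippable positions by global significance
    by_sig = sorted(flippable, key=lambda i: n - 1 - i)  # ascending significance
    sig_of = {pos: j for j, pos in enumerate(by_sig)}
    flipped = [sig_of[i] for i in flippable if v[i] != prior.guess[i]]
    k = len(flipped)
    return prefix_count(m, k) + _colex_rank(flipped) + 1


def unrank_start_vector(prior: PriorSpec, index: int) -> State:
    """The start vector emitted at 1-based trial ``index`` (single class)."""
    flippable = _require_single_class(prior)
    m = len(flippable)
    if not 1 <= index <= (1 << m):
        raise ValueError(f"index {index} outside [1, 2^{m}]")
    n = prior.n
    # locate the weight class k with S(m,k) < index <= S(m,k+1)
    k = 0
    s = 0
    while True:
        c = math.comb(m, k)
        if index <= s + c:
            break
        s += c
        k += 1
    flipped_sig = _colex_unrank(index - s - 1, k)
    by_sig = sorted(flippable, key=lambda i: n - 1 - i)
    bits = list(prior.guess)
    for j in flipped_sig:
        pos = by_sig[j]
        bits[pos] = 1 - bits[pos]
    return tuple(bits)


def trial_index_of_target(prior: PriorSpec, target: State) -> int:
    """Exact trial number at which the enumeration examines ``target``.

    This is the modified-search counting used by the theory: it asks when
    the target *state* itself is tried, which upper-bounds the trials of the
    real search (any earlier trial reaching the target attractor stops it).
    """
    return rank_start_vector(prior, target)


# ---------------------------------------------------------------------------
# General stream (multiple classes, thresholds, uninformed bits)
# ---------------------------------------------------------------------------

def _class_subsets_in_numeric_order(
    positions: tuple[int, ...], k: int, n: int
) -> Iterator[tuple[int, ...]]:
    """Weight-k subsets of class positions, ordered by flip-pattern numeric value."""
    by_sig = sorted(positions, key=lambda i: n - 1 - i)  # ascending significance
    # colex order over significance indices == increasing numeric value
    for combo in _colex_combinations(len(by_sig), k):
        yield tuple(by_sig[j] for j in combo)


def _colex_combinations(m: int, k: int) -> Iterator[tuple[int, ...]]:
    """All k-subsets of range(m) in colexicographic order."""
    def gen(kk: int, top: int) -> Iterator[tuple[int, ...]]:
        if kk == 0:
            yield ()
            return
        for largest in range(kk - 1, top):
            for rest in gen(kk - 1, largest):
                yield rest + (largest,)

    yield from gen(k, m)


def _uninformed_order(n2: int, seed: int, pattern_index: int) -> Iterator[int]:
    """Seeded pseudo-random order over the 2^n2 uninformed assignments.

    Deterministic in ``(seed, pattern_index)`` so the stream is reproducible
    without storing permutations.  Small blocks use a Fisher–Yates shuffle;
    large blocks use a lazy affine bijection j -> (a*j + b) mod 2^n2.
    """
    size = 1 << n2
    rng = random.Random(f"{seed}:{pattern_index}:uninformed")
    if n2 <= 16:
        order = list(range(size))
        rng.shuffle(order)
        yield from order
    else:
        a = rng.randrange(1, size, 2)  # odd => invertible mod 2^n2
        b = rng.randrange(size)
        for j in range(size):
            yield (a * j + b) % size


@dataclass(frozen=True)
class AttractorCriteria:
    """What makes a detected attractor a desired one.

    ``required_values`` must hold in *every* cycle state by default (a stable
    signature); set ``require_in_all=False`` to accept a value held in some
    state.  ``accept_any`` accepts the first attractor found.
    """

    period_min: int | None = None
    period_max: int | None = None
    required_values: Mapping[str, int] | None = None
    accept_any: bool = False
    require_in_all: bool = True

    def __post_init__(self) -> None:
        if (
            self.period_min is not None
            and self.period_max is not None
            and self.period_min > self.period_max
        ):
            raise ValueError("period_min > period_max")

    def matches(self, att: Attractor, node_names: Sequence[str]) -> bool:
        if self.accept_any:
            return True
        if self.period_min is not None and att.period < self.period_min:
            return False
        if self.period_max is not None and att.period > self.period_max:
            return False
        if self.required_values:
            index = {name: i for i, name in enumerate(node_names)}
            for name, bit in self.required_values.items():
                if name not in index:
                    raise KeyError(f"criteria references unknown node {name!r}")
                i = index[name]
                holds = [s[i] == bit for s in att.cycle]
                if self.require_in_all and not all(holds):
                    return False
                if not self.require_in_all and not any(holds):
                    return False
        return True


@dataclass(frozen=True)
class SearchConfig:
    """Termination and ordering knobs for a search run."""

    step_cap: int | None = None
    max_trials: int | None = None
    time_limit: float | None = None
    class_thresholds: Mapping[float, int] | None = None
    seed: int = 0
    mode: str = "first_hit"  # or "collect_all"

    def __post_init__(self) -> None:
        if self.mode not in ("first_hit", "collect_all"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SearchResult:
    """Outcome of a search: attractors in discovery order plus accounting."""

    attractors: list[Attractor] = field(default_factory=list)
    trials_used: int = 0
    total_transient_steps: int = 0
    truncated_trials: int = 0
    termination_reason: str = "exhausted"


def iterate_start_vectors(prior: PriorSpec, config: SearchConfig | None = None) -> Iterator[State]:
    """The full start-vector stream in prior-likelihood order.

    Flip-count tuples over the informed classes are enumerated in
    nondecreasing total log-odds cost sum_c k_c * ln(p_c/(1-p_c)), ties by
    fewer total flips then lexicographic tuple; within a tuple the Cartesian
    product of per-class constant-weight flip patterns runs with
    higher-confidence classes varying slower, each class in numeric order.
    Uninformed (p = 0.5) bits are enumerated innermost, in a seeded random
    order that is complete over their 2^n2 assignments.  Probability-1 bits
    never change.  With no thresholds the stream is a permutation of all
    assignments to the flippable bits.
    """
    if config is None:
        config = SearchConfig()
    n = prior.n
    informed = prior.informed_classes
    uninformed = prior.uninformed_positions
    n2 = len(uninformed)
    thresholds = config.class_thresholds or {}

    def cap(cls: PriorClass) -> int:
        limit = thresholds.get(cls.confidence, len(cls.positions))
        return min(limit, len(cls.positions))

    costs = [math.log(c.confidence / (1 - c.confidence)) for c in informed]
    h = len(informed)

    # lazily enumerate flip-count tuples by nondecreasing cost via a heap;
    # each tuple is generated once by incrementing classes left-to-right
    heap: list[tuple[float, int, tuple[int, ...]]] = []
    start = (0,) * h
    heapq.heappush(heap, (0.0, 0, start))
    seen = {start}
    pattern_index = 0
    while heap:
        cost, total, tup = heapq.heappop(heap)
        # successors: increment class c for c >= last nonzero index
        last_nz = 0
        for c in range(h - 1, -1, -1):
            if tup[c] > 0:
                last_nz = c
                break
        for c in range(last_nz, h):
            if tup[c] < cap(informed[c]):
                nxt = tup[:c] + (tup[c] + 1,) + tup[c + 1 :]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, (cost + costs[c], total + 1, nxt))
        # emit all start vectors for this tuple
        per_class = [
            list(_class_subsets_in_numeric_order(informed[c].positions, tup[c], n))
            for c in range(h)
        ]
        for flip_sets in itertools.product(*per_class):
            bits = list(prior.guess)
            for fs in flip_sets:
                for pos in fs:
                    bits[pos] = 1 - bits[pos]
            if n2 == 0:
                yield tuple(bits)
            else:
                for pat in _uninformed_order(n2, config.seed, pattern_index):
                    out = bits[:]
                    for j, pos in enumerate(uninformed):
                        # x_n least significant within the uninformed block
                        out[pos] = prior.guess[pos] ^ ((pat >> (n2 - 1 - j)) & 1)
                    yield tuple(out)
            pattern_index += 1


def attapriori_search(
    net: BooleanNetwork,
    prior: PriorSpec,
    criteria: AttractorCriteria | None = None,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Run trials from prior-ordered start vectors until a desired attractor.

    Each trial simulates the trajectory from the next start vector to its
    first repeated state and extracts the attractor.  ``first_hit`` mode
    stops at the first attractor satisfying the criteria; ``collect_all``
    runs to exhaustion or limits, deduplicating canonical attractors but
    preserving discovery order.  Trials truncated by the step cap count as
    failed.  The time limit is checked between trials; the trial limit is
    exact.
    """
    if criteria is None:
        criteria = AttractorCriteria(accept_any=True)
    if config is None:
        config = SearchConfig()
    if tuple(prior.node_names) != tuple(net.node_names):
        raise ValueError("prior and network node sets differ")
    result = SearchResult()
    seen: set[Attractor] = set()
    t0 = time.monotonic()
    for start in iterate_start_vectors(prior, config):
        if config.max_trials is not None and result.trials_used >= config.max_trials:
            result.termination_reason = "trial_limit"
            return result
        if config.time_limit is not None and time.monotonic() - t0 > config.time_limit:
            result.termination_reason = "time_limit"
            return result
        result.trials_used += 1
        traj = simulate_to_attractor(net, start, config.step_cap)
        if traj.truncated:
            result.truncated_trials += 1
            continue
        result.total_transient_steps += traj.transient_length
        att = extract_attractor(traj)
        if att not in seen:
            if config.mode == "first_hit":
                if criteria.matches(att, net.node_names):
                    result.attractors.append(att)
                    result.termination_reason = "criteria_met"
                    return result
                seen.add(att)
            else:
                seen.add(att)
                result.attractors.append(att)
    result.termination_reason = "exhausted"
    return result
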