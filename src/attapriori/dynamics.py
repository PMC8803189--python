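"""Trajectory simulation, attractor extraction and exhaustive enumeration.

Under synchronous updates every trajectory is eventually periodic: iterating
the update map from any start state must revisit a state, and the segment
between the first repeat and its earlier occurrence is an attractor (a point
attractor if the period is 1).  Simulation keeps a visited-map from state
integer to time index so the first repeat and its position t' are found in a
single pass; memory is proportional to the trajectory length.

Attractors are canonicalized by rotating the cycle to start at the
numerically smallest state (x_n least significant), which makes attractor
identity independent of the phase at which a trajectory entered the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import BooleanNetwork, State, int_to_state, state_to_int, step

__all__ = [
    "Trajectory",
    "Attractor",
    "TruncatedTrajectoryError",
    "simulate_to_attractor",
    "extract_attractor",
    "enumerate_all_attractors",
    "attractor_basins",
    "default_step_cap",
]


class TruncatedTrajectoryError(RuntimeError):
    """Raised when an attractor is requested from a capped trajectory."""


@dataclass
class Trajectory:
    """A simulated state sequence x(0) … x(T).

    ``cycle_entry`` is the index t' with step(x(T)) = x(t'); it is ``None``
    when the walk was truncated by the step cap before any repeat.  The
    transient length (states strictly before the cycle) equals ``cycle_entry``.
    """

    states: list[State]
    cycle_entry: int | None
    truncated: bool

    @property
    def transient_length(self) -> int:
        """Steps before entering the cycle; excludes the cycle itself."""
        if self.cycle_entry is None:
            raise TruncatedTrajectoryError("trajectory was truncated before a repeat")
        return self.cycle_entry


@dataclass(frozen=True)
class Attractor:
    """A cycle of states closed under the synchronous step, in canonical phase."""

    cycle: tuple[State, ...]
    canonical: bool = True

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def is_point(self) -> bool:
        return len(self.cycle) == 1


def canonical_cycle(cycle: tuple[State, ...]) -> tuple[State, ...]:
    """Rotate a cycle to start at its numerically smallest state."""
    ints = [state_to_int(s) for s in cycle]
    start = ints.index(min(ints))
    return cycle[start:] + cycle[:start]


def default_step_cap(n: int) -> int:
    """Default trajectory cap, 100·n steps.

    Transients in practically occurring Boolean networks are short (averages
    stay below a few hundred even at n = 100 for K = 2 random networks), so
    a linear cap leaves ample headroom while keeping every trial bounded.
    """
    return 100 * n


def simulate_to_attractor(
    net: BooleanNetwork, start: State, step_cap: int | None = None
) -> Trajectory:
    """Iterate the synchronous step from ``start`` until the first repeat.

    Returns a :class:`Trajectory` whose ``cycle_entry`` marks the start of
    the attractor, or a truncated trajectory after exactly ``step_cap`` steps
    if no state repeated.
    """
    if step_cap is None:
        step_cap = default_step_cap(net.n)
    if step_cap < 1:
        raise ValueError("step_cap must be >= 1")
    if len(start) != net.n:
        raise ValueError(f"state length {len(start)} != network size {net.n}")
    states: list[State] = [tuple(start)]
    visited: dict[int, int] = {state_to_int(start): 0}
    current = tuple(start)
    for _ in range(step_cap):
        current = step(net, current)
        key = state_to_int(current)
        if key in visited:
            return Trajectory(states, visited[key], truncated=False)
        visited[key] = len(states)
        states.append(current)
    return Trajectory(states, None, truncated=True)


def extract_attractor(traj: Trajectory) -> Attractor:
    """The canonical attractor at the end of a non-truncated trajectory."""
    if traj.truncated or traj.cycle_entry is None:
        raise TruncatedTrajectoryError("cannot extract an attractor from a truncated trajectory")
    cycle = tuple(traj.states[traj.cycle_entry :])
    return Attractor(canonical_cycle(cycle))


def attractor_basins(
    net: BooleanNetwork, n_limit: int = 20
) -> dict[Attractor, int]:
    """All attractors with basin sizes, by memoized walks over all 2^n states.

    Every state is walked at most once: each walk follows the step map until
    it meets a state already assigned to an attractor or revisits itself (in
    which case the closing segment is a new attractor); the whole path is
    then assigned.  Basin sizes therefore sum to 2^n.
    """
    n = net.n
    if n > n_limit:
        raise ValueError(f"network size {n} exceeds enumeration limit {n_limit}")
    assignment: dict[int, int] = {}
    attractors: list[Attractor] = []
    counts: list[int] = []
    for s0 in range(1 << n):
        if s0 in assignment:
            continue
        path: list[int] = []
        position: dict[int, int] = {}
        current = s0
        while current not in assignment and current not in position:
            position[current] = len(path)
            path.append(current)
            current = state_to_int(step(net, int_to_state(current, n)))
        if current in assignment:
            aid = assignment[current]
        else:
            entry = position[current]
            cycle = tuple(int_to_state(v, n) for v in path[entry:])
            attractors.append(Attractor(canonical_cycle(cycle)))
            counts.append(0)
            aid = len(attractors) - 1
        for v in path:
            assignment[v] = aid
            counts[aid] += 1
    return dict(zip(attractors, counts))


def enumerate_all_attractors(net: BooleanNetwork, n_limit: int = 20) -> set[Attractor]:
    """Exact attractor set of a small network (n ≤ ``n_limit``), canonical forms."""
    return set(attractor_basins(net, n_limit=n_limit))
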