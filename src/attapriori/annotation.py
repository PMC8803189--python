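"""Biological interpretation of detected attractors.

Three families of rules are implemented:

* **Behavior markers** — an attractor is assigned a behavior label (e.g. the
  endothelial-cell behaviors phalanx / stalk / tip) only when every marker
  the signature names holds its required value in *every* cycle state; an
  oscillating marker or a non-matching stable signature makes the attractor
  atypical.  The default EC scheme is phalanx: AKT=1, JAGa=0, NRP1=0;
  stalk: JAGa=1, NRP1=0; tip: NRP1=1, DLL4a=1, AKT=0.  Signatures may be
  partial: markers a behavior does not name are unconstrained.

* **Validity and viability** for bipartite Boolean models — each macroscopic
  process is an ordered group of mutually exclusive stage nodes (e.g. DNA
  licensed / replicating / replicated) of which exactly one must be true at
  any time.  An attractor is *valid* iff every group has exactly one true
  member in every cycle state (and every required component, if any, is
  represented).  A valid attractor is *viable* iff it is periodic and its
  cycle traverses every stage of every group; point attractors are always
  lethal.

* **Absent components** — in a bipartite model a component whose every state
  node is constitutively 0 has de facto been deleted (no synthesis occurs).
  Comparing against a reference attractor identifies such in-silico deletion
  mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dynamics import Attractor

__all__ = [
    "MarkerScheme",
    "ExclusiveGroup",
    "ComponentMap",
    "AttractorAnnotation",
    "AbsenceReport",
    "AnnotationConfigError",
    "EC_MARKER_SCHEME",
    "classify_behavior",
    "check_validity",
    "call_viability",
    "absent_components",
    "dedupe_and_census",
]

ATYPICAL = "atypical"
VALID = "valid"
INVALID = "invalid"
VIABLE = "viable"
LETHAL = "lethal"


class AnnotationConfigError(ValueError):
    """Unknown nodes or overlapping marker signatures on a concrete attractor."""


@dataclass(frozen=True)
class MarkerScheme:
    """Behavior label -> required marker values; non-matches get ``atypical_label``."""

    behaviors: Mapping[str, Mapping[str, int]]
    atypical_label: str = ATYPICAL


#: The endothelial-cell behavior signatures over the four marker nodes.
EC_MARKER_SCHEME = MarkerScheme(
    behaviors={
        "phalanx": {"AKT": 1, "JAGa": 0, "NRP1": 0},
        "stalk": {"JAGa": 1, "NRP1": 0},
        "tip": {"NRP1": 1, "DLL4a": 1, "AKT": 0},
    }
)


@dataclass(frozen=True)
class ExclusiveGroup:
    """A macroscopic process: ordered stage nodes, exactly one true at a time."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"group {self.name!r} needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.name!r} has duplicate members")


#: Component name -> the node names representing its states.
ComponentMap = Mapping[str, frozenset[str] | set[str] | tuple[str, ...]]


@dataclass
class AttractorAnnotation:
    """Combined verdicts for one attractor."""

    validity: str
    label: str | None = None  # behavior label or viable/lethal
    absent: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)


def _index(node_names: Sequence[str]) -> dict[str, int]:
    return {name: i for i, name in enumerate(node_names)}


def _require_nodes(names: Iterable[str], index: Mapping[str, int], what: str) -> None:
    missing = [n for n in names if n not in index]
    if missing:
        raise AnnotationConfigError(f"{what} references unknown nodes: {missing}")


def classify_behavior(
    att: Attractor, scheme: MarkerScheme, node_names: Sequence[str]
) -> str:
    """Behavior label of an attractor, or the atypical label.

    A behavior matches only when each of its markers is *stable* at the
    required value across the whole cycle.  If a user scheme lets two
    behaviors match the same attractor, that is a configuration error.
    """
    index = _index(node_names)
    matches: list[str] = []
    for label, signature in scheme.behaviors.items():
        _require_nodes(signature, index, f"behavior {label!r}")
        if all(
            all(state[index[node]] == bit for state in att.cycle)
            for node, bit in signature.items()
        ):
            matches.append(label)
    if len(matches) > 1:
        raise AnnotationConfigError(
            f"marker signatures overlap on this attractor: {matches}"
        )
    return matches[0] if matches else scheme.atypical_label


def check_validity(
    att: Attractor,
    groups: Sequence[ExclusiveGroup],
    node_names: Sequence[str],
    required_components: ComponentMap | None = None,
) -> tuple[str, list[str]]:
    """Valid iff every group has exactly one true member in every cycle state
    and every required component has at least one true node in every state.

    Returns ``(verdict, violations)`` where each violation names the group or
    component and the 0-based cycle-state index.
    """
    index = _index(node_names)
    violations: list[str] = []
    for group in groups:
        _require_nodes(group.members, index, f"group {group.name!r}")
        for t, state in enumerate(att.cycle):
            true_members = [m for m in group.members if state[index[m]] == 1]
            if len(true_members) != 1:
                violations.append(
                    f"group {group.name!r} has {len(true_members)} true members "
                    f"in cycle state {t}"
                )
    for comp, nodes in (required_components or {}).items():
        _require_nodes(nodes, index, f"component {comp!r}")
        for t, state in enumerate(att.cycle):
            if not any(state[index[n]] == 1 for n in nodes):
                violations.append(
                    f"required component {comp!r} absent in cycle state {t}"
                )
    return (VALID if not violations else INVALID), violations


def call_viability(
    att: Attractor, groups: Sequence[ExclusiveGroup], node_names: Sequence[str]
) -> str:
    """Viable iff periodic and every stage of every group is reached in the cycle.

    Must only be called on valid attractors (a point attractor can be valid —
    one stage stuck true — but is always lethal: the processes never traverse).
    """
    verdict, violations = check_validity(att, groups, node_names)
    if verdict != VALID:
        raise ValueError(f"viability is defined only for valid attractors: {violations}")
    if att.is_point:
        return LETHAL
    index = _index(node_names)
    for group in groups:
        for member in group.members:
            if not any(state[index[member]] == 1 for state in att.cycle):
                return LETHAL
    return VIABLE


@dataclass
class AbsenceReport:
    """Components constitutively off in an attractor but active in the reference."""

    absent: list[str]
    residue: list[str]  # constitutively-zero nodes not covered by any component


def absent_components(
    att: Attractor,
    ref: Attractor,
    cmap: ComponentMap,
    node_names: Sequence[str],
) -> AbsenceReport:
    """Identify de facto deletion mutants relative to a reference attractor.

    A component is absent when all of its nodes are 0 in every state of
    ``att`` while at least one of them is 1 somewhere in ``ref``.  Nodes
    constitutively 0 in ``att`` but not covered by any component are listed
    as residue.
    """
    index = _index(node_names)
    for comp, nodes in cmap.items():
        _require_nodes(nodes, index, f"component {comp!r}")
    const_zero = {
        name
        for name, i in index.items()
        if all(state[i] == 0 for state in att.cycle)
    }
    absent: list[str] = []
    covered: set[str] = set()
    for comp, nodes in cmap.items():
        nodes = set(nodes)
        covered |= nodes
        if nodes <= const_zero and any(
            any(state[index[n]] == 1 for state in ref.cycle) for n in nodes
        ):
            absent.append(comp)
    residue = sorted((const_zero - covered), key=list(index).index)
    return AbsenceReport(absent=absent, residue=residue)


def dedupe_and_census(
    attractors: Sequence[Attractor],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unique attractors with counts by period (and label when provided).

    Input attractors must be canonical so that phase-shifted copies of the
    same cycle collapse to one row.  Counts partition the input.
    """
    if labels is not None and len(labels) != len(attractors):
        raise ValueError("labels must align with attractors")
    rows: dict[tuple, dict] = {}
    for i, att in enumerate(attractors):
        key = (att.cycle, labels[i] if labels is not None else None)
        if key not in rows:
            rows[key] = {
                "period": att.period,
                "kind": "point" if att.is_point else "periodic",
                "label": labels[i] if labels is not None else None,
                "count": 0,
            }
        rows[key]["count"] += 1
    df = pd.DataFrame(list(rows.values()), columns=["period", "kind", "label", "count"])
    if labels is None:
        df = df.drop(columns=["label"])
    return df.sort_values(["period", "count"], ignore_index=True)
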