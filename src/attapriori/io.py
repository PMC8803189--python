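"""Readers and writers for the tool's tabular side formats.

* Prior file: TSV with header ``node<TAB>guess<TAB>prob``; guess in {0, 1},
  prob in (0, 1].  Probability 0.5 marks an uninformed node.  Network nodes
  absent from the file default to uninformed with guess 0 (logged).
* Groups file: TSV ``group<TAB>node``; row order defines the stage order.
* Marker file: TSV ``behavior<TAB>node<TAB>value``.
* Component map: TSV ``component<TAB>node``.
* Attractors: JSON lines (one object per attractor) and a CSV summary.
* Run manifest: JSON with the resolved config, seed and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import ExclusiveGroup, MarkerScheme
from .dynamics import Attractor
from .network import BooleanNetwork
from .search import PriorSpec, canonicalize_prior

__all__ = [
    "read_prior_tsv",
    "write_prior_tsv",
    "read_groups_tsv",
    "read_markers_tsv",
    "read_components_tsv",
    "attractors_to_records",
    "write_attractors_jsonl",
    "write_attractors_csv",
    "write_manifest",
    "file_digest",
]

logger = logging.getLogger("attapriori")


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != list(columns):
        raise ValueError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    return df


def read_prior_tsv(path: str | Path, net: BooleanNetwork) -> PriorSpec:
    """Load and canonicalize a prior for ``net``'s node set.

    Nodes missing from the file become uninformed (guess 0, prob 0.5) and
    are logged; nodes unknown to the network are an error.
    """
    df = _read_tsv(path, ["node", "guess", "prob"])
    known = set(net.node_names)
    unknown = [n for n in df["node"] if n not in known]
    if unknown:
        raise ValueError(f"{path}: prior names nodes not in the network: {unknown}")
    if df["node"].duplicated().any():
        dupes = sorted(df.loc[df["node"].duplicated(), "node"])
        raise ValueError(f"{path}: duplicate prior rows for {dupes}")
    by_node = {row["node"]: row for _, row in df.iterrows()}
    guesses, probs = [], []
    defaulted = []
    for name in net.node_names:
        if name in by_node:
            guesses.append(int(by_node[name]["guess"]))
            probs.append(float(by_node[name]["prob"]))
        else:
            guesses.append(0)
            probs.append(0.5)
            defaulted.append(name)
    if defaulted:
        logger.info(
            "%d nodes absent from prior file default to uninformed: %s",
            len(defaulted),
            ", ".join(defaulted[:10]) + ("…" if len(defaulted) > 10 else ""),
        )
    return canonicalize_prior(net.node_names, guesses, probs)


def write_prior_tsv(path: str | Path, prior: PriorSpec) -> None:
    pd.DataFrame(
        {
            "node": prior.node_names,
            "guess": prior.guess,
            "prob": prior.confidence,
        }
    ).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> list[ExclusiveGroup]:
    df = _read_tsv(path, ["group", "node"])
    groups = []
    for name, sub in df.groupby("group", sort=False):
        groups.append(ExclusiveGroup(str(name), tuple(sub["node"])))
    return groups


def read_markers_tsv(path: str | Path) -> MarkerScheme:
    df = _read_tsv(path, ["behavior", "node", "value"])
    behaviors: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        behaviors.setdefault(str(row["behavior"]), {})[str(row["node"])] = int(
            row["value"]
        )
    return MarkerScheme(behaviors=behaviors)


def read_components_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    df = _read_tsv(path, ["component", "node"])
    cmap: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        cmap.setdefault(str(row["component"]), set()).add(str(row["node"]))
    return {k: frozenset(v) for k, v in cmap.items()}


def attractors_to_records(
    attractors: Iterable[Attractor],
    node_names: Sequence[str],
    transients: Sequence[int] | None = None,
) -> list[dict]:
    """One record per attractor: period, cycle as bit strings, canonical flag."""
    records = []
    for i, att in enumerate(attractors):
        rec = {
            "period": att.period,
            "kind": "point" if att.is_point else "periodic",
            "cycle": ["".join(map(str, s)) for s in att.cycle],
            "canonical": att.canonical,
            "nodes": list(node_names),
        }
        if transients is not None:
            rec["transient"] = transients[i]
        records.append(rec)
    return records


def write_attractors_jsonl(path: str | Path, records: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def write_attractors_csv(path: str | Path, records: list[dict]) -> None:
    rows = [
        {
            "period": rec["period"],
            "kind": rec["kind"],
            "cycle": ";".join(rec["cycle"]),
            "canonical": rec["canonical"],
            **({"transient": rec["transient"]} if "transient" in rec else {}),
        }
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    config: dict,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
    started: str = "",
    finished: str = "",
) -> None:
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "version": __version__,
        "started": started,
        "finished": finished,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
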