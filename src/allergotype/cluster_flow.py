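"""Longitudinal flows of component clusters across ages.

Clusterings are inferred independently at each age; this module links them
post hoc.  Every component of the ever-active universe routes, between two
adjacent ages, from the cluster containing it (or the "inactive" node) to
its cluster at the next age (or "inactive").  Edge weights count shared
components, so weights out of a node always sum to its member count —
components are conserved.

Flow topology is then summarized into qualitative per-cluster events
(persist / split / absorb / newly-formed / reabsorbed / dropout).  The
continuation of a cluster B at age t+1 is defined as the heaviest incoming
source whose own dominant target is B; this prevents a large donor that
mostly persists elsewhere from claiming B, and reproduces the narrative
patterns these flows are meant to expose (a stable mite cluster persisting,
a grass cluster absorbing new members, a singleton reabsorbed into a broad
cluster, one cluster dividing in two).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .panel_io import ACTIVE, ActivityTimeline

__all__ = [
    "INACTIVE_NODE",
    "FlowGraph",
    "FlowEvent",
    "flow_edges",
    "build_flow_graph",
    "summarize_flows",
    "membership_timeline",
]

INACTIVE_NODE = "inactive"

PERSIST = "persist"
SPLIT = "split"
ABSORB = "absorb"
NEWLY_FORMED = "newly-formed"
REABSORBED = "reabsorbed"
DROPOUT = "dropout"


@dataclass
class FlowGraph:
    """Weighted component flows between clusterings at adjacent ages.

    ``clusterings[age]`` maps cluster label -> set of member components
    (the inactive node is implicit).  ``edges`` rows:
    (age_from, cluster_from, age_to, cluster_to, weight, members).
    """

    ages: list[str]
    universe: list[str]
    clusterings: dict[str, dict[object, set]]
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["age_from", "cluster_from", "age_to", "cluster_to", "weight", "members"]
        )
    )

    def layer(self, age_from: str, age_to: str) -> pd.DataFrame:
        e = self.edges
        return e[(e["age_from"] == age_from) & (e["age_to"] == age_to)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for age in self.ages:
            for label, members in self.clusterings[age].items():
                g.add_node((age, label), members=sorted(members))
            g.add_node((age, INACTIVE_NODE))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                (row.age_from, row.cluster_from),
                (row.age_to, row.cluster_to),
                weight=int(row.weight),
                members=list(row.members),
            )
        return g

    def to_json(self, path: str | Path) -> None:
        """Dump nodes and edges as JSON suitable for alluvial plotting."""
        payload = {
            "ages": self.ages,
            "nodes": [
                {
                    "age": age,
                    "cluster": str(label),
                    "members": sorted(members),
                }
                for age in self.ages
                for label, members in self.clusterings[age].items()
            ],
            "edges": [
                {
                    "age_from": r.age_from,
                    "cluster_from": str(r.cluster_from),
                    "age_to": r.age_to,
                    "cluster_to": str(r.cluster_to),
                    "weight": int(r.weight),
                    "members": sorted(r.members),
                }
                for r in self.edges.itertuples(index=False)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class FlowEvent:
    """One qualitative event at a transition: ``side`` is "source" (cluster
    at age_from) or "target" (cluster at age_to)."""

    age_from: str
    age_to: str
    cluster: object
    side: str
    label: str


def _route(members: Mapping[object, set], component: str) -> object:
    for label, mset in members.items():
        if component in mset:
            return label
    return INACTIVE_NODE


def flow_edges(
    members_t: Mapping[object, set],
    members_t1: Mapping[object, set],
    universe: Sequence[str],
    age_from: str = "t",
    age_to: str = "t+1",
) -> pd.DataFrame:
    """One flow layer: edge (A -> B) weight = |A's members also in B| over
    ``universe``; components inactive on either side route through the
    inactive node.  Clusters within an age must be disjoint."""
    for members, age in ((members_t, age_from), (members_t1, age_to)):
        seen: set = set()
        for label, mset in members.items():
            overlap = seen & set(mset)
            if overlap:
                raise ValueError(
                    f"overlapping clusters at age {age}: component(s) {sorted(overlap)} "
                    "appear in more than one cluster"
                )
            seen |= set(mset)
    flows: dict[tuple, list] = {}
    for comp in universe:
        src = _route(members_t, comp)
        dst = _route(members_t1, comp)
        flows.setdefault((src, dst), []).append(comp)
    rows = [
        {
            "age_from": age_from,
            "cluster_from": src,
            "age_to": age_to,
            "cluster_to": dst,
            "weight": len(comps),
            "members": tuple(comps),
        }
        for (src, dst), comps in flows.items()
    ]
    return pd.DataFrame(rows, columns=["age_from", "cluster_from", "age_to", "cluster_to", "weight", "members"])


def build_flow_graph(
    clusterings: Mapping[str, Mapping[object, set]],
    universe: Sequence[str],
    ages: Sequence[str] | None = None,
) -> FlowGraph:
    """Assemble all adjacent-age layers into a :class:`FlowGraph`."""
    ages = list(ages) if ages is not None else list(clusterings)
    layers = [
        flow_edges(clusterings[a], clusterings[b], universe, age_from=a, age_to=b)
        for a, b in zip(ages, ages[1:])
    ]
    edges = (
        pd.concat(layers, ignore_index=True)
        if layers
        else FlowGraph(ages=[], universe=[], clusterings={}).edges
    )
    return FlowGraph(
        ages=ages,
        universe=list(universe),
        clusterings={a: {k: set(v) for k, v in clusterings[a].items()} for a in ages},
        edges=edges,
    )


def summarize_flows(graph: FlowGraph, min_weight: int = 1) -> list[FlowEvent]:
    """Deterministic event labels from edge topology, per transition.

    Source side: ``dropout`` (all members to inactive), ``split`` (>= 2
    substantial outgoing edges to clusters), ``persist`` (single target that
    continues this cluster), ``reabsorbed`` (single target continuing a
    different cluster).  Target side: ``absorb`` (>= 2 substantial incoming
    cluster edges), ``newly-formed`` (no incoming cluster is continued here).
    Substantial means weight >= ``min_weight`` (default 1: single-component
    moves count).  Labels are invariant to cluster label permutations.
    """
    events: list[FlowEvent] = []
    for a, b in zip(graph.ages, graph.ages[1:]):
        layer = graph.layer(a, b)
        cl = layer[
            (layer["cluster_from"] != INACTIVE_NODE)
            & (layer["cluster_to"] != INACTIVE_NODE)
            & (layer["weight"] >= min_weight)
        ]
        sources = [s for s in graph.clusterings[a] if graph.clusterings[a][s]]
        targets = [t for t in graph.clusterings[b] if graph.clusterings[b][t]]

        def dominant_target(src):
            sub = cl[cl["cluster_from"] == src]
            if sub.empty:
                return None
            best = sub.loc[sub["weight"].idxmax()]
            return best["cluster_to"]

        # continuation of target B: heaviest source whose dominant target is B
        continues: dict[object, object] = {}
        for tgt in targets:
            candidates = cl[
                (cl["cluster_to"] == tgt)
                & cl["cluster_from"].map(lambda s, t=tgt: dominant_target(s) == t)
            ]
            if not candidates.empty:
                continues[tgt] = candidates.loc[candidates["weight"].idxmax()]["cluster_from"]

        # source labels are not exclusive: a cluster that donates a minor
        # slice elsewhere while its dominant edge continues is persist+split
        for src in sources:
            out = cl[cl["cluster_from"] == src]
            if out.empty:
                events.append(FlowEvent(a, b, src, "source", DROPOUT))
                continue
            if len(out) >= 2:
                events.append(FlowEvent(a, b, src, "source", SPLIT))
            dom = out.loc[out["weight"].idxmax()]["cluster_to"]
            if continues.get(dom) == src:
                events.append(FlowEvent(a, b, src, "source", PERSIST))
            elif len(out) == 1:
                events.append(FlowEvent(a, b, src, "source", REABSORBED))
        for tgt in targets:
            inc = cl[cl["cluster_to"] == tgt]
            if len(inc) >= 2:
                events.append(FlowEvent(a, b, tgt, "target", ABSORB))
            if tgt not in continues:
                events.append(FlowEvent(a, b, tgt, "target", NEWLY_FORMED))
    return events


def membership_timeline(
    memberships: Mapping[str, Mapping[str, object]],
    timeline: ActivityTimeline,
) -> pd.DataFrame:
    """Component x age table of cluster membership for the ever-active
    universe, sorted for timeline display.

    ``memberships[age][component]`` is the modal cluster of an active
    component.  Sort order: first-activity age, then total active ages
    (descending: persistent components first), then the membership sequence,
    then persistence (remaining active after first activation).  Components
    active at exactly one age are placed at the bottom.
    """
    ages = timeline.ages
    rows = []
    for comp in timeline.ever_active():
        membership = {
            age: (
                memberships.get(age, {}).get(comp, "")
                if timeline.status.loc[comp, age] == ACTIVE
                else ""
            )
            for age in ages
        }
        active_flags = [timeline.status.loc[comp, age] == ACTIVE for age in ages]
        n_active = sum(active_flags)
        first_idx = active_flags.index(True)
        persistent = all(active_flags[first_idx:])
        rows.append(
            {
                "component": comp,
                **{f"age_{age}": str(membership[age]) for age in ages},
                "first_active_age": ages[first_idx],
                "n_active_ages": n_active,
                "persistent": persistent,
                "_first_idx": first_idx,
                "_single": n_active == 1,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["_membership_key"] = frame[[f"age_{a}" for a in ages]].agg("|".join, axis=1)
    frame = frame.sort_values(
        by=["_single", "_first_idx", "n_active_ages", "_membership_key", "persistent"],
        ascending=[True, True, False, True, False],
        kind="stable",
    )
    return frame.drop(columns=["_first_idx", "_single", "_membership_key"]).reset_index(
        drop=True
    )
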