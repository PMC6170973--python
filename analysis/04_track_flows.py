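#!/usr/bin/env python
"""Link the per-age clusterings into longitudinal flows.

Builds the component-flow graph between adjacent ages (every ever-active
component routes from its cluster, or the inactive node, to its next-age
location), labels the qualitative events (persist / split / absorb /
newly-formed / reabsorbed / dropout), classifies drop-out causes
(resolution vs attrition), and writes the display-ordered membership
timeline.  Outputs under results/flows/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from allergotype.cluster_flow import (
    build_flow_graph,
    membership_timeline,
    summarize_flows,
)
from allergotype.panel_io import (
    binarize_panel,
    build_activity_timeline,
    classify_dropout_cause,
    read_panel,
)

AGES = ["1", "3", "5", "8", "11", "16"]
ROOT = Path(__file__).resolve().parent.parent
BASE = ROOT / "results"
SCRATCH = ROOT / "scratch"
OUT = BASE / "flows"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panels = [
        binarize_panel(read_panel(SCRATCH / "cohort" / f"panel_{age}.csv", age))
        for age in AGES
    ]
    timeline = classify_dropout_cause(build_activity_timeline(panels), panels)
    timeline.dropouts.to_csv(OUT / "dropouts.csv", index=False)

    memberships = {}
    clusterings = {}
    for age in AGES:
        table = pd.read_csv(BASE / "membership" / f"membership_{age}.csv",
                            index_col="component")
        memberships[age] = table["modal_cluster"].to_dict()
        clusters: dict[int, set] = {}
        for comp, k in table["modal_cluster"].items():
            clusters.setdefault(int(k), set()).add(comp)
        clusterings[age] = clusters

    graph = build_flow_graph(clusterings, timeline.ever_active(), ages=AGES)
    edges = graph.edges.copy()
    edges["members"] = edges["members"].map(lambda m: ";".join(m))
    edges.to_csv(OUT / "flow_edges.csv", index=False)
    graph.to_json(OUT / "flow_graph.json")

    events = summarize_flows(graph)
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
        OUT / "flow_events.csv", index=False
    )
    membership_timeline(memberships, timeline).to_csv(
        OUT / "membership_timeline.csv", index=False
    )

    n_drop = len(timeline.dropouts)
    causes = timeline.dropouts["cause"].value_counts().to_dict() if n_drop else {}
    by_label = pd.Series([e.label for e in events]).value_counts().to_dict()
    print(f"{len(timeline.ever_active())} ever-active components, "
          f"{n_drop} drop-out events (causes: {causes})")
    print(f"flow events across {len(AGES) - 1} transitions: {by_label}")
    print(f"flow tables in {OUT}")


if __name__ == "__main__":
    main()
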