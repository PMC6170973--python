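"""End-to-end orchestration: binarize -> filter -> fit per age -> relabel ->
flows -> associations, from a single YAML config.

Clusterings at different ages are fit independently (the flow stage is
purely post hoc), each from its own deterministic seed derived from the
global one.  Every output table is a pure function of (inputs, config,
seed); the manifest records config, seeds, package version and input
checksums, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bernoulli_mixture import (
    MixtureConfig,
    SampleChain,
    default_kmax,
    mc3_run,
    modal_k,
    posterior_over_K,
)
from .cluster_flow import build_flow_graph, membership_timeline, summarize_flows
from .outcome_association import (
    build_profiles,
    derive_outcomes,
    multiple_or,
    results_table,
    univariable_or,
)
from .panel_io import (
    MIN_POSITIVE_DEFAULT,
    POSITIVITY_THRESHOLD_ISU,
    active_components,
    binarize_panel,
    build_activity_timeline,
    classify_dropout_cause,
    read_panel,
    responder_subjects,
)
from .relabeling import assignment_matrix, relabel_chain

__all__ = ["PipelineConfig", "run_pipeline", "write_chain", "read_chain"]

logger = logging.getLogger(__name__)

DEFAULT_OUTCOME_COLUMNS = ("current_asthma", "current_wheeze", "current_rhinitis")


@dataclass
class PipelineConfig:
    """Everything a run needs.  ``panels`` maps age label -> panel path, in
    age order.  ``mixture`` holds sampler settings, with optional per-age
    overrides (Kmax in particular may differ by age)."""

    panels: dict[str, str]
    out_dir: str
    seed: int
    threshold: float = POSITIVITY_THRESHOLD_ISU
    min_positive: int = MIN_POSITIVE_DEFAULT
    mixture: dict[str, Any] = field(default_factory=dict)
    mixture_per_age: dict[str, dict[str, Any]] = field(default_factory=dict)
    outcomes_path: str | None = None
    association_ages: list[str] = field(default_factory=list)
    outcome_columns: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOME_COLUMNS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if not self.panels:
            raise ValueError("config lists no panels")
        for age, p in self.panels.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"panel for age {age!r} not found: {p}")
        if self.outcomes_path and not Path(self.outcomes_path).exists():
            raise FileNotFoundError(f"outcomes table not found: {self.outcomes_path}")
        for age in self.association_ages:
            if age not in self.panels:
                raise ValueError(f"association age {age!r} has no panel")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_chain(chain: SampleChain, component_ids: list[str], path: Path) -> None:
    """Chain draws as delimited text: one row per retained draw
    (sweep index, K, allocation per component, log posterior)."""
    frame = pd.DataFrame(chain.zs, columns=component_ids)
    frame.insert(0, "K", chain.ks)
    frame.insert(0, "draw", np.arange(len(chain)))
    frame["log_post"] = chain.log_posts
    frame.to_csv(path, index=False, float_format="%.10g")


def read_chain(path: str | Path) -> tuple[SampleChain, list[str]]:
    """Inverse of :func:`write_chain` (kmax is recovered as max(K))."""
    frame = pd.read_csv(path)
    comp_cols = [c for c in frame.columns if c not in ("draw", "K", "log_post")]
    ks = frame["K"].to_numpy(dtype=np.int64)
    chain = SampleChain(
        ks=ks,
        zs=frame[comp_cols].to_numpy(dtype=np.int64),
        log_posts=frame["log_post"].to_numpy(dtype=float),
        kmax=int(ks.max()),
        seed=-1,
    )
    return chain, comp_cols


def _mixture_config(cfg: PipelineConfig, age: str, n_items: int, seed: int) -> MixtureConfig:
    settings: dict[str, Any] = {
        "kmax": default_kmax(n_items),
        **cfg.mixture,
        **cfg.mixture_per_age.get(age, {}),
    }
    settings["seed"] = seed
    return MixtureConfig(**settings)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Writes, per age: the binarized panel, posterior over K, chain draws,
    diagnostics, and the membership table with assignment probabilities;
    across ages: the activity timeline with classified drop-outs, the flow
    edge list and JSON graph, flow event labels and the display-ordered
    membership timeline; optionally association tables; and a manifest.
    """
    config.validate()  # before any compute
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ages = list(config.panels)
    master = np.random.default_rng(config.seed)
    age_seeds = {age: int(master.integers(2**31)) for age in ages}

    @_stage("load")
    def load():
        return [read_panel(config.panels[age], age) for age in ages]

    @_stage("binarize")
    def binarize(quant_panels):
        panels = [binarize_panel(q, config.threshold) for q in quant_panels]
        for p in panels:
            frame = p.data.copy()
            frame.insert(0, "subject_id", frame.index)
            frame.to_csv(out / f"binary_{p.age_label}.csv", index=False, float_format="%g")
        return panels

    @_stage("activity")
    def activity(panels):
        timeline = build_activity_timeline(panels, config.min_positive)
        timeline = classify_dropout_cause(timeline, panels)
        timeline.status.rename_axis("component").to_csv(out / "activity_timeline.csv")
        timeline.dropouts.to_csv(out / "dropouts.csv", index=False)
        return timeline

    @_stage("fit")
    def fit(panels):
        per_age = {}
        for panel in panels:
            age = panel.age_label
            active = active_components(panel, config.min_positive)
            responders = responder_subjects(panel, active)
            sub = panel.restrict(responders, active)
            mcfg = _mixture_config(config, age, len(active), age_seeds[age])
            # clustered items are components: rows = components, dims = subjects
            chain = mc3_run(sub.data.to_numpy().T, mcfg)
            post = posterior_over_K(chain)
            kstar = modal_k(post)
            post.rename("posterior").to_csv(out / f"posterior_K_{age}.csv", float_format="%.6g")
            write_chain(chain, active, out / f"chain_{age}.csv")
            (out / f"diagnostics_{age}.json").write_text(
                json.dumps(
                    {"age": age, "k_star": kstar, "seed": mcfg.seed, **chain.diagnostics},
                    indent=1,
                    sort_keys=True,
                )
            )
            logger.info(
                "age %s: %d active, %d responders, %d draws, K*=%d",
                age, len(active), len(responders), len(chain), kstar,
            )
            per_age[age] = {"panel": panel, "active": active, "chain": chain, "k_star": kstar}
        return per_age

    @_stage("relabel")
    def relabel(per_age):
        for age, bundle in per_age.items():
            rl = relabel_chain(bundle["chain"], bundle["k_star"])
            am = assignment_matrix(rl, component_ids=bundle["active"])
            table = am.probs.copy()
            table.columns = [f"cluster_{k}" for k in table.columns]
            table["modal_cluster"] = am.modal_cluster
            table["modal_probability"] = am.modal_probability
            table.rename_axis("component").to_csv(
                out / f"membership_{age}.csv", float_format="%.6g"
            )
            bundle["assignment"] = am
        return per_age

    @_stage("flows")
    def flows(per_age, timeline):
        clusterings = {}
        memberships = {}
        for age, bundle in per_age.items():
            am = bundle["assignment"]
            clusters: dict[int, set] = {}
            for comp, k in am.modal_cluster.items():
                clusters.setdefault(int(k), set()).add(comp)
            clusterings[age] = clusters
            memberships[age] = {c: int(k) for c, k in am.modal_cluster.items()}
        graph = build_flow_graph(clusterings, timeline.ever_active(), ages)
        edges = graph.edges.copy()
        edges["members"] = edges["members"].map(lambda m: ";".join(m))
        edges.to_csv(out / "flow_edges.csv", index=False)
        graph.to_json(out / "flow_graph.json")
        events = summarize_flows(graph)
        pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
            out / "flow_events.csv", index=False
        )
        membership_timeline(memberships, timeline).to_csv(
            out / "membership_timeline.csv", index=False
        )
        return graph

    @_stage("associate")
    def associate(per_age):
        outcomes = pd.read_csv(config.outcomes_path, index_col="subject_id")
        outcomes = derive_outcomes(outcomes.astype(float))
        results = []
        for age in config.association_ages:
            bundle = per_age[age]
            clustering = {c: int(k) for c, k in bundle["assignment"].modal_cluster.items()}
            profiles = build_profiles(bundle["panel"], clustering, bundle["active"])
            indicators = profiles.drop(columns="nonsensitized")
            for outcome_name in config.outcome_columns:
                y = outcomes[outcome_name]
                for cluster in indicators.columns:
                    results.append(
                        univariable_or(
                            y, indicators[cluster].astype(float),
                            outcome_name=f"{outcome_name}@{age}",
                            exposure_name=str(cluster),
                        )
                    )
                results.extend(
                    multiple_or(y, indicators, outcome_name=f"{outcome_name}@{age}")
                )
        results_table(results).to_csv(out / "associations.csv", index=False, float_format="%.6g")

    quant_panels = load()
    panels = binarize(quant_panels)
    timeline = activity(panels)
    per_age = fit(panels)
    per_age = relabel(per_age)
    flows(per_age, timeline)
    if config.outcomes_path and config.association_ages:
        associate(per_age)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "age_seeds": age_seeds,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "input_checksums": {age: _sha256(p) for age, p in config.panels.items()},
    }
    if config.outcomes_path:
        manifest["input_checksums"]["outcomes"] = _sha256(config.outcomes_path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
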