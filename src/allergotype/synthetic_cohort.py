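"""Synthetic longitudinal sensitization cohorts with planted truth.

The generator plants exactly the statistical structure the clustering model
assumes: components are partitioned into clusters and each cluster has a
matched block of responder subjects; cell (i, j) is Bernoulli(theta_in)
when subject j's block matches component i's cluster and
Bernoulli(theta_out) otherwise.  Longitudinal scenarios script the cluster
structure per age — persisting, splitting, absorbing members, newly forming
and dropping out — and per-age subject rosters drawn from a common pool so
that attrition-vs-resolution classification is exercised.  Outcomes are
generated from a logistic model on the true cluster-sensitization
indicators, with the wheeze/medication/diagnosis triple constructed so the
2-of-3 asthma rule reproduces the intended prevalence exactly.

Continuous ISU values are drawn so that thresholding at 0.30 inverts the
generation exactly: positives uniform on [0.30, 15), negatives uniform on
[0, 0.30).

Three presets: ``s1`` (one age, 4 well-separated clusters, 70 components,
400 subjects), ``childhood`` (6 ages whose active-component counts ramp
10, 26, 63, 68, 71, 72 with scripted flow events) and ``hard`` (s1 with
weak separation, theta_in = 0.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    MIN_POSITIVE_DEFAULT,
    POSITIVITY_THRESHOLD_ISU,
    ActivityTimeline,
    BinaryPanel,
    QuantPanel,
    build_activity_timeline,
)

__all__ = [
    "AgeSpec",
    "ScenarioSpec",
    "SyntheticCohort",
    "simulate_panel",
    "quantify_panel",
    "simulate_longitudinal",
    "simulate_outcomes",
    "scenario",
]

ISU_MAX = 15.0
BACKGROUND_RATE = 0.005  # positivity rate of scripted-inactive components


@dataclass
class AgeSpec:
    """Scripted structure at one age: the planted clusters over that age's
    active components, the roster size, and how subjects map to responder
    blocks.

    Two block modes exist.  Default (``block_rates=None``): a fraction
    ``responder_fraction`` of subjects is split into disjoint blocks sized
    proportionally to cluster membership — clean, orthogonal structure.
    With ``block_rates``, each subject joins each cluster's responder block
    independently with that cluster's rate; blocks overlap, emulating
    polysensitized children.  Overlap is what keeps small clusters
    identifiable under the per-subject collapsed likelihood: disjoint tiny
    blocks leave most subjects concordant-negative for any pair of sparse
    clusters, and the Beta-Bernoulli Occam factor then prefers merging
    them."""

    age_label: str
    n_subjects: int
    clusters: dict[str, list[str]]
    theta_in: float = 0.7
    theta_out: float = 0.05
    responder_fraction: float = 1.0
    block_rates: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.block_rates is not None:
            for k, r in self.block_rates.items():
                if k not in self.clusters:
                    raise ValueError(f"block rate for unknown cluster {k!r}")
                if not 0 <= r <= 1:
                    raise ValueError("block rates must lie in [0, 1]")
        seen: dict[str, str] = {}
        for name, members in self.clusters.items():
            for comp in members:
                if comp in seen:
                    raise ValueError(
                        f"inconsistent flow script: component {comp!r} belongs to "
                        f"clusters {seen[comp]!r} and {name!r} at age {self.age_label}"
                    )
                seen[comp] = name
        for p in (self.theta_in, self.theta_out, self.responder_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.theta_out < self.theta_in:
            raise ValueError("need theta_out < theta_in")

    @property
    def active(self) -> list[str]:
        return [c for members in self.clusters.values() for c in members]


@dataclass
class ScenarioSpec:
    """A full longitudinal scenario (ages, component universe, outcome model).

    ``cluster_logors`` are per-cluster log odds ratios applied to the true
    sensitization indicators at the last age.  ``seed`` is mandatory: a
    cohort is a pure function of (spec, seed).
    """

    name: str
    ages: list[AgeSpec]
    universe: list[str]
    n_pool: int
    seed: int
    asthma_baseline_logodds: float = -2.2
    cluster_logors: dict[str, float] = field(default_factory=dict)
    rhinitis_baseline_logodds: float = -1.4
    rhinitis_logors: dict[str, float] = field(default_factory=dict)
    min_positive: int = MIN_POSITIVE_DEFAULT
    enforce_activity: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        labels = [a.age_label for a in self.ages]
        if len(set(labels)) != len(labels):
            raise ValueError("age labels must be unique")
        known = set(self.universe)
        for age in self.ages:
            stray = set(age.active) - known
            if stray:
                raise ValueError(
                    f"inconsistent flow script: component(s) {sorted(stray)} at age "
                    f"{age.age_label} are not in the universe"
                )
            if age.n_subjects > self.n_pool:
                raise ValueError("age roster larger than the subject pool")


@dataclass
class SyntheticCohort:
    """Generated panels plus the planted truths they realize."""

    spec: ScenarioSpec
    quant_panels: list[QuantPanel]
    binary_panels: list[BinaryPanel]
    true_memberships: dict[str, dict[str, str]]  # age -> component -> cluster
    true_timeline: ActivityTimeline
    true_profiles: pd.DataFrame  # subject x cluster truth at the last age
    outcomes: pd.DataFrame
    provenance: dict


def _blocks(subjects: Sequence[str], clusters: Mapping[str, Sequence[str]],
            responder_fraction: float, rng: np.random.Generator) -> dict[str, str]:
    """Assign each subject a responder block (one per cluster, sized
    proportionally to cluster membership) or the background group."""
    names = list(clusters)
    n_resp = int(round(responder_fraction * len(subjects)))
    chosen = rng.permutation(len(subjects))[:n_resp]
    sizes = np.array([max(len(clusters[c]), 1) for c in names], dtype=float)
    weights = sizes / sizes.sum()
    counts = np.floor(weights * n_resp).astype(int)
    while counts.sum() < n_resp:
        counts[int(np.argmax(weights * n_resp - counts))] += 1
    out = {s: "background" for s in subjects}
    pos = 0
    for name, cnt in zip(names, counts):
        for idx in chosen[pos : pos + cnt]:
            out[subjects[idx]] = name
        pos += cnt
    return out


def simulate_panel(
    n_components: int,
    n_subjects: int,
    partition: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    theta_in: float,
    theta_out: float,
    seed: int,
    age_label: str = "t",
    subject_ids: Sequence[str] | None = None,
    responder_fraction: float = 1.0,
) -> tuple[BinaryPanel, dict]:
    """One cross-sectional panel with planted block structure.

    ``partition`` maps cluster name -> member components (or a list of
    member lists) and must cover all components.  Returns the binary panel
    and a truth dict with the planted membership and subject blocks.
    """
    if not isinstance(partition, Mapping):
        partition = {f"k{i}": list(members) for i, members in enumerate(partition)}
    components = [c for members in partition.values() for c in members]
    if len(components) != n_components or len(set(components)) != n_components:
        raise ValueError("partition must cover each component exactly once")
    if not 0 <= theta_out < theta_in <= 1:
        raise ValueError("need 0 <= theta_out < theta_in <= 1")
    subjects = (
        list(subject_ids)
        if subject_ids is not None
        else [f"s{j:04d}" for j in range(n_subjects)]
    )
    rng = np.random.default_rng(seed)
    block_of = _blocks(subjects, partition, responder_fraction, rng)
    membership = {c: name for name, members in partition.items() for c in members}
    comp_cluster = np.array([membership[c] for c in components])
    subj_block = np.array([block_of[s] for s in subjects])
    theta = np.where(comp_cluster[:, None] == subj_block[None, :], theta_in, theta_out)
    cells = (rng.random((n_components, len(subjects))) < theta).astype(float)
    frame = pd.DataFrame(cells.T, index=subjects, columns=components)
    panel = BinaryPanel(age_label=age_label, data=frame, threshold_used=POSITIVITY_THRESHOLD_ISU)
    truth = {"membership": membership, "subject_block": block_of}
    return panel, truth


def quantify_panel(binary: BinaryPanel, seed: int) -> QuantPanel:
    """Draw ISU values consistent with a binary panel: positives uniform on
    [0.30, 15), negatives uniform on [0, 0.30); thresholding at 0.30
    recovers the binary panel exactly."""
    rng = np.random.default_rng(seed)
    vals = binary.data.to_numpy(dtype=float)
    u = rng.random(vals.shape)
    thr = binary.threshold_used
    isu = np.where(vals == 1.0, thr + u * (ISU_MAX - thr), u * thr)
    isu = np.where(np.isnan(vals), np.nan, isu)
    frame = pd.DataFrame(isu, index=binary.data.index, columns=binary.data.columns)
    return QuantPanel(age_label=binary.age_label, data=frame)


def _age_panel(
    spec: ScenarioSpec, age: AgeSpec, roster: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Full-universe binary panel for one age: planted draws for scripted-
    active components; near-zero background for the rest, capped below the
    activity rule (and topped up to meet it for scripted members)."""
    membership = {c: k for k, members in age.clusters.items() for c in members}
    if age.block_rates is None:
        block_of = _blocks(roster, age.clusters, age.responder_fraction, rng)
        subj_block = np.array([block_of[s] for s in roster])
        in_block = {k: subj_block == k for k in age.clusters}
    else:
        in_block = {
            k: rng.random(len(roster)) < age.block_rates.get(k, 0.0)
            for k in age.clusters
        }
    data = pd.DataFrame(0.0, index=roster, columns=spec.universe)
    for comp in spec.universe:
        if comp in membership:
            theta = np.where(in_block[membership[comp]], age.theta_in, age.theta_out)
            col = (rng.random(len(roster)) < theta).astype(float)
            if spec.enforce_activity and col.sum() < spec.min_positive:
                short = int(spec.min_positive - col.sum())
                zeros = np.flatnonzero(col == 0)
                col[rng.choice(zeros, size=short, replace=False)] = 1.0
        else:
            col = (rng.random(len(roster)) < BACKGROUND_RATE).astype(float)
            if spec.enforce_activity and col.sum() >= spec.min_positive:
                ones = np.flatnonzero(col == 1)
                keep = rng.choice(ones, size=spec.min_positive - 1, replace=False)
                col = np.zeros_like(col)
                col[keep] = 1.0
        data[comp] = col
    return data


def simulate_longitudinal(spec: ScenarioSpec) -> SyntheticCohort:
    """Realize a scripted scenario: per-age rosters from a common pool,
    per-age panels honoring the planted clusters and the activity rule, and
    outcomes from the logistic model on last-age truth profiles.
    Regenerating with the same spec and seed is bit-identical."""
    rng = np.random.default_rng(spec.seed)
    pool = [f"s{j:04d}" for j in range(spec.n_pool)]
    binary_panels: list[BinaryPanel] = []
    quant_panels: list[QuantPanel] = []
    memberships: dict[str, dict[str, str]] = {}
    for age in spec.ages:
        roster_idx = np.sort(rng.permutation(spec.n_pool)[: age.n_subjects])
        roster = [pool[j] for j in roster_idx]
        frame = _age_panel(spec, age, roster, rng)
        panel = BinaryPanel(
            age_label=age.age_label, data=frame, threshold_used=POSITIVITY_THRESHOLD_ISU
        )
        binary_panels.append(panel)
        quant_panels.append(quantify_panel(panel, seed=int(rng.integers(2**31))))
        memberships[age.age_label] = {
            c: k for k, members in age.clusters.items() for c in members
        }
    timeline = build_activity_timeline(binary_panels, min_positive=spec.min_positive)

    last_age = spec.ages[-1]
    last_panel = binary_panels[-1]
    clusters = list(last_age.clusters)
    profiles = pd.DataFrame(index=pd.Index(last_panel.subject_ids, name="subject_id"))
    for k in clusters:
        members = last_age.clusters[k]
        profiles[k] = (last_panel.data[members] == 1).any(axis=1)
    profiles["nonsensitized"] = ~profiles[clusters].any(axis=1)

    outcomes = simulate_outcomes(
        profiles[clusters],
        spec.asthma_baseline_logodds,
        spec.cluster_logors,
        seed=int(rng.integers(2**31)),
        rhinitis_baseline_logodds=spec.rhinitis_baseline_logodds,
        rhinitis_logors=spec.rhinitis_logors,
    )
    return SyntheticCohort(
        spec=spec,
        quant_panels=quant_panels,
        binary_panels=binary_panels,
        true_memberships=memberships,
        true_timeline=timeline,
        true_profiles=profiles,
        outcomes=outcomes,
        provenance={"scenario": spec.name, "seed": spec.seed},
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_outcomes(
    profiles: pd.DataFrame,
    baseline_logodds: float,
    cluster_logors: Mapping[str, float],
    seed: int,
    rhinitis_baseline_logodds: float | None = None,
    rhinitis_logors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Outcome records from a logistic model on cluster indicators.

    Asthma status is drawn first, then the wheeze/medication/diagnosis
    triple is filled with a pattern satisfying (asthma) or violating
    (no asthma) the 2-of-3 rule, so derived asthma prevalence equals
    logistic(eta) exactly.  Rhinitis has its own logistic model (defaults to
    the asthma coefficients when unspecified).
    """
    for coefs in (cluster_logors, rhinitis_logors or {}):
        for k, v in coefs.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite log-OR for cluster {k!r}")
    rng = np.random.default_rng(seed)
    indicator_cols = [c for c in profiles.columns if c != "nonsensitized"]
    x = profiles[indicator_cols].to_numpy(dtype=float)
    beta = np.array([cluster_logors.get(c, 0.0) for c in indicator_cols])
    eta = baseline_logodds + x @ beta
    asthma = rng.random(len(profiles)) < _sigmoid(eta)

    if rhinitis_baseline_logodds is None:
        rhinitis_baseline_logodds = baseline_logodds
    rbeta = np.array(
        [(rhinitis_logors or cluster_logors).get(c, 0.0) for c in indicator_cols]
    )
    rhinitis = rng.random(len(profiles)) < _sigmoid(rhinitis_baseline_logodds + x @ rbeta)

    pos_patterns = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
    neg_patterns = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    pos_choice = rng.choice(4, size=len(profiles), p=[0.25, 0.2, 0.2, 0.35])
    neg_choice = rng.choice(4, size=len(profiles), p=[0.7, 0.12, 0.08, 0.1])
    triple = np.where(asthma[:, None], pos_patterns[pos_choice], neg_patterns[neg_choice])
    return pd.DataFrame(
        {
            "current_wheeze": triple[:, 0].astype(bool),
            "asthma_medication": triple[:, 1].astype(bool),
            "physician_asthma_ever": triple[:, 2].astype(bool),
            "current_rhinitis": rhinitis,
        },
        index=profiles.index,
    )


# ---------------------------------------------------------------------------
# presets


def _s1_spec(seed: int, theta_in: float = 0.7, name: str = "s1") -> ScenarioSpec:
    comps = [f"c{i:02d}" for i in range(70)]
    clusters = {
        "A": comps[:25],
        "B": comps[25:45],
        "C": comps[45:60],
        "D": comps[60:70],
    }
    age = AgeSpec(
        age_label="5",
        n_subjects=400,
        clusters=clusters,
        theta_in=theta_in,
        theta_out=0.05,
        responder_fraction=1.0,
    )
    return ScenarioSpec(
        name=name,
        ages=[age],
        universe=comps,
        n_pool=400,
        seed=seed,
        asthma_baseline_logodds=-2.2,
        cluster_logors={"A": math.log(3.5)},
        rhinitis_baseline_logodds=-1.4,
        rhinitis_logors={"B": math.log(2.0)},
    )


def _childhood_spec(seed: int) -> ScenarioSpec:
    """Six ages whose active-component counts ramp 10, 26, 63, 68, 71, 72 by
    construction, with scripted flow events: a broad cluster at every age
    (with drop-outs and one re-activation), a 4-component mite cluster that
    forms at age 3 and never changes, a single-component grass cluster that
    absorbs 3 grass components plus the cat component at age 5, a
    single-component mould cluster reabsorbed by the broad cluster at age
    11, two clusters newly formed at age 11, one of which divides at 16."""
    pool = [f"p{i:02d}" for i in range(67)]
    hdm = [f"hdm{i}" for i in range(1, 5)]
    grass = [f"g{i}" for i in range(1, 7)]
    cat = ["f1"]
    alt = ["a1"]
    pr10 = [f"r{i}" for i in range(1, 5)]
    profilin = [f"q{i}" for i in range(1, 4)]
    universe = pool + hdm + grass + cat + alt + pr10 + profilin

    pool_a1 = pool[0:10]
    pool_a3 = pool[0:8] + pool[10:23]                      # pool[8:10] drop out
    pool_a5 = pool_a3 + pool[23:46]
    pool_a8 = pool_a5[2:] + pool[46:53]                    # pool[0:2] drop out
    pool_a11 = [p for p in pool_a8 if p not in pool[2:5]] + pool[53:58] + [pool[8]]
    pool_a16 = [p for p in pool_a11 if p not in pool[5:8]] + pool[58:62]

    specials_58 = grass[4:6] + pr10 + profilin             # in broad at ages 5 and 8
    # block rates emulate polysensitization: responder blocks overlap, and
    # every cluster's block covers enough subjects to keep it identifiable
    ages = [
        AgeSpec("1", 150, {"broad": pool_a1},
                block_rates={"broad": 0.08}),
        AgeSpec("3", 200, {"broad": pool_a3, "hdm": hdm, "grass": grass[:1]},
                block_rates={"broad": 0.40, "hdm": 0.40, "grass": 0.35}),
        AgeSpec("5", 350, {"broad": pool_a5 + specials_58, "hdm": hdm,
                           "grass_cat": grass[:4] + cat, "alternaria": alt},
                block_rates={"broad": 0.50, "hdm": 0.45,
                             "grass_cat": 0.40, "alternaria": 0.35}),
        AgeSpec("8", 330, {"broad": pool_a8 + specials_58, "hdm": hdm,
                           "grass_cat": grass[:4] + cat, "alternaria": alt},
                block_rates={"broad": 0.50, "hdm": 0.45,
                             "grass_cat": 0.40, "alternaria": 0.35}),
        AgeSpec("11", 300, {"broad": pool_a11 + alt, "hdm": hdm, "grass": grass,
                            "cat": cat, "pr10_profilin": pr10 + profilin},
                block_rates={"broad": 0.50, "hdm": 0.45, "grass": 0.40,
                             "cat": 0.40, "pr10_profilin": 0.40}),
        AgeSpec("16", 280, {"broad": pool_a16 + alt, "hdm": hdm, "grass": grass,
                            "cat": cat, "pr10": pr10, "profilin": profilin},
                block_rates={"broad": 0.50, "hdm": 0.45, "grass": 0.40,
                             "cat": 0.40, "pr10": 0.35, "profilin": 0.35}),
    ]
    return ScenarioSpec(
        name="childhood",
        ages=ages,
        universe=universe,
        n_pool=500,
        seed=seed,
        asthma_baseline_logodds=-2.5,
        cluster_logors={"hdm": math.log(2.6), "grass": math.log(1.4)},
        rhinitis_baseline_logodds=-1.2,
        rhinitis_logors={"profilin": math.log(5.0), "broad": math.log(1.5)},
    )


def scenario(name: str, seed: int) -> ScenarioSpec:
    """Named preset: "s1", "childhood" or "hard"."""
    if name == "s1":
        return _s1_spec(seed)
    if name == "hard":
        return _s1_spec(seed, theta_in=0.4, name="hard")
    if name == "childhood":
        return _childhood_spec(seed)
    raise ValueError(f"unknown scenario {name!r}")
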