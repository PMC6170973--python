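# allergotype

Model-based clustering of allergen-component IgE responses across
childhood, with longitudinal cluster tracking and clinical outcome
association.

## The problem

Component-resolved diagnostics measure IgE antibodies against individual
allergenic proteins (Der p 1, Phl p 1, Fel d 1, ...) instead of whole
allergen extracts.  A birth cohort followed at several ages yields one
subjects × components panel of IgE levels (ISAC standardized units, ISU)
per follow-up.  This package answers three questions for such data:

1. **Which components cluster together at each age?**  Binarized responses
   (positive ≥ 0.30 ISU) of *active* components (≥ 3 positive responders)
   are clustered with a Bayesian Bernoulli mixture model of unknown order:
   component *i* in cluster *k* responds in subject *j* with probability
   θ_kj ~ Beta(a, b); mixture weights are Dirichlet(γ); the number of
   clusters *K* has a truncated-Poisson(1) (or uniform) prior up to K_max.
   θ and the weights are integrated out and the collapsed posterior over
   (K, z) is explored with an allocation sampler — collapsed Gibbs plus
   Metropolis cluster moves and a trans-dimensional eject/absorb pair —
   embedded in Metropolis-coupled MCMC.  Label switching is resolved with
   the Equivalence Classes Representatives (ECR) algorithm, giving a
   posterior over *K*, modal memberships and per-component assignment
   probabilities.
2. **How do clusters evolve?**  Clusterings are inferred independently per
   age and then linked: every ever-active component routes between
   adjacent-age clusters (or an "inactive" node), and the resulting flow
   graph is summarized into persist / split / absorb / newly-formed /
   reabsorbed / dropout events, with drop-outs classified as resolution of
   sensitization vs subject attrition.
3. **Do cluster sensitizations predict disease?**  A subject is sensitized
   to a cluster if positive to ≥ 1 member component.  Current asthma (any
   2 of: current wheeze, asthma medication, physician-diagnosed asthma
   ever) and current rhinitis are regressed on cluster indicators by
   univariable and multiple logistic models; results are odds ratios with
   Wald 95% CIs, with complete separation flagged.

Because no cohort data are distributed, the package ships a synthetic
cohort generator that plants exactly the model's structure (block
Bernoulli panels, scripted longitudinal flow events, logistic outcomes)
so every stage is testable end to end.  See `docs/methods.md` for the
model, sampler and design details.

## Worked example

The `analysis/` scripts run the whole study on a scripted six-age cohort
("childhood": active-component counts ramp 10 → 72, with a stable mite
cluster, a grass cluster that absorbs members, singleton clusters that
form and get reabsorbed, and a final-age division):

```sh
python analysis/01_simulate_cohort.py   # panels + outcomes -> scratch/cohort/
python analysis/02_fit_mixtures.py      # per-age mixture fits
python analysis/03_relabel_memberships.py
python analysis/04_track_flows.py
python analysis/05_associate_outcomes.py
```

`02_fit_mixtures.py` prints the inferred number of clusters per age:

```
age  1: 10 active components,  61 responders, Kmax=9, K*=1 (posterior 0.918)
age  3: 26 active components, 189 responders, Kmax=25, K*=3 (posterior 0.910)
age  5: 63 active components, 349 responders, Kmax=25, K*=4 (posterior 0.933)
age  8: 68 active components, 328 responders, Kmax=25, K*=4 (posterior 0.970)
age 11: 71 active components, 299 responders, Kmax=25, K*=5 (posterior 0.972)
age 16: 72 active components, 280 responders, Kmax=25, K*=6 (posterior 0.915)
```

The modal cluster count grows 1 → 3 → 4 → 4 → 5 → 6 as the scripted
architecture diversifies, each with high posterior probability; the
relabeled memberships match the planted clusters exactly (purity 1.000 at
every age, `03_relabel_memberships.py`).  The flow stage then reports

```
flow events across 5 transitions: {'persist': 16, 'newly-formed': 6, 'split': 3, 'absorb': 2, 'reabsorbed': 1}
```

and the association stage recovers the planted effects — e.g. the
mite-like cluster (planted OR 2.6) against asthma at age 16:

```
current_asthma@16 ~ cluster 4: OR 2.86 (1.48-5.52), p=0.0018, n=280
```

Read: subjects sensitized to that cluster have 2.9-fold higher odds of
current asthma, CI excluding 1.  Small summary tables land in `results/`;
bulky intermediates (panels, chain draws) in `scratch/`.

The same pipeline runs from a YAML config on any delimited-text panels via
the CLI:

```sh
allergotype simulate --scenario s1 --seed 5 --out data/
allergotype fit --panel data/panel_5.csv --age 5 --kmax 8 --sweeps 2000 --seed 5 --out fit5
allergotype relabel --chain fit5_chain.csv --kstar 4 --out fit5
allergotype run --config pipeline.yaml
```

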