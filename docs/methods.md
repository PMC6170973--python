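# Methods

## The problem

Component-resolved diagnostics measure IgE against individual allergenic
proteins ("components", e.g. Der p 1, Phl p 1, Fel d 1) rather than whole
allergen extracts.  In a longitudinal birth cohort this yields, at each
follow-up age, a subjects x components matrix of IgE levels in ISAC
standardized units (ISU).  The scientific questions this package addresses
are: which components co-occur in subjects' IgE repertoires at each age
(cross-sectional clusters), how those clusters evolve across childhood
(flows), and whether sensitization to particular clusters predicts asthma
and rhinitis in adolescence (odds ratios).

## Pre-processing

IgE levels are dichotomized at 0.30 ISU, inclusive (`binarize_panel`).  A
component is *active* at an age when at least `min_positive = 3` present
subjects are positive; clustering at an age uses only active components and
the subjects positive to at least one of them.  Missingness is whole-row: a
subject absent at an age contributes nothing to that age's counts, so
denominators vary by age.  A *drop-out* is any active-to-inactive
transition between consecutive measured ages (re-activation is allowed);
each drop-out is attributed to *resolution* (every previously positive
subject is present and now negative), *attrition* (every previously
positive subject is absent), or left *undetermined* (mixed evidence, or a
previously positive subject still positive while the activity rule fails).

Percentages in demographic tables use round-half-up at two decimals,
matching how such tables are printed.  The included-vs-excluded group
comparison uses a chi-square test with continuity correction, switching to
Fisher's exact test when any expected cell count is below 5; only the
direction of significance is meaningful, since the choice of test variant
shifts exact p-values.

## Model

Active components are the clustered items; subjects are the dimensions.
Component `i` in cluster `k` responds in subject `j` with probability
`theta_kj ~ Beta(a, b)` (default `a = b = 1`).  Mixture weights carry a
symmetric Dirichlet(`gamma`) prior (default 1); the number of mixture
components `K` carries either a uniform prior on `1..Kmax` or a truncated
Poisson(1) prior (the default).  Integrating `theta` and the weights
analytically gives the collapsed posterior over `(K, z)`, with `z` the
allocation vector:

    p(K, z | X)  ∝  p(K) · Γ(Kγ)/Γ(n+Kγ) · Π_k Γ(n_k+γ)/Γ(γ)
                  · Π_k Π_j B(a + s_kj, b + n_k − s_kj) / B(a, b)

where `n_k` is cluster k's size and `s_kj` its positive count in subject j.
Empty labels are permitted mid-chain (standard allocation-sampler
semantics); reported memberships use the non-empty clusters of the retained
draws.  `Kmax` defaults to `min(25, n_items − 1)`.

## Sampling

Each sweep runs, per chain:

1. a collapsed Gibbs sweep reassigning every item from its full
   conditional;
2. three fixed-dimension Metropolis moves: a symmetric subset swap between
   two clusters, a subset mass reallocation (proposal ratio
   `2^(n1−n2−|S|)`), and a sequential two-cluster reshuffle that refills
   two emptied clusters item-by-item from the collapsed predictive, with
   the reverse-path probability obtained by replaying the same scheme on
   the original labels;
3. one trans-dimensional move: *eject* splits a random cluster binomially
   (split probability uniform, integrated out to a Beta(m+1, n−m+1)
   proposal mass) into a new cluster placed at a uniformly random label
   slot, and *absorb* merges one cluster into another, swapping the top
   label into the vacated slot.  The random label placement makes the two
   moves exact labeled-space inverses, so the cluster-choice factors cancel
   and detailed balance holds across dimensions.

The sampler is Metropolis-coupled: `n_chains` chains (default 4) run at
inverse temperatures `beta_c = 1/(1 + delta·c)` (default `delta = 0.15`),
one adjacent pair attempts a state swap per sweep, and only cold-chain
draws are retained (default: 50% burn-in, no thinning).  Chains are
initialized at `K = Kmax` with a random allocation: starting over-split is
deliberate, because the Gibbs sweep separates structure within existing
labels quickly and absorb moves merge the surplus, whereas a chain started
at `K = 1` must wait for an eject proposal to hit a near-perfect split,
whose acceptance is exponentially small for well-separated clusters.

The incremental log posterior is refreshed from scratch every 500 sweeps to
bound floating-point drift; the tests verify increment-vs-recomputation
agreement at 1e-8.  All randomness flows from one seed through per-chain
spawned generators, so runs are bit-reproducible.

For small instances (at most 10^7 states) `exact_posterior_small`
enumerates every `(K, z)` and is the independent oracle for the sampler
tests: total-variation distance between the chain's posterior over K and
the enumeration is required to stay within 0.02 on a fixed 6x4 panel.

## Relabeling

Mixture labels are unidentified across draws.  Conditional on the modal
`K*` (ties broken toward smaller K), draws with `K = K*` are ECR-relabeled:
the pivot is the maximum-a-posteriori retained draw, and each draw gets the
label permutation minimizing disagreement with the pivot — an assignment
problem on the K* x K* agreement matrix, solved by brute force with
lexicographic tie-breaking up to K* = 7 and by the Hungarian algorithm
above.  Assignment probabilities are empirical frequencies over relabeled
draws; modal membership breaks ties toward the lower cluster index.

## Flows

Clusterings at different ages are inferred independently; flows are purely
post hoc.  Between adjacent ages every ever-active component routes from
its cluster (or the "inactive" node) to its next-age location; edge weight
is the number of shared components, so weights out of a node sum to its
member count (conservation).  Components newly active at the later age
enter through the inactive node.

Qualitative events come from edge topology with every weight >= 1 counted
as substantial (single-component moves matter).  The *continuation* of a
cluster B at the later age is the heaviest incoming source whose own
dominant target is B — this stops a large donor that mostly persists
elsewhere from claiming B.  Source-side labels (not exclusive): *dropout*
(all members inactive), *split* (>= 2 outgoing cluster edges), *persist*
(continues its dominant target), *reabsorbed* (sole target continues a
different cluster).  Target-side: *absorb* (>= 2 incoming cluster edges),
*newly-formed* (no incoming cluster is continued here).  A cluster that
donates a minor slice while its main body persists is labeled persist and
split simultaneously, which matches how such histories are narrated.

The membership timeline orders components by first-activity age, then by
total active ages (descending, so persistent components lead — the
direction is a display choice), then by the membership sequence, then by
persistence; components active at exactly one age are placed last.

## Outcomes and association

Current asthma is any 2 of {current wheeze, current asthma medication,
physician-diagnosed asthma ever}; missing any feature makes the outcome
missing.  Current rhinitis is a single questionnaire item.  A subject is
sensitized to a cluster when positive to >= 1 member component; subjects
positive to no active component form the nonsensitized group and
contribute zeros to every indicator.  Odds ratios come from logistic
regressions — univariable (one indicator) and multiple (all cluster
indicators jointly) — with Wald 95% intervals (z = 1.96) and complete-case
handling.  For a binary exposure the univariable fit is computed as the
closed-form 2x2 cross-product ratio, which is the exact MLE.  Complete
separation (an empty 2x2 cell, or a diverging Wald SE in the joint model)
is flagged and the estimate reported as unbounded rather than silently
penalized; an L2-penalized fit is available but off by default, and
degenerate (constant) indicator columns are flagged and dropped without
affecting the rest.

## Synthetic cohorts

No cohort data are distributed, so the generator plants exactly the
structure the model assumes: a partition of components into clusters, a
matched block of responder subjects per cluster, and cells drawn
Bernoulli(`theta_in`) on matched block x cluster pairs and
Bernoulli(`theta_out`) elsewhere.  ISU values are drawn uniform on
[0.30, 15) for positives and [0, 0.30) for negatives so thresholding
inverts generation exactly.  Longitudinal scenarios script the cluster
architecture per age and draw per-age subject rosters from a common pool
(missing-at-random attrition).  Outcomes follow a logistic model on the
true final-age profiles; the wheeze/medication/diagnosis triple is filled
with a pattern satisfying or violating the 2-of-3 rule, so derived asthma
prevalence equals the logistic target exactly.

Presets:

* `s1` — one age, 4 clusters of sizes 25/20/15/10 over 70 components, 400
  subjects in matched blocks, `theta_in = 0.7`, `theta_out = 0.05`.  The
  separation is deliberately strong: observed assignment probabilities in
  this kind of data are very high, and this preset is the recovery
  benchmark (posterior mode K = 4, >= 95% correct membership after
  relabeling).
* `childhood` — six ages ("1" through "16") whose active-component counts
  ramp 10, 26, 63, 68, 71, 72 *by construction*: scripted-active
  components are topped up to >= 3 positives and scripted-inactive ones
  capped at 2, so the activity filter reproduces the scripted counts
  deterministically.  The flow script includes a broad multi-source
  cluster at every age with drop-outs and one re-activation, a stable
  4-component mite cluster from age 3, a single-component grass cluster
  absorbing 3 grass components plus the cat component at age 5, a
  single-component mould cluster reabsorbed by the broad cluster at age
  11, two clusters newly formed at age 11, and one division at age 16.
  Rosters of 120-220 subjects per age are drawn from a 300-subject pool;
  responder fractions rise from 0.10 to 0.60 across ages to emulate the
  sparsity of infant panels.
* `hard` — `s1` with `theta_in = 0.4`, a stress preset for weak separation.

What the generator does **not** emulate: ISU measurement error and assay
chemistry, cross-reactivity structure (components in different planted
clusters are independent given the blocks), subject-level heterogeneity
within blocks, informative (non-random) attrition, and confounding between
sensitization and outcomes.  Passing recovery tests therefore shows the
machinery is correct and well-calibrated on data satisfying the model's
assumptions — not that real IgE panels satisfy them.

## Numerical and design choices

* Problem sizes in tests and verification runs (a 6x4 enumeration panel at
  2x10^5 sweeps; S1 at 1500 sweeps with 4 chains; 50 replicates of n=2000
  for OR recovery) are chosen so each check runs in seconds to minutes on
  one core while leaving Monte Carlo error well inside the asserted
  tolerances.
* The truncated-Poisson(1) default prior on K follows the cited
  allocation-sampler convention; the uniform prior is one switch away.
  The full prior/move specification used on the original cohort is not
  public, so these defaults are declared substitutes, not reconstructions.
* Modal-K ties break toward smaller K (parsimony); modal-membership ties
  toward the lower cluster index; ECR ties toward the lexicographically
  smallest permutation.  All are determinism guarantees, not substantive
  claims.
* Cluster display names ("broad", "HDM", "grass/cat", ...) are user-side
  labels; the algorithmic layer uses opaque indices throughout.

## Known limitations

* The sampler's mixing guarantee is empirical (oracle agreement on small
  panels, multi-seed recovery on planted data); strongly overlapping
  clusters (`hard` preset) can hold the chain below the true K within
  short runs.
* No missing-data likelihood: clustering requires the complete
  responder x active submatrix.
* No joint longitudinal model: per-age independence is a design decision,
  and flow labels are descriptive topology, not inference.
* Separation in association models is flagged, not resolved; with sparse
  outcomes the multiple model can be unstable, which the flags surface.
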