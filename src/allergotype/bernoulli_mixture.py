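"""Bayesian Bernoulli mixture model with an unknown number of clusters.

Allergen components (rows) are clustered by their binary response profiles
across subjects (columns).  Component ``i`` in cluster ``k`` responds in
subject ``j`` with probability ``theta_{kj} ~ Beta(a, b)``; mixture weights
carry a symmetric Dirichlet(gamma) prior and the number of mixture
components ``K`` a prior that is either uniform on ``1..Kmax`` or a
truncated Poisson.  Both theta and the weights are integrated out
analytically, leaving a collapsed posterior over ``(K, z)`` where ``z`` is
the allocation vector.  Cluster labels are 0-based; empty labels are
allowed mid-chain (standard allocation-sampler semantics).

Sampling combines a collapsed Gibbs sweep over allocations, three
fixed-dimension Metropolis moves (subset swap between two clusters, subset
mass reallocation, sequential two-cluster reshuffle), and a
trans-dimensional eject/absorb pair changing ``K`` by one.  The whole move
schedule runs inside a Metropolis-coupled MCMC (parallel tempering) scheme;
inference uses the cold chain only.

For small instances :func:`exact_posterior_small` provides the exhaustive
enumeration of the collapsed posterior used as an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "MixtureConfig",
    "AllocationState",
    "SampleChain",
    "log_marginal_cluster",
    "log_allocation_prior",
    "log_k_prior",
    "log_collapsed_posterior",
    "gibbs_sweep",
    "metropolis_moves",
    "eject_absorb",
    "mc3_run",
    "posterior_over_K",
    "modal_k",
    "exact_posterior_small",
    "default_kmax",
]

_ENUM_GUARD = 10_000_000
_REFRESH_EVERY = 500  # sweeps between from-scratch log-posterior refreshes


def default_kmax(n_items: int) -> int:
    """Default cluster-count cap: min(25, n_items - 1), at least 1."""
    return max(1, min(25, n_items - 1))


@dataclass
class MixtureConfig:
    """Hyperparameters and run settings for the allocation sampler.

    beta_a, beta_b : Beta prior on per-cluster per-subject response
        probabilities (default 1,1 = uniform).
    gamma : symmetric Dirichlet concentration on mixture weights.
    k_prior : "poisson" (truncated Poisson, rate ``poisson_rate``) or
        "uniform" on 1..kmax.
    delta : tempering spacing; chain c runs at beta_c = 1/(1 + delta*c).
    """

    kmax: int
    beta_a: float = 1.0
    beta_b: float = 1.0
    gamma: float = 1.0
    k_prior: str = "poisson"
    poisson_rate: float = 1.0
    n_chains: int = 4
    delta: float = 0.15
    n_sweeps: int = 2000
    burn_in: float = 0.5
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if min(self.beta_a, self.beta_b, self.gamma, self.delta) <= 0:
            raise ValueError("beta_a, beta_b, gamma, delta must be > 0")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")
        if self.k_prior not in ("poisson", "uniform"):
            raise ValueError("k_prior must be 'poisson' or 'uniform'")
        if self.n_chains < 1 or self.thin < 1 or self.n_sweeps < 1:
            raise ValueError("n_chains, thin, n_sweeps must be >= 1")


@dataclass
class AllocationState:
    """Current sampler state: cluster count ``K``, allocation ``z`` (0-based,
    values in ``0..K-1``, empty labels permitted) and its collapsed log
    posterior.  Sufficient statistics (cluster sizes and per-subject positive
    counts) are carried alongside so moves are incremental."""

    K: int
    z: np.ndarray
    log_post: float
    nk: np.ndarray  # capacity kmax; first K entries valid
    s: np.ndarray  # capacity kmax x n_subjects

    @classmethod
    def from_allocation(
        cls, z: Sequence[int], K: int, data: np.ndarray, config: MixtureConfig
    ) -> "AllocationState":
        z = np.asarray(z, dtype=np.int64)
        data = _as_binary(data)
        if z.shape[0] != data.shape[0]:
            raise ValueError("allocation length must match number of items")
        if K < 1 or K > config.kmax or (z.size and z.max() >= K) or (z.size and z.min() < 0):
            raise ValueError("labels must lie in 0..K-1 with K <= kmax")
        nk = np.zeros(config.kmax, dtype=np.int64)
        s = np.zeros((config.kmax, data.shape[1]), dtype=np.int64)
        for k in range(K):
            members = z == k
            nk[k] = int(members.sum())
            s[k] = data[members].sum(axis=0)
        lp = log_collapsed_posterior(K, z, data, config)
        return cls(K=K, z=z, log_post=lp, nk=nk, s=s)


@dataclass
class SampleChain:
    """Cold-chain draws after burn-in and thinning, plus diagnostics."""

    ks: np.ndarray  # (n_draws,)
    zs: np.ndarray  # (n_draws, n_items)
    log_posts: np.ndarray
    kmax: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.ks.shape[0])


# ---------------------------------------------------------------------------
# collapsed posterior pieces


def _as_binary(data: np.ndarray | pd.DataFrame) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if np.isnan(arr).any():
        raise ValueError(
            "clustering operates on the complete responder x active submatrix; "
            "missing cells are not allowed"
        )
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("data must be 0/1")
    return arr.astype(np.uint8)


def log_marginal_cluster(
    positives: np.ndarray | Sequence[int], n_k: int, beta_a: float, beta_b: float
) -> float:
    """Collapsed Beta-Bernoulli log marginal of one cluster.

    ``positives[j]`` counts the cluster's positive responses in subject j out
    of ``n_k`` member components:  sum_j [ log B(a+s_j, b+n_k-s_j) - log B(a,b) ].
    """
    s = np.asarray(positives, dtype=float)
    if s.size and (s.min() < 0 or s.max() > n_k):
        raise ValueError("need 0 <= s_j <= n_k")
    return float(
        betaln(beta_a + s, beta_b + (n_k - s)).sum() - s.size * betaln(beta_a, beta_b)
    )


def log_allocation_prior(z: Sequence[int], K: int, gamma: float) -> float:
    """Collapsed symmetric-Dirichlet prior on the allocation vector:
    Gamma(K*g)/Gamma(n+K*g) * prod_k Gamma(n_k+g)/Gamma(g).  Sums to 1 over
    the K^n allocations."""
    z = np.asarray(z, dtype=np.int64)
    n = z.shape[0]
    counts = np.bincount(z, minlength=K)
    return float(
        gammaln(K * gamma)
        - gammaln(n + K * gamma)
        + (gammaln(counts + gamma) - gammaln(gamma)).sum()
    )


def log_k_prior(K: int, config: MixtureConfig) -> float:
    """Log prior on the number of mixture components, normalized over 1..kmax."""
    if not 1 <= K <= config.kmax:
        raise ValueError("K out of range")
    ks = np.arange(1, config.kmax + 1)
    if config.k_prior == "uniform":
        return float(-np.log(config.kmax))
    lam = config.poisson_rate
    logw = ks * np.log(lam) - gammaln(ks + 1)
    return float(K * np.log(lam) - gammaln(K + 1) - logsumexp(logw))


def log_collapsed_posterior(
    K: int, z: Sequence[int], data: np.ndarray, config: MixtureConfig
) -> float:
    """Unnormalized collapsed log posterior of (K, z): cluster marginals +
    allocation prior + prior on K.  Exactly invariant under permutations of
    the cluster labels."""
    data = _as_binary(data)
    z = np.asarray(z, dtype=np.int64)
    total = log_allocation_prior(z, K, config.gamma) + log_k_prior(K, config)
    for k in range(K):
        members = z == k
        n_k = int(members.sum())
        s = data[members].sum(axis=0)
        total += log_marginal_cluster(s, n_k, config.beta_a, config.beta_b)
    if not math.isfinite(total):
        raise FloatingPointError("non-finite collapsed log posterior")
    return float(total)


# ---------------------------------------------------------------------------
# sampler internals: lookup tables and incremental statistics


class _Ctx:
    """Precomputed tables and per-item index lists for one data matrix."""

    def __init__(self, data: np.ndarray, config: MixtureConfig):
        self.data = _as_binary(data)
        self.n, self.m = self.data.shape
        self.cfg = config
        a, b, g = config.beta_a, config.beta_b, config.gamma
        t = np.arange(self.n + 2, dtype=float)
        self.TA = np.log(a + t)
        self.TB = np.log(b + t)
        self.TC = np.log(a + b + t)
        self.GA = gammaln(a + t)
        self.GB = gammaln(b + t)
        self.GC = gammaln(a + b + t)
        self.GG = gammaln(g + t)
        self.lbab = float(betaln(a, b))
        self.idx1 = [np.flatnonzero(self.data[i]) for i in range(self.n)]
        self.idx0 = [np.flatnonzero(1 - self.data[i]) for i in range(self.n)]
        ks = np.arange(1, config.kmax + 1, dtype=float)
        if config.k_prior == "uniform":
            self.logpk = np.full(config.kmax, -np.log(config.kmax))
        else:
            lw = ks * np.log(config.poisson_rate) - gammaln(ks + 1)
            self.logpk = lw - logsumexp(lw)

    def logmarg(self, s: np.ndarray, n_k: int) -> float:
        """Cluster log marginal from table lookups."""
        return float(
            self.GA[s].sum() + self.GB[n_k - s].sum() - self.m * (self.GC[n_k] + self.lbab)
        )

    def alloc_norm(self, K: int) -> float:
        g = self.cfg.gamma
        return float(gammaln(K * g) - gammaln(self.n + K * g))

    def pred_one(self, i: int, s: np.ndarray, n_k: int) -> float:
        """Log predictive of item i's profile under a cluster with stats (s, n_k)."""
        return float(
            self.TA[s[self.idx1[i]]].sum()
            + self.TB[(n_k - s)[self.idx0[i]]].sum()
            - self.m * self.TC[n_k]
        )


_CTX_CACHE: dict[tuple, _Ctx] = {}


def _get_ctx(data: np.ndarray, config: MixtureConfig) -> _Ctx:
    """Context cache for the public per-move wrappers (the lookup tables are
    pure functions of the data and the prior hyperparameters)."""
    arr = np.ascontiguousarray(np.asarray(data))
    key = (
        arr.tobytes(), arr.shape,
        config.kmax, config.beta_a, config.beta_b, config.gamma,
        config.k_prior, config.poisson_rate,
    )
    ctx = _CTX_CACHE.get(key)
    if ctx is None:
        if len(_CTX_CACHE) >= 8:
            _CTX_CACHE.clear()
        ctx = _CTX_CACHE[key] = _Ctx(data, config)
    return ctx


def _item_logweights(st: AllocationState, i: int, ctx: _Ctx) -> np.ndarray:
    """Untempered full-conditional log weights of item i over clusters 0..K-1,
    to be called with item i removed from the sufficient statistics."""
    K = st.K
    s = st.s[:K]
    nk = st.nk[:K]
    w = (
        ctx.TA[s[:, ctx.idx1[i]]].sum(axis=1)
        + ctx.TB[(nk[:, None] - s)[:, ctx.idx0[i]]].sum(axis=1)
        - ctx.m * ctx.TC[nk]
    )
    return w + np.log(nk + ctx.cfg.gamma)


def _remove_item(st: AllocationState, i: int, ctx: _Ctx) -> None:
    c = st.z[i]
    st.nk[c] -= 1
    st.s[c] -= ctx.data[i]


def _insert_item(st: AllocationState, i: int, c: int, ctx: _Ctx) -> None:
    st.z[i] = c
    st.nk[c] += 1
    st.s[c] += ctx.data[i]


def _gibbs_impl(
    st: AllocationState,
    ctx: _Ctx,
    rng: np.random.Generator,
    beta: float,
    items: Iterable[int] | None = None,
) -> None:
    order = range(ctx.n) if items is None else items
    delta = 0.0
    for i in order:
        c_old = int(st.z[i])
        _remove_item(st, i, ctx)
        w = _item_logweights(st, i, ctx)
        wq = w if beta == 1.0 else beta * w
        wq = wq - wq.max()
        p = np.exp(wq)
        p /= p.sum()
        c_new = int(np.searchsorted(np.cumsum(p), rng.random()))
        c_new = min(c_new, st.K - 1)
        delta += w[c_new] - w[c_old]
        _insert_item(st, i, c_new, ctx)
    st.log_post += delta


def _pair_delta(
    ctx: _Ctx,
    old: list[tuple[np.ndarray, int]],
    new: list[tuple[np.ndarray, int]],
) -> float:
    """Log-posterior change when the listed clusters' stats change (K fixed)."""
    d = 0.0
    for s, n in new:
        d += ctx.logmarg(s, n) + ctx.GG[n]
    for s, n in old:
        d -= ctx.logmarg(s, n) + ctx.GG[n]
    return d


def _m1_swap(st, ctx, rng, beta, record=None) -> bool:
    """Subset swap: reassign the union of two clusters uniformly at random
    between them (symmetric proposal)."""
    K = st.K
    j1, j2 = (int(v) for v in rng.choice(K, size=2, replace=False))
    members = np.flatnonzero((st.z == j1) | (st.z == j2))
    if members.size == 0:
        return True  # proposal identical to the current state
    to_j1 = rng.random(members.size) < 0.5
    s1 = ctx.data[members[to_j1]].sum(axis=0).astype(np.int64)
    n1 = int(to_j1.sum())
    s2 = ctx.data[members[~to_j1]].sum(axis=0).astype(np.int64)
    n2 = members.size - n1
    delta = _pair_delta(
        ctx,
        old=[(st.s[j1], int(st.nk[j1])), (st.s[j2], int(st.nk[j2]))],
        new=[(s1, n1), (s2, n2)],
    )
    if record is not None:
        z_new = st.z.copy()
        z_new[members[to_j1]] = j1
        z_new[members[~to_j1]] = j2
        record.update(move="m1", j1=j1, j2=j2, z_old=st.z.copy(), z_new=z_new,
                      log_accept=min(0.0, beta * delta))
    if np.log(rng.random()) < beta * delta:
        st.z[members[to_j1]] = j1
        st.z[members[~to_j1]] = j2
        st.s[j1], st.nk[j1] = s1, n1
        st.s[j2], st.nk[j2] = s2, n2
        st.log_post += delta
        return True
    return False


def _m2_mass(st, ctx, rng, beta, record=None) -> bool:
    """Mass reallocation: move a random half-rate subset of one cluster into
    another; proposal ratio 2^(n1 - n2 - |S|)."""
    K = st.K
    j1, j2 = (int(v) for v in rng.choice(K, size=2, replace=False))
    members = np.flatnonzero(st.z == j1)
    n1, n2 = int(st.nk[j1]), int(st.nk[j2])
    sel = rng.random(members.size) < 0.5
    S = members[sel]
    mS = int(S.size)
    dS = ctx.data[S].sum(axis=0).astype(np.int64)
    s1n = st.s[j1] - dS
    s2n = st.s[j2] + dS
    delta = _pair_delta(
        ctx,
        old=[(st.s[j1], n1), (st.s[j2], n2)],
        new=[(s1n, n1 - mS), (s2n, n2 + mS)],
    )
    log_ratio = (n1 - n2 - mS) * math.log(2.0)
    log_acc = beta * delta + log_ratio
    if record is not None:
        z_new = st.z.copy()
        z_new[S] = j2
        record.update(move="m2", j1=j1, j2=j2, n1=n1, n2=n2, subset_size=mS,
                      z_old=st.z.copy(), z_new=z_new, log_accept=min(0.0, log_acc))
    if np.log(rng.random()) < log_acc:
        st.z[S] = j2
        st.s[j1], st.nk[j1] = s1n, n1 - mS
        st.s[j2], st.nk[j2] = s2n, n2 + mS
        st.log_post += delta
        return True
    return False


def _sequential_alloc(
    ctx: _Ctx,
    members: np.ndarray,
    j1: int,
    j2: int,
    rng: np.random.Generator | None,
    forced: np.ndarray | None,
):
    """Sequentially allocate ``members`` between two emptied clusters using
    collapsed predictive probabilities.  With ``forced`` labels, returns the
    log probability of producing that assignment instead of sampling."""
    g = ctx.cfg.gamma
    s1 = np.zeros(ctx.m, dtype=np.int64)
    s2 = np.zeros(ctx.m, dtype=np.int64)
    n1 = n2 = 0
    logq = 0.0
    labels = np.empty(members.size, dtype=np.int64)
    for t, i in enumerate(members):
        w1 = math.log(n1 + g) + ctx.pred_one(i, s1, n1)
        w2 = math.log(n2 + g) + ctx.pred_one(i, s2, n2)
        norm = np.logaddexp(w1, w2)
        logp1, logp2 = w1 - norm, w2 - norm
        if forced is None:
            take1 = math.log(rng.random()) < logp1
        else:
            take1 = forced[t] == j1
        logq += logp1 if take1 else logp2
        if take1:
            labels[t] = j1
            s1 += ctx.data[i]
            n1 += 1
        else:
            labels[t] = j2
            s2 += ctx.data[i]
            n2 += 1
    return labels, (s1, n1), (s2, n2), logq


def _m3_reshuffle(st, ctx, rng, beta, record=None) -> bool:
    """Sequential two-cluster reshuffle: empty two clusters and refill them
    item by item from the collapsed predictive (independence-type proposal
    with an exactly replayable reverse probability)."""
    K = st.K
    j1, j2 = (int(v) for v in rng.choice(K, size=2, replace=False))
    members = np.flatnonzero((st.z == j1) | (st.z == j2))
    if members.size == 0:
        return True
    old_labels = st.z[members].copy()
    new_labels, (s1, n1), (s2, n2), logq_fwd = _sequential_alloc(
        ctx, members, j1, j2, rng, forced=None
    )
    _, _, _, logq_rev = _sequential_alloc(ctx, members, j1, j2, None, forced=old_labels)
    delta = _pair_delta(
        ctx,
        old=[(st.s[j1], int(st.nk[j1])), (st.s[j2], int(st.nk[j2]))],
        new=[(s1, n1), (s2, n2)],
    )
    log_acc = beta * delta + logq_rev - logq_fwd
    if record is not None:
        z_new = st.z.copy()
        z_new[members] = new_labels
        record.update(move="m3", j1=j1, j2=j2, logq_fwd=logq_fwd, logq_rev=logq_rev,
                      z_old=st.z.copy(), z_new=z_new, log_accept=min(0.0, log_acc))
    if np.log(rng.random()) < log_acc:
        st.z[members] = new_labels
        st.s[j1], st.nk[j1] = s1, n1
        st.s[j2], st.nk[j2] = s2, n2
        st.log_post += delta
        return True
    return False


def _k_delta(ctx: _Ctx, k_old: int, k_new: int) -> float:
    """Allocation-prior normalizer + K-prior change when K changes."""
    return (
        ctx.alloc_norm(k_new)
        - ctx.alloc_norm(k_old)
        + ctx.logpk[k_new - 1]
        - ctx.logpk[k_old - 1]
    )


def _eject(st, ctx, rng, beta, record=None) -> bool:
    # The ejected cluster is created at the top label and then swapped into a
    # uniformly chosen label slot; this makes eject the exact labeled-space
    # inverse of absorb (which swaps the top label back into the vacated
    # slot), and the label-choice factors cancel out of the acceptance ratio.
    K = st.K
    if K >= ctx.cfg.kmax:
        return False
    j1 = int(rng.integers(K))
    members = np.flatnonzero(st.z == j1)
    n1 = int(st.nk[j1])
    p = rng.random()  # uniform ejection probability, integrated out below
    sel = rng.random(members.size) < p if members.size else np.zeros(0, dtype=bool)
    S = members[sel]
    mS = int(S.size)
    u = int(rng.integers(K + 1))  # label slot for the new cluster
    dS = ctx.data[S].sum(axis=0).astype(np.int64) if mS else np.zeros(ctx.m, dtype=np.int64)
    s1n = st.s[j1] - dS
    delta = (
        ctx.logmarg(s1n, n1 - mS)
        + ctx.logmarg(dS, mS)
        - ctx.logmarg(st.s[j1], n1)
        + ctx.GG[n1 - mS]
        + ctx.GG[mS]
        - ctx.GG[n1]
        - ctx.GG[0]
        + _k_delta(ctx, K, K + 1)
    )
    log_acc = beta * delta - float(betaln(mS + 1, n1 - mS + 1))
    if record is not None:
        record.update(move="eject", log_accept=min(0.0, log_acc))
    if np.log(rng.random()) < log_acc:
        st.z[S] = K
        st.s[j1], st.nk[j1] = s1n, n1 - mS
        st.s[K], st.nk[K] = dS, mS
        if u != K:
            moved = st.z == u
            st.z[st.z == K] = -1
            st.z[moved] = K
            st.z[st.z == -1] = u
            su, nu = st.s[u].copy(), int(st.nk[u])
            st.s[u], st.nk[u] = st.s[K].copy(), int(st.nk[K])
            st.s[K], st.nk[K] = su, nu
        st.K = K + 1
        st.log_post += delta
        return True
    return False


def _absorb(st, ctx, rng, beta, record=None) -> bool:
    K = st.K
    if K <= 1:
        return False
    keep, gone = (int(v) for v in rng.choice(K, size=2, replace=False))
    n_keep, n_gone = int(st.nk[keep]), int(st.nk[gone])
    s_merged = st.s[keep] + st.s[gone]
    delta = (
        ctx.logmarg(s_merged, n_keep + n_gone)
        - ctx.logmarg(st.s[keep], n_keep)
        - ctx.logmarg(st.s[gone], n_gone)
        + ctx.GG[n_keep + n_gone]
        - ctx.GG[n_keep]
        - ctx.GG[n_gone]
        + ctx.GG[0]
        + _k_delta(ctx, K, K - 1)
    )
    log_acc = beta * delta + float(betaln(n_gone + 1, n_keep + 1))
    if record is not None:
        record.update(move="absorb", log_accept=min(0.0, log_acc))
    if np.log(rng.random()) < log_acc:
        st.z[st.z == gone] = keep
        st.s[keep], st.nk[keep] = s_merged, n_keep + n_gone
        last = K - 1
        if gone != last:
            st.z[st.z == last] = gone
            st.s[gone], st.nk[gone] = st.s[last].copy(), int(st.nk[last])
        st.s[last] = 0
        st.nk[last] = 0
        st.K = K - 1
        st.log_post += delta
        return True
    return False


# ---------------------------------------------------------------------------
# public move operations


def gibbs_sweep(
    state: AllocationState,
    data: np.ndarray,
    config: MixtureConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
    items: Iterable[int] | None = None,
) -> AllocationState:
    """Collapsed Gibbs sweep: each item is reassigned from its full
    conditional over the K current labels.  ``items`` restricts the sweep
    (used by diagnostics); the tracked log posterior stays consistent with
    from-scratch recomputation."""
    ctx = _get_ctx(data, config)
    _gibbs_impl(state, ctx, rng, beta, items)
    return state


def full_conditional(
    state: AllocationState, item: int, data: np.ndarray, config: MixtureConfig
) -> np.ndarray:
    """Exact full-conditional probabilities of one item's label given the
    rest of the allocation (diagnostic helper)."""
    ctx = _get_ctx(data, config)
    _remove_item(state, item, ctx)
    w = _item_logweights(state, item, ctx)
    _insert_item(state, item, int(state.z[item]), ctx)
    w = w - w.max()
    p = np.exp(w)
    return p / p.sum()


def metropolis_moves(
    state: AllocationState,
    data: np.ndarray,
    config: MixtureConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
    moves: Sequence[str] = ("m1", "m2", "m3"),
    record: dict | None = None,
) -> AllocationState:
    """Fixed-dimension Metropolis moves (no-ops when K < 2): subset swap
    (m1), subset mass reallocation (m2), sequential reshuffle (m3).  Each
    satisfies detailed balance on the collapsed posterior."""
    if state.K < 2:
        return state
    ctx = _get_ctx(data, config)
    table = {"m1": _m1_swap, "m2": _m2_mass, "m3": _m3_reshuffle}
    for name in moves:
        table[name](state, ctx, rng, beta, record=record)
    return state


def eject_absorb(
    state: AllocationState,
    data: np.ndarray,
    config: MixtureConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
    record: dict | None = None,
) -> AllocationState:
    """Trans-dimensional pair: eject splits a random cluster binomially into
    a new label (blocked at K = kmax); absorb merges one cluster into
    another (blocked at K = 1).  Paired proposal terms give detailed
    balance across dimensions."""
    ctx = _get_ctx(data, config)
    if rng.random() < 0.5:
        _eject(state, ctx, rng, beta, record=record)
    else:
        _absorb(state, ctx, rng, beta, record=record)
    return state


# ---------------------------------------------------------------------------
# the full sampler


def mc3_run(data: np.ndarray | pd.DataFrame, config: MixtureConfig) -> SampleChain:
    """Metropolis-coupled run of the allocation sampler.

    ``n_chains`` tempered chains (beta_c = 1/(1 + delta*c)) each run the full
    move schedule per sweep (Gibbs sweep, m1-m3, eject/absorb); one adjacent
    pair attempts a state swap per sweep.  Cold-chain draws are retained
    after burn-in and thinning.  Fully reproducible from ``config.seed``.
    """
    ctx = _Ctx(data, config)
    n_chains = config.n_chains
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_chains + 1)
    rngs = [np.random.default_rng(c) for c in children[:n_chains]]
    swap_rng = np.random.default_rng(children[-1])
    betas = 1.0 / (1.0 + config.delta * np.arange(n_chains))

    # Start every chain at K = kmax with a random allocation: the Gibbs sweep
    # then finds fine structure within existing labels and the chain reaches
    # the posterior mostly through easy absorb moves.  (Starting at K = 1
    # instead requires eject to propose near-perfect splits, whose acceptance
    # is exponentially small for well-separated clusters.)
    states = []
    for c in range(n_chains):
        z0 = rngs[c].integers(config.kmax, size=ctx.n)
        states.append(AllocationState.from_allocation(z0, config.kmax, ctx.data, config))

    accept = {name: np.zeros(n_chains, dtype=np.int64) for name in ("m1", "m2", "m3", "eject", "absorb")}
    propose = {name: np.zeros(n_chains, dtype=np.int64) for name in ("m1", "m2", "m3", "eject", "absorb")}
    swap_acc = np.zeros(max(n_chains - 1, 1), dtype=np.int64)
    swap_try = np.zeros(max(n_chains - 1, 1), dtype=np.int64)

    keep_from = int(config.burn_in * config.n_sweeps)
    ks: list[int] = []
    zs: list[np.ndarray] = []
    lps: list[float] = []

    for sweep in range(config.n_sweeps):
        for c in range(n_chains):
            st, rng, beta = states[c], rngs[c], betas[c]
            _gibbs_impl(st, ctx, rng, beta)
            if st.K >= 2:
                for name, fn in (("m1", _m1_swap), ("m2", _m2_mass), ("m3", _m3_reshuffle)):
                    propose[name][c] += 1
                    if fn(st, ctx, rng, beta):
                        accept[name][c] += 1
            if rng.random() < 0.5:
                propose["eject"][c] += 1
                if _eject(st, ctx, rng, beta):
                    accept["eject"][c] += 1
            else:
                propose["absorb"][c] += 1
                if _absorb(st, ctx, rng, beta):
                    accept["absorb"][c] += 1
        if n_chains > 1:
            pair = int(swap_rng.integers(n_chains - 1))
            swap_try[pair] += 1
            log_r = (betas[pair] - betas[pair + 1]) * (
                states[pair + 1].log_post - states[pair].log_post
            )
            if np.log(swap_rng.random()) < log_r:
                states[pair], states[pair + 1] = states[pair + 1], states[pair]
                swap_acc[pair] += 1
        if (sweep + 1) % _REFRESH_EVERY == 0:
            for st in states:
                st.log_post = log_collapsed_posterior(st.K, st.z, ctx.data, config)
        if not math.isfinite(states[0].log_post):
            raise FloatingPointError(
                f"non-finite cold-chain log posterior at sweep {sweep}: aborting"
            )
        if sweep >= keep_from and (sweep - keep_from) % config.thin == 0:
            cold = states[0]
            ks.append(cold.K)
            zs.append(cold.z.copy())
            lps.append(cold.log_post)

    diagnostics = {
        "acceptance": {
            name: (accept[name] / np.maximum(propose[name], 1)).tolist() for name in accept
        },
        "swap_rate": (swap_acc / np.maximum(swap_try, 1)).tolist(),
        "betas": betas.tolist(),
        "n_sweeps": config.n_sweeps,
        "n_retained": len(ks),
    }
    return SampleChain(
        ks=np.asarray(ks, dtype=np.int64),
        zs=np.asarray(zs, dtype=np.int64),
        log_posts=np.asarray(lps, dtype=float),
        kmax=config.kmax,
        seed=config.seed,
        diagnostics=diagnostics,
    )


def posterior_over_K(chain: SampleChain, kmax: int | None = None) -> pd.Series:
    """Empirical posterior over K from the retained cold-chain draws
    (index 1..kmax; sums to 1)."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    kmax = kmax or chain.kmax
    counts = np.bincount(chain.ks, minlength=kmax + 1)[1 : kmax + 1]
    probs = counts / counts.sum()
    return pd.Series(probs, index=pd.RangeIndex(1, kmax + 1, name="K"), name="posterior")


def modal_k(posterior: pd.Series) -> int:
    """Modal K; ties broken toward the smaller K (parsimony)."""
    best = posterior[posterior == posterior.max()]
    return int(best.index.min())


# ---------------------------------------------------------------------------
# enumeration oracle


def exact_posterior_small(
    data: np.ndarray | pd.DataFrame, config: MixtureConfig
) -> tuple[pd.Series, dict[tuple[int, tuple[int, ...]], float]]:
    """Exact posterior over (K, z) and over K by exhaustive enumeration.

    Sums the collapsed unnormalized mass over every allocation for each
    K <= kmax.  Refuses instances with more than 10^7 states.
    """
    arr = _as_binary(data)
    n = arr.shape[0]
    n_states = sum(k**n for k in range(1, config.kmax + 1))
    if n_states > _ENUM_GUARD:
        raise ValueError(
            f"enumeration would visit {n_states} states (> {_ENUM_GUARD}); "
            "instance too large for the exact oracle"
        )
    log_masses: list[float] = []
    keys: list[tuple[int, tuple[int, ...]]] = []
    for K in range(1, config.kmax + 1):
        for z in itertools.product(range(K), repeat=n):
            keys.append((K, z))
            log_masses.append(log_collapsed_posterior(K, np.asarray(z), arr, config))
    log_masses_arr = np.asarray(log_masses)
    norm = logsumexp(log_masses_arr)
    probs = np.exp(log_masses_arr - norm)
    joint = dict(zip(keys, probs.tolist()))
    pk = np.zeros(config.kmax)
    for (K, _), p in joint.items():
        pk[K - 1] += p
    series = pd.Series(
        pk, index=pd.RangeIndex(1, config.kmax + 1, name="K"), name="posterior"
    )
    return series, joint
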