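"""Label-switching resolution with the Equivalence Classes Representatives
(ECR) algorithm.

Mixture allocations are only identified up to a permutation of cluster
labels, so raw MCMC draws cannot be averaged directly.  ECR fixes a pivot
allocation (here: the maximum-a-posteriori draw among those retained) and,
for every draw, applies the label permutation that minimizes the number of
items whose label disagrees with the pivot — an assignment problem on the
K x K agreement matrix.  Membership probabilities are then empirical
frequencies over the relabeled draws, conditional on the selected number of
clusters K*.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .bernoulli_mixture import SampleChain

__all__ = [
    "RelabeledChain",
    "AssignmentMatrix",
    "select_conditional_draws",
    "select_pivot",
    "ecr_permute",
    "relabel_chain",
    "assignment_matrix",
]

_BRUTE_FORCE_MAX_K = 7
_MIN_DRAWS_WARN = 100


@dataclass
class RelabeledChain:
    """ECR output: pivot, per-draw permutations, and relabeled draws
    (all with K = k_star).  ``provenance`` holds the indices of the retained
    draws within the original chain."""

    k_star: int
    pivot: np.ndarray
    permutations: np.ndarray  # (n_draws, k_star); perm[d, old_label] = new_label
    draws: np.ndarray  # (n_draws, n_items) relabeled
    log_posts: np.ndarray
    provenance: np.ndarray


@dataclass
class AssignmentMatrix:
    """Component x cluster posterior assignment probabilities under K*."""

    probs: pd.DataFrame  # rows: components, columns: cluster indices 0..K*-1
    modal_cluster: pd.Series
    modal_probability: pd.Series


def select_conditional_draws(
    chain: SampleChain, k_star: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draws with K = k_star, in chain order.

    Returns (indices, allocations, log_posts).  Errors when no draw has
    K = k_star; warns when fewer than 100 draws remain.
    """
    idx = np.flatnonzero(chain.ks == k_star)
    if idx.size == 0:
        raise ValueError(
            f"no retained draws with K = {k_star}; run more sweeps or check the "
            "posterior over K"
        )
    if idx.size < _MIN_DRAWS_WARN:
        warnings.warn(
            f"only {idx.size} draws at K = {k_star}; membership probabilities "
            "will be noisy",
            stacklevel=2,
        )
    return idx, chain.zs[idx], chain.log_posts[idx]


def select_pivot(draws: np.ndarray, log_posts: np.ndarray) -> int:
    """Index of the pivot: the draw with maximal collapsed log posterior
    (MAP among retained draws); ties go to the earliest draw."""
    if draws.shape[0] == 0:
        raise ValueError("no draws to pick a pivot from")
    return int(np.argmax(log_posts))  # argmax returns the first maximum


def _agreement(draw: np.ndarray, pivot: np.ndarray, k_star: int) -> np.ndarray:
    a = np.zeros((k_star, k_star), dtype=np.int64)
    np.add.at(a, (draw, pivot), 1)
    return a


def ecr_permute(draw: np.ndarray, pivot: np.ndarray, k_star: int) -> np.ndarray:
    """Permutation of 0..K*-1 minimizing disagreement with the pivot.

    Returns ``perm`` with ``perm[old_label] = new_label``.  Solved by brute
    force (lexicographically smallest optimum) for K* <= 7 and by the
    Hungarian algorithm above.  Empty labels simply contribute zero
    agreement and are permuted along with the rest.
    """
    draw = np.asarray(draw)
    pivot = np.asarray(pivot)
    if draw.shape != pivot.shape:
        raise ValueError("draw and pivot must have the same length")
    agree = _agreement(draw, pivot, k_star)
    if k_star <= _BRUTE_FORCE_MAX_K:
        best_perm: tuple[int, ...] | None = None
        best_score = -1
        rng_labels = range(k_star)
        for perm in itertools.permutations(rng_labels):
            score = int(agree[rng_labels, perm].sum())
            if score > best_score:  # lexicographic order of enumeration breaks ties
                best_score = score
                best_perm = perm
        return np.asarray(best_perm, dtype=np.int64)
    rows, cols = linear_sum_assignment(-agree)
    perm = np.empty(k_star, dtype=np.int64)
    perm[rows] = cols
    return perm


def relabel_chain(
    chain: SampleChain, k_star: int, pivot_index: int | None = None
) -> RelabeledChain:
    """Apply ECR to the draws at K = k_star.

    Relabeling permutes labels only, so every draw's collapsed posterior
    mass is unchanged.
    """
    idx, draws, log_posts = select_conditional_draws(chain, k_star)
    p = select_pivot(draws, log_posts) if pivot_index is None else pivot_index
    pivot = draws[p]
    n_draws = draws.shape[0]
    perms = np.empty((n_draws, k_star), dtype=np.int64)
    out = np.empty_like(draws)
    for d in range(n_draws):
        perm = ecr_permute(draws[d], pivot, k_star)
        perms[d] = perm
        out[d] = perm[draws[d]]
    return RelabeledChain(
        k_star=k_star,
        pivot=pivot.copy(),
        permutations=perms,
        draws=out,
        log_posts=log_posts.copy(),
        provenance=idx,
    )


def assignment_matrix(
    relabeled: RelabeledChain, component_ids: list[str] | None = None
) -> AssignmentMatrix:
    """Posterior assignment probabilities: entry (i, k) is the fraction of
    relabeled draws placing component i in cluster k.  Modal membership
    breaks ties toward the lower cluster index."""
    n_draws, n_items = relabeled.draws.shape
    if n_draws == 0:
        raise ValueError("empty relabeled chain")
    k_star = relabeled.k_star
    counts = np.zeros((n_items, k_star), dtype=np.int64)
    for d in range(n_draws):
        counts[np.arange(n_items), relabeled.draws[d]] += 1
    probs = counts / n_draws
    index = component_ids if component_ids is not None else list(range(n_items))
    frame = pd.DataFrame(probs, index=index, columns=list(range(k_star)))
    modal = pd.Series(np.argmax(probs, axis=1), index=index)  # first max = lower index
    modal_p = pd.Series(probs[np.arange(n_items), modal.to_numpy()], index=index)
    return AssignmentMatrix(probs=frame, modal_cluster=modal, modal_probability=modal_p)
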