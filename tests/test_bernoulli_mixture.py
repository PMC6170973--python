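"""Collapsed Bernoulli-mixture posterior, the allocation sampler and its
enumeration oracle."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp

from allergotype.bernoulli_mixture import (
    AllocationState,
    MixtureConfig,
    default_kmax,
    eject_absorb,
    exact_posterior_small,
    full_conditional,
    gibbs_sweep,
    log_allocation_prior,
    log_collapsed_posterior,
    log_k_prior,
    log_marginal_cluster,
    mc3_run,
    metropolis_moves,
    modal_k,
    posterior_over_K,
)

TOY5 = np.array(
    [[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1], [1, 0, 0]], dtype=np.uint8
)


def tv(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


class TestCollapsedPieces:
    def test_single_bernoulli_uniform_prior(self):
        # one item, one subject, positive: marginal = int theta dtheta = 1/2
        assert log_marginal_cluster([1], 1, 1, 1) == pytest.approx(np.log(0.5))

    def test_two_positives_one_subject(self):
        # marginal = int theta^2 dtheta = 1/3; cross-check by quadrature
        expected, _ = quad(lambda t: t**2, 0, 1)
        assert log_marginal_cluster([2], 2, 1, 1) == pytest.approx(np.log(expected))

    def test_additive_over_subjects_and_order_invariant(self):
        s = [3, 1, 2]
        total = log_marginal_cluster(s, 4, 1.5, 0.5)
        parts = sum(log_marginal_cluster([x], 4, 1.5, 0.5) / 1 for x in s)
        assert total == pytest.approx(parts)
        assert total == pytest.approx(log_marginal_cluster(s[::-1], 4, 1.5, 0.5))

    def test_allocation_prior_enumeration(self):
        # n=2, K=2, gamma=1: allocations (0,0),(1,1) have mass 1/3 and
        # (0,1),(1,0) mass 1/6
        assert log_allocation_prior([0, 1], 2, 1.0) == pytest.approx(np.log(1 / 6))
        assert log_allocation_prior([0, 0], 2, 1.0) == pytest.approx(np.log(1 / 3))

    def test_allocation_prior_k1_is_zero(self):
        assert log_allocation_prior([0, 0, 0], 1, 2.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,K,gamma", [(3, 2, 1.0), (4, 3, 0.5), (6, 3, 2.0)])
    def test_allocation_prior_normalized(self, n, K, gamma):
        total = logsumexp(
            [log_allocation_prior(z, K, gamma) for z in itertools.product(range(K), repeat=n)]
        )
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_k_prior_normalized(self):
        for prior in ("uniform", "poisson"):
            cfg = MixtureConfig(kmax=6, k_prior=prior)
            assert sum(np.exp(log_k_prior(k, cfg)) for k in range(1, 7)) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        cfg = MixtureConfig(kmax=3)
        z = np.array([0, 1, 2, 1, 0])
        base = log_collapsed_posterior(3, z, TOY5, cfg)
        for perm in itertools.permutations(range(3)):
            relabeled = np.asarray(perm)[z]
            assert log_collapsed_posterior(3, relabeled, TOY5, cfg) == pytest.approx(base)

    def test_missing_cells_rejected(self):
        cfg = MixtureConfig(kmax=2)
        bad = TOY5.astype(float).copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            log_collapsed_posterior(1, np.zeros(5, dtype=int), bad, cfg)

    def test_complement_symmetry(self):
        # with beta_a == beta_b, flipping every 0/1 leaves the posterior alone
        cfg = MixtureConfig(kmax=3, beta_a=1.0, beta_b=1.0)
        z = np.array([0, 1, 0, 2, 1])
        assert log_collapsed_posterior(3, z, 1 - TOY5, cfg) == pytest.approx(
            log_collapsed_posterior(3, z, TOY5, cfg)
        )

    def test_duplicate_profiles_merge_changes_prior_terms_only(self):
        # two clusters with identical per-subject counts: merging changes the
        # posterior only through allocation-prior and K-prior terms, because
        # the Beta-Bernoulli marginal is a function of the per-cluster counts
        data = np.array([[1, 0], [1, 0], [1, 0], [1, 0]], dtype=np.uint8)
        cfg = MixtureConfig(kmax=2, k_prior="uniform")
        split = log_collapsed_posterior(2, np.array([0, 0, 1, 1]), data, cfg)
        merged = log_collapsed_posterior(1, np.array([0, 0, 0, 0]), data, cfg)
        lik_split = 2 * log_marginal_cluster([2, 0], 2, 1, 1)
        lik_merged = log_marginal_cluster([4, 0], 4, 1, 1)
        prior_split = log_allocation_prior([0, 0, 1, 1], 2, 1.0)
        prior_merged = log_allocation_prior([0, 0, 0, 0], 1, 1.0)
        assert split - merged == pytest.approx(
            (lik_split - lik_merged) + (prior_split - prior_merged)
        )


class TestExactOracle:
    def test_distribution_sums_to_one(self):
        cfg = MixtureConfig(kmax=3)
        post_k, joint = exact_posterior_small(TOY5, cfg)
        assert sum(joint.values()) == pytest.approx(1.0)
        assert post_k.sum() == pytest.approx(1.0)

    def test_single_item_posterior_proportional_to_k_prior(self):
        cfg = MixtureConfig(kmax=4, k_prior="poisson")
        post_k, _ = exact_posterior_small(np.array([[1, 0]], dtype=np.uint8), cfg)
        expected = np.exp([log_k_prior(k, cfg) for k in range(1, 5)])
        np.testing.assert_allclose(post_k.to_numpy(), expected, atol=1e-12)

    def test_duplicated_items_favor_fewer_clusters(self):
        cfg = MixtureConfig(kmax=3)
        rng = np.random.default_rng(0)
        dup = np.tile(rng.integers(0, 2, size=(1, 4)), (6, 1)).astype(np.uint8)
        mixed = rng.integers(0, 2, size=(6, 4)).astype(np.uint8)
        pk_dup, _ = exact_posterior_small(dup, cfg)
        pk_mixed, _ = exact_posterior_small(mixed, cfg)
        assert pk_dup[1] > pk_mixed[1]

    def test_guard_refuses_large_instances(self):
        cfg = MixtureConfig(kmax=25)
        with pytest.raises(ValueError, match="10000000"):
            exact_posterior_small(np.zeros((30, 2), dtype=np.uint8), cfg)


class TestMoves:
    def make_state(self, z, K, data, cfg):
        return AllocationState.from_allocation(np.asarray(z), K, data, cfg)

    def test_gibbs_single_item_k1_unchanged(self):
        cfg = MixtureConfig(kmax=1)
        data = np.array([[1, 0, 1]], dtype=np.uint8)
        st = self.make_state([0], 1, data, cfg)
        before = st.log_post
        gibbs_sweep(st, data, cfg, np.random.default_rng(0))
        assert st.K == 1 and st.z.tolist() == [0]
        assert st.log_post == pytest.approx(before)

    def test_incremental_log_post_matches_recomputation(self):
        cfg = MixtureConfig(kmax=3)
        rng = np.random.default_rng(1)
        st = self.make_state([0, 1, 2, 0, 1], 3, TOY5, cfg)
        for _ in range(200):
            gibbs_sweep(st, TOY5, cfg, rng)
            metropolis_moves(st, TOY5, cfg, rng)
            eject_absorb(st, TOY5, cfg, rng)
            assert st.log_post == pytest.approx(
                log_collapsed_posterior(st.K, st.z, TOY5, cfg), abs=1e-8
            )

    def test_full_conditional_matches_enumeration(self):
        # condition on z[1], z[2] fixed; enumerate z[0] against the collapsed
        # posterior directly
        data = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1]], dtype=np.uint8)
        cfg = MixtureConfig(kmax=2)
        st = self.make_state([0, 0, 1], 2, data, cfg)
        probs = full_conditional(st, 0, data, cfg)
        masses = np.array(
            [
                np.exp(log_collapsed_posterior(2, np.array([k, 0, 1]), data, cfg))
                for k in range(2)
            ]
        )
        np.testing.assert_allclose(probs, masses / masses.sum(), atol=1e-12)

    def test_gibbs_sampling_frequencies_match_conditional(self):
        # resample a single item 50k times with the rest pinned: empirical
        # frequencies must match the exact conditional within Monte Carlo error
        data = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1]], dtype=np.uint8)
        cfg = MixtureConfig(kmax=2)
        st = self.make_state([0, 0, 1], 2, data, cfg)
        target = full_conditional(st, 0, data, cfg)
        rng = np.random.default_rng(42)
        n = 50_000
        counts = np.zeros(2)
        for _ in range(n):
            gibbs_sweep(st, data, cfg, rng, items=[0])
            counts[st.z[0]] += 1
        freq = counts / n
        se = np.sqrt(target * (1 - target) / n)
        assert np.all(np.abs(freq - target) < 4 * se + 1e-9)

    def test_metropolis_identity_proposal_accepted(self):
        # an m1 proposal that reproduces the current state has delta = 0 and
        # must be accepted with probability 1
        data = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        cfg = MixtureConfig(kmax=2)
        st = self.make_state([0, 1], 2, data, cfg)
        rec: dict = {}
        metropolis_moves(st, data, cfg, np.random.default_rng(5), moves=("m1",), record=rec)
        if np.array_equal(rec["z_new"], rec["z_old"]):
            assert rec["log_accept"] == pytest.approx(0.0)

    def test_recorded_acceptance_matches_hand_recomputation(self):
        # replay recorded proposals on a 4-item fixture and recompute each
        # acceptance from scratch: exp(delta log posterior) x proposal ratio
        cfg = MixtureConfig(kmax=3)
        rng = np.random.default_rng(11)
        data = TOY5[:4]
        st = self.make_state([0, 1, 2, 0], 3, data, cfg)
        for trial in range(30):
            for move in ("m1", "m2", "m3"):
                rec: dict = {}
                metropolis_moves(st, data, cfg, rng, moves=(move,), record=rec)
                if not rec:  # both chosen clusters empty: no proposal made
                    continue
                lp_old = log_collapsed_posterior(3, rec["z_old"], data, cfg)
                lp_new = log_collapsed_posterior(3, rec["z_new"], data, cfg)
                delta = lp_new - lp_old
                if move == "m1":  # symmetric proposal
                    log_ratio = 0.0
                elif move == "m2":  # subset move of |S| items from j1 to j2
                    log_ratio = (rec["n1"] - rec["n2"] - rec["subset_size"]) * np.log(2.0)
                else:  # sequential reshuffle: replayed reverse / forward
                    log_ratio = rec["logq_rev"] - rec["logq_fwd"]
                assert rec["log_accept"] == pytest.approx(
                    min(0.0, delta + log_ratio), abs=1e-8
                )
                st = self.make_state(st.z, st.K, data, cfg)

    def test_eject_blocked_at_kmax_absorb_blocked_at_k1(self):
        data = TOY5[:3]
        cfg = MixtureConfig(kmax=2)
        rng = np.random.default_rng(3)
        st_low = self.make_state([0, 0, 0], 1, data, cfg)
        st_hi = self.make_state([0, 1, 0], 2, data, cfg)
        for _ in range(50):
            # force the absorb branch at K=1: state must never change
            eject_absorb(st_low, data, cfg, rng)
            assert st_low.K >= 1
            eject_absorb(st_hi, data, cfg, rng)
            assert st_hi.K <= 2


class TestSampler:
    def test_same_seed_bit_identical(self):
        cfg = MixtureConfig(kmax=3, n_chains=2, n_sweeps=300, seed=123)
        c1 = mc3_run(TOY5, cfg)
        c2 = mc3_run(TOY5, cfg)
        np.testing.assert_array_equal(c1.ks, c2.ks)
        np.testing.assert_array_equal(c1.zs, c2.zs)
        np.testing.assert_array_equal(c1.log_posts, c2.log_posts)

    def test_posterior_over_k_sums_to_one_and_modal_tie_rule(self):
        cfg = MixtureConfig(kmax=3, n_chains=1, n_sweeps=200, seed=5)
        chain = mc3_run(TOY5, cfg)
        post = posterior_over_K(chain)
        assert post.sum() == pytest.approx(1.0)
        import pandas as pd

        tied = pd.Series([0.4, 0.4, 0.2], index=pd.RangeIndex(1, 4, name="K"))
        assert modal_k(tied) == 1

    def test_plain_sampler_matches_oracle(self):
        # n_chains=1 degrades to the plain allocation sampler; its posterior
        # over K must agree with exhaustive enumeration
        cfg = MixtureConfig(kmax=3, n_chains=1, n_sweeps=30_000, seed=9)
        exact, _ = exact_posterior_small(TOY5, cfg)
        post = posterior_over_K(mc3_run(TOY5, cfg))
        assert tv(post.to_numpy(), exact.to_numpy()) < 0.05

    def test_tempered_sampler_matches_oracle(self):
        cfg = MixtureConfig(kmax=3, n_chains=3, n_sweeps=30_000, seed=17)
        exact, _ = exact_posterior_small(TOY5, cfg)
        post = posterior_over_K(mc3_run(TOY5, cfg))
        assert tv(post.to_numpy(), exact.to_numpy()) < 0.05

    def test_equal_temperature_swap_always_accepts(self):
        # delta -> 0 makes all chains cold; every attempted swap must succeed
        cfg = MixtureConfig(kmax=3, n_chains=2, delta=1e-12, n_sweeps=500, seed=2)
        chain = mc3_run(TOY5, cfg)
        assert chain.diagnostics["swap_rate"][0] == pytest.approx(1.0)

    def test_default_kmax_mirrors_panel_sizes(self):
        assert default_kmax(10) == 9
        assert default_kmax(72) == 25
        assert default_kmax(1) == 1
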