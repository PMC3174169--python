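"""Proposals, acceptance rule, stochastic mapping, augmentation, summaries."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from intronevo.mcmc import (
    ChainState,
    MCMCConfig,
    MCMCError,
    Proposal,
    ProposalConfig,
    SampleStore,
    accept_step,
    potential_scale_reduction,
    propose,
    run_chains,
    sample_all_absent,
    sample_site_history,
    summarize,
)
from intronevo.ml import node_posteriors
from intronevo.model import EdgeParams, ModelParams, TreeArrays, p_all_absent
from intronevo.profiles import AMBIGUOUS, ProfileTable, Site

from .conftest import make_params


def _table(cols, species):
    sites = [Site(f"g1:{j+1}:0", "g1", 0) for j in range(len(cols))]
    return ProfileTable(list(species), sites, np.array(cols, dtype=np.int8).T)


class TestPropose:
    def test_zero_delta_is_identity_with_zero_ratio(self, cherry3, params3):
        rng = np.random.default_rng(0)
        prop = propose(params3, rng, ProposalConfig(delta=0.0))
        assert prop.log_hastings == 0.0
        assert prop.params.to_dict() == pytest.approx(params3.to_dict())

    def test_single_scalar_hastings_is_log_multiplier(self, cherry3, params3):
        # when the pi block is chosen, the ratio equals log(pi'/pi)
        rng = np.random.default_rng(1)
        seen = 0
        for _ in range(200):
            prop = propose(params3, rng, ProposalConfig(delta=0.4))
            d_old, d_new = params3.to_dict(), prop.params.to_dict()
            changed = [k for k in d_old
                       if not np.isclose(d_new[k], d_old[k], rtol=1e-15)]
            if changed == ["pi"]:
                seen += 1
                m = d_new["pi"] / d_old["pi"]
                assert prop.log_hastings == pytest.approx(np.log(m), abs=1e-12)
        assert seen > 10

    def test_out_of_support_flagged_invalid(self, cherry3):
        params = ModelParams(pi=0.9, edge_params={
            n: EdgeParams(1.0, 0.5) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(2)
        saw_invalid = False
        for _ in range(500):
            prop = propose(params, rng, ProposalConfig(delta=1.0))
            if not prop.valid:
                saw_invalid = True
                continue
            d = prop.params.to_dict()
            assert 0 <= d["pi"] <= 1
        assert saw_invalid  # pi=0.9 scaled by e^u easily exceeds 1

    def test_multiplicative_kernel_density(self, cherry3, params3):
        """The pi-block multiplier m = e^u, u~U(-d,d): check its CDF."""
        rng = np.random.default_rng(3)
        delta = 0.5
        ms = []
        for _ in range(4000):
            prop = propose(params3, rng, ProposalConfig(delta=delta))
            d_old, d_new = params3.to_dict(), prop.params.to_dict()
            if not np.isclose(d_new["pi"], d_old["pi"], rtol=1e-15):
                only_pi = all(np.isclose(d_new[k], d_old[k], rtol=1e-15)
                              for k in d_old if k != "pi")
                if only_pi:
                    ms.append(np.log(d_new["pi"] / d_old["pi"]))
        stat = kstest(ms, "uniform", args=(-delta, 2 * delta))
        assert stat.pvalue > 0.01


class TestAcceptStep:
    def test_identical_proposal_always_accepted(self):
        rng = np.random.default_rng(0)
        state = ChainState(params=None, log_likelihood=-10.0)
        for _ in range(50):
            prop = Proposal(params=None, log_hastings=0.0, valid=True)
            new, ok = accept_step(state, prop, lambda p: -10.0, rng)
            assert ok

    def test_invalid_proposal_never_accepted(self):
        rng = np.random.default_rng(0)
        state = ChainState(params="x", log_likelihood=-1.0)
        prop = Proposal(params="y", log_hastings=0.0, valid=False)
        for _ in range(50):
            new, ok = accept_step(state, prop, lambda p: 100.0, rng)
            assert not ok and new.params == "x"

    def test_two_point_acceptance_frequency_matches_metropolis(self):
        """Empirical acceptance of a worse state ≈ exp(Δll) within 3 SE."""
        rng = np.random.default_rng(4)
        delta_ll = -1.2
        p_true = np.exp(delta_ll)
        n, acc = 10_000, 0
        state = ChainState(params=0, log_likelihood=0.0)
        for _ in range(n):
            prop = Proposal(params=1, log_hastings=0.0, valid=True)
            _, ok = accept_step(state, prop, lambda p: delta_ll, rng)
            acc += ok
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(acc / n - p_true) < 3 * se

    def test_nonfinite_proposal_rejected(self):
        rng = np.random.default_rng(0)
        state = ChainState(params="x", log_likelihood=-1.0)
        prop = Proposal(params="y", log_hastings=0.0, valid=True)
        new, ok = accept_step(state, prop, lambda p: np.nan, rng)
        assert not ok


class TestSampleSiteHistory:
    def test_unambiguous_leaves_reproduced(self, tree6):
        rng = np.random.default_rng(5)
        params = make_params(tree6, rng)
        col = [1, 0, 1, AMBIGUOUS, 0, 1]
        for _ in range(20):
            h = sample_site_history(col, tree6, params, rng)
            for i, u in enumerate(tree6.leaves()):
                if col[i] != AMBIGUOUS:
                    assert h.labels[u] == col[i]

    def test_impossible_root_state_when_pi_zero(self, cherry3):
        params = ModelParams(pi=0.0, edge_params={
            n: EdgeParams(0.5, 0.0) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(6)
        # zero gain everywhere and pi=0: all-zero column forces all-absent
        for _ in range(10):
            h = sample_site_history([0, 0, 0], cherry3, params, rng)
            assert h.labels.sum() == 0

    def test_marginal_frequencies_match_exact_posteriors(self, tree6):
        """Mapping marginals agree with the up-down pass within 3 MC SE."""
        rng = np.random.default_rng(7)
        params = make_params(tree6, rng, k_loss=2)
        col = [1, 0, AMBIGUOUS, 1, 0, 0]
        n_draws = 4000
        table = _table([col] * n_draws, tree6.leaf_names())
        from intronevo.mcmc import sample_histories

        arrays = TreeArrays.build(tree6, table.species)
        labels, _ = sample_histories(table.entries, arrays, params, rng)
        freq = labels.mean(axis=0)
        exact = node_posteriors(_table([col], tree6.leaf_names()), tree6,
                                params).presence[0]
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_draws)
        assert np.all(np.abs(freq - exact) <= 3 * se + 1e-9)


class TestSampleAllAbsent:
    def test_p0_zero_gives_no_hidden_sites(self, cherry3):
        params = ModelParams(pi=1.0, edge_params={
            n: EdgeParams(1.0, 1.0) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(8)
        m, labels = sample_all_absent(100, cherry3, params, rng)
        assert m == 0 and labels.shape == (0, cherry3.n_nodes)

    def test_mean_matches_negative_binomial(self, cherry3, params3):
        rng = np.random.default_rng(9)
        p0 = p_all_absent(cherry3, params3)
        n_obs = 50
        want = n_obs * p0 / (1 - p0)
        draws = [sample_all_absent(n_obs, cherry3, params3, rng)[0]
                 for _ in range(3000)]
        var = n_obs * p0 / (1 - p0) ** 2
        se = np.sqrt(var / len(draws))
        assert abs(np.mean(draws) - want) < 3 * se

    def test_histories_all_absent_at_leaves(self, cherry3, params3):
        rng = np.random.default_rng(10)
        m, labels = sample_all_absent(200, cherry3, params3, rng)
        if m:
            assert labels[:, cherry3.leaves()].sum() == 0


class TestRunChains:
    def test_same_seed_identical_stores(self, cherry3, params3):
        table = _table([[1, 0, 1], [0, 1, 0], [1, 1, 1]], ["A", "B", "C"])
        cfg = MCMCConfig(n_chains=2, n_steps=300, burnin=100, thin=2, seed=42,
                         k_loss=2)
        a = run_chains(table, cherry3, cfg)
        b = run_chains(table, cherry3, cfg)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.loglik, b.loglik)

    def test_no_data_recovers_uniform_priors(self, cherry3):
        """With an empty table and no correction the target is the prior."""
        table = ProfileTable(["A", "B", "C"], [],
                             np.zeros((3, 0), dtype=np.int8))
        cfg = MCMCConfig(n_chains=4, n_steps=80000, burnin=5000, thin=30,
                         seed=7, k_gain=1, k_loss=1, adapt=False, delta=2.5,
                         observability_correction=False,
                         augment_all_absent=False)
        store = run_chains(table, cherry3, cfg)
        pi = store.params[:, :, store.param_names.index("pi")].ravel()
        stat = kstest(pi, "uniform")
        assert stat.pvalue > 0.01
        length = store.params[:, :,
                              store.param_names.index("edge.ab.length")].ravel()
        stat2 = kstest(length, "uniform", args=(0, 10))
        assert stat2.pvalue > 0.01

    def test_counts_conserved_between_store_and_summary(self, cherry3,
                                                        params3):
        table = _table([[1, 0, 1], [0, 1, 0]], ["A", "B", "C"])
        cfg = MCMCConfig(n_chains=1, n_steps=400, burnin=100, thin=3, seed=1,
                         k_loss=2)
        store = run_chains(table, cherry3, cfg)
        summ = summarize(store)
        for u, name in enumerate(store.node_names):
            med = np.median(store.counts[:, :, u])
            row = summ.node_stats.set_index("node").loc[name]
            assert row["count_median"] == pytest.approx(med)
            assert row["count_lo"] <= row["count_median"] <= row["count_hi"]


class TestSummarize:
    def _store(self, counts):
        counts = np.asarray(counts, dtype=float)[None, :, None]
        z = np.zeros_like(counts)
        return SampleStore(node_names=["root"], param_names=["pi"],
                           counts=counts, gains=z, losses=z,
                           params=counts.copy(), loglik=counts[:, :, 0],
                           m_unobserved=counts[:, :, 0],
                           acceptance=np.array([0.3]))

    def test_constant_samples_collapse_interval(self):
        s = summarize(self._store([5.0] * 100))
        row = s.node_stats.iloc[0]
        assert row["count_lo"] == row["count_median"] == row["count_hi"] == 5.0

    def test_percentiles_are_order_statistics(self):
        vals = np.arange(1, 1001, dtype=float)
        s = summarize(self._store(vals))
        row = s.node_stats.iloc[0]
        assert row["count_median"] == pytest.approx(np.median(vals))
        assert row["count_lo"] == pytest.approx(np.percentile(vals, 2.5))
        assert row["count_hi"] == pytest.approx(np.percentile(vals, 97.5))

    def test_gamma_sample_quantiles_match_closed_form(self):
        rng = np.random.default_rng(11)
        vals = rng.gamma(shape=3.0, scale=2.0, size=40_000)
        s = summarize(self._store(vals))
        row = s.node_stats.iloc[0]
        assert row["count_median"] == pytest.approx(
            gamma_dist.ppf(0.5, a=3.0, scale=2.0), rel=0.03)
        assert row["count_hi"] == pytest.approx(
            gamma_dist.ppf(0.975, a=3.0, scale=2.0), rel=0.03)

    def test_empty_store_rejected(self):
        store = self._store([1.0])
        store.counts = np.zeros((1, 0, 1))
        with pytest.raises(MCMCError):
            summarize(store)

    def test_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(12)
        chains = rng.normal(size=(4, 2000))
        assert potential_scale_reduction(chains) == pytest.approx(1.0,
                                                                  abs=0.05)
        shifted = chains + np.array([0, 0, 0, 10.0])[:, None]
        assert potential_scale_reduction(shifted) > 2.0
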