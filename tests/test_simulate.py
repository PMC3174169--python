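"""Synthetic-data generator: distributional fidelity and the scenarios."""

import numpy as np
import pytest
from scipy.stats import chisquare

from intronevo.model import EdgeParams, ModelParams, marginal_site_likelihood, p_all_absent
from intronevo.profiles import AMBIGUOUS, filter_columns
from intronevo.simulate import (
    apply_heterotachy,
    apply_missing_orthologs,
    default_generating_params,
    random_tree,
    simulate_dataset,
)
from intronevo.trees import SpeciesTree


class TestRandomTree:
    def test_two_leaves_is_a_cherry(self):
        tree = random_tree(2, np.random.default_rng(0))
        assert tree.n_leaves == 2 and tree.n_nodes == 3

    def test_trifurcating_root_option(self):
        tree = random_tree(9, np.random.default_rng(1), trifurcating_root=True)
        assert len(tree.children[tree.root]) == 3

    def test_leaf_names_unique_and_conventional(self):
        tree = random_tree(12, np.random.default_rng(2))
        names = tree.leaf_names()
        assert sorted(names) == sorted(f"sp{i+1}" for i in range(12))


class TestSimulateDataset:
    def test_certain_presence_gives_all_present(self, cherry3):
        params = ModelParams(pi=1.0, edge_params={
            n: EdgeParams(0.5, 1.0) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(3)
        table, truth = simulate_dataset(cherry3, params, 50, 5, rng)
        assert (table.entries == 1).all()
        assert truth.n_unobserved == 0

    def test_no_emitted_column_all_absent(self, cherry3, params3):
        rng = np.random.default_rng(4)
        table, truth = simulate_dataset(cherry3, params3, 300, 10, rng)
        assert ((table.entries == 1).any(axis=0)).all()

    def test_truth_tallies_consistent_with_histories(self, cherry3, params3):
        rng = np.random.default_rng(5)
        table, truth = simulate_dataset(cherry3, params3, 200, 10, rng)
        leaf_ids = cherry3.leaves()
        assert np.array_equal(truth.histories[:, leaf_ids].T, table.entries)
        counts = truth.node_counts(include_unobserved=False)
        for u, name in enumerate(cherry3.names):
            assert counts[name] == truth.histories[:, u].sum()

    def test_pattern_frequencies_match_conditional_law(self, cherry3,
                                                       params3):
        """Emitted patterns follow L(pattern)/(1−p0) (chi-square at 0.01)."""
        rng = np.random.default_rng(6)
        n = 30_000
        table, _ = simulate_dataset(cherry3, params3, n, 10, rng)
        pat = table.entries[0] * 4 + table.entries[1] * 2 + table.entries[2]
        obs = np.array([(pat == k).sum() for k in range(1, 8)])
        p0 = p_all_absent(cherry3, params3)
        probs = np.array([
            marginal_site_likelihood(
                [(k >> 2) & 1, (k >> 1) & 1, k & 1], cherry3, params3,
                ["A", "B", "C"])
            for k in range(1, 8)
        ]) / (1 - p0)
        stat = chisquare(obs, n * probs)
        assert stat.pvalue > 0.01

    def test_unobserved_tally_mean_matches_negative_binomial(self, cherry3,
                                                             params3):
        rng = np.random.default_rng(7)
        n, reps = 200, 60
        p0 = p_all_absent(cherry3, params3)
        want = n * p0 / (1 - p0)
        ms = [simulate_dataset(cherry3, params3, n, 5, rng)[1].n_unobserved
              for _ in range(reps)]
        se = np.sqrt(n * p0 / (1 - p0) ** 2 / reps)
        assert abs(np.mean(ms) - want) < 3 * se

    def test_phase_mix_respected(self, cherry3, params3):
        rng = np.random.default_rng(8)
        table, truth = simulate_dataset(cherry3, params3, 4000, 10, rng,
                                        phase_mix=(0.5, 0.25, 0.25))
        frac = np.bincount(truth.phases, minlength=3) / 4000
        assert np.allclose(frac, [0.5, 0.25, 0.25], atol=0.03)

    def test_deterministic_under_seed(self, cherry3, params3):
        t1, tr1 = simulate_dataset(cherry3, params3, 100, 5,
                                   np.random.default_rng(99))
        t2, tr2 = simulate_dataset(cherry3, params3, 100, 5,
                                   np.random.default_rng(99))
        assert np.array_equal(t1.entries, t2.entries)
        assert np.array_equal(tr1.histories, tr2.histories)
        assert tr1.n_unobserved == tr2.n_unobserved

    def test_degenerate_observability_rejected(self, cherry3):
        params = ModelParams(pi=0.0, edge_params={
            n: EdgeParams(1e-6, 0.5) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(9)
        with pytest.raises(Exception):
            simulate_dataset(cherry3, params, 10, 2, rng)


class TestMissingOrthologs:
    def test_probability_zero_is_identity(self, cherry3, params3):
        rng = np.random.default_rng(10)
        table, _ = simulate_dataset(cherry3, params3, 60, 6, rng)
        out = apply_missing_orthologs(table, 0.0, np.random.default_rng(1))
        assert np.array_equal(out.entries, table.entries)

    def test_probability_one_erases_everything(self, cherry3, params3):
        rng = np.random.default_rng(11)
        table, _ = simulate_dataset(cherry3, params3, 60, 6, rng)
        out = apply_missing_orthologs(table, 1.0, np.random.default_rng(1))
        assert (out.entries == AMBIGUOUS).all()
        filtered, dropped = filter_columns(out, max_ambiguous=0)
        assert filtered.n_sites == 0

    def test_erasure_is_blockwise_per_gene(self, cherry3, params3):
        rng = np.random.default_rng(12)
        table, _ = simulate_dataset(cherry3, params3, 120, 8, rng)
        out = apply_missing_orthologs(table, 0.4, np.random.default_rng(2))
        genes = {s.gene for s in out.sites}
        for i in range(out.n_species):
            for g in genes:
                cols = [j for j, s in enumerate(out.sites) if s.gene == g]
                star = out.entries[i, cols] == AMBIGUOUS
                was_star = table.entries[i, cols] == AMBIGUOUS
                touched = star & ~was_star
                # either the whole block was erased or none of it
                assert touched.all() or not touched.any()


class TestHeterotachy:
    def test_sigma_zero_keeps_intensities_within_exponential_stretch(self,
                                                                     cherry3,
                                                                     params3):
        out, clips = apply_heterotachy(params3, np.random.default_rng(13),
                                       sigma=0.0)
        for name, ep in out.edge_params.items():
            # gain fraction unchanged when only the length is stretched
            assert ep.rate_ratio == pytest.approx(
                params3.edge_params[name].rate_ratio, abs=1e-12)

    def test_exponential_stretch_has_unit_mean(self, cherry3, params3):
        rng = np.random.default_rng(14)
        draws = []
        for _ in range(4000):
            out, _ = apply_heterotachy(params3, rng, sigma=0.0)
            draws.append(out.edge_params["A"].length /
                         params3.edge_params["A"].length)
        se = 1.0 / np.sqrt(len(draws))  # exp(1) has sd 1
        assert abs(np.mean(draws) - 1.0) < 3 * se

    def test_multipliers_independent_across_edges(self, cherry3, params3):
        rng = np.random.default_rng(15)
        a, b = [], []
        for _ in range(800):
            out, _ = apply_heterotachy(params3, rng, sigma=0.5)
            a.append(out.edge_params["A"].length)
            b.append(out.edge_params["B"].length)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.1

    def test_clipping_reported(self, cherry3):
        params = ModelParams(pi=0.5, edge_params={
            n: EdgeParams(9.5, 0.5) for n in ["A", "B", "ab", "C"]})
        rng = np.random.default_rng(16)
        clipped_any = 0
        for _ in range(50):
            _, clips = apply_heterotachy(params, rng, sigma=1.0)
            clipped_any += clips
        assert clipped_any > 0


def test_clean_scenario_survives_filter(cherry3, params3):
    """Without erasure, the ambiguity filter never drops a column."""
    rng = np.random.default_rng(17)
    table, _ = simulate_dataset(cherry3, params3, 150, 10, rng)
    filtered, dropped = filter_columns(table)
    assert not dropped and filtered.n_sites == table.n_sites


def test_validation_experiment_single_replicate_shapes():
    from intronevo.simulate import ValidationConfig, summarize_validation, validation_experiment

    cfg = ValidationConfig(n_leaves=5, n_sites=150, n_genes=10, replicates=1,
                           seed=3, run_mcmc=False, ml_starts=1)
    df = validation_experiment(cfg)
    # one row per (node, method) for ml and dollo
    n_nodes = df["node"].nunique()
    assert len(df) == 2 * n_nodes
    assert set(df["method"]) == {"ml", "dollo"}
    assert np.isfinite(df["error"]).all()
    summ = summarize_validation(df)
    assert {"bias", "rel_bias", "rmse"} <= set(summ.columns)
    # deterministic under the same seed
    df2 = validation_experiment(cfg)
    assert np.allclose(df["estimate"], df2["estimate"])


def test_ml_error_shrinks_with_more_sites():
    """Simulate→fit round trip: root-count error decreases from 400 to
    3000 sites under one generating model (seeded)."""
    from intronevo.ml import expected_ancestral_counts, optimize_ml

    tree = random_tree(6, np.random.default_rng(19), trifurcating_root=True)
    gen = default_generating_params(tree, np.random.default_rng(20))
    root = tree.names[tree.root]
    errs = {}
    for n_sites in (400, 3000):
        rel = []
        for rep in range(3):
            rng = np.random.default_rng([21, n_sites, rep])
            table, truth = simulate_dataset(tree, gen, n_sites, 20, rng)
            fit, _ = optimize_ml(table, tree, n_starts=1, seed=0,
                                 options={"maxiter": 300})
            counts = expected_ancestral_counts(table, tree, fit)
            tc = truth.node_counts()[root]
            rel.append(abs(counts[root] - tc) / tc)
        errs[n_sites] = np.mean(rel)
    assert errs[3000] < errs[400]


def test_default_generating_params_are_loss_dominated(cherry3):
    params = default_generating_params(cherry3, np.random.default_rng(18))
    for ep in params.edge_params.values():
        assert ep.loss > ep.gain
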