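"""Metropolis–Hastings sampling of parameters and ancestral histories.

The sampler walks jointly over model parameters θ and, at every
retained step, draws full ancestral site histories ξ (one binary label
per tree node per site) from their exact conditional posterior by
stochastic mapping: a postorder pruning pass gives conditional
likelihoods L[u:x], the root label is drawn from
{(1−π)L[root:0], πL[root:1]}, and a preorder pass draws each child
label y with probability ∝ P(parent→y)·L[child:y].  Rate-category
pairs are drawn per column from their posterior weights before each
mapping pass.

Priors are uniform (lengths and shapes on [0, 10], π and rate ratios
on [0, 1]); proposals are multiplicative — a parameter block is chosen,
each scalar in it is multiplied by exp(U(−δ, δ)) — so the Hastings
correction is the sum of the log multipliers.  Unobservable (all-absent)
sites are reintroduced by drawing their number M from a negative
binomial with N successes and failure probability p0, then mapping M
histories conditioned on the all-zero column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from .model import (
    LENGTH_MAX,
    SHAPE_MAX,
    EdgeParams,
    ModelError,
    ModelParams,
    TreeArrays,
    conditional_likelihoods,
    edge_transition_tensor,
)
from .profiles import ProfileTable
from .trees import SpeciesTree

_SHAPE_MIN = 1e-2


class MCMCError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# proposals and acceptance


@dataclass
class ProposalConfig:
    """Multiplicative random-walk proposal settings.

    ``delta`` is the half-width of the uniform log-multiplier;
    ``subset_prob`` is the inclusion probability when a random subset of
    edge lengths or rate ratios is perturbed.
    """

    delta: float = 0.5
    subset_prob: float = 0.2


@dataclass
class Proposal:
    params: ModelParams
    log_hastings: float
    valid: bool


def _in_support(params: ModelParams) -> bool:
    if not (0.0 <= params.pi <= 1.0):
        return False
    for s in (params.shape_gain, params.shape_loss):
        if not (0.0 < s <= SHAPE_MAX):
            return False
    for ep in params.edge_params.values():
        if not (0.0 <= ep.length <= LENGTH_MAX):
            return False
        if not (0.0 <= ep.rate_ratio <= 1.0):
            return False
    return True


def propose(params: ModelParams, rng: np.random.Generator,
            config: ProposalConfig | None = None) -> Proposal:
    """Propose θ′ by scaling one randomly chosen parameter block.

    Blocks: π | Gamma shapes | a random subset of edge lengths | a
    random subset of rate ratios.  Each chosen scalar x is replaced by
    x·exp(u) with u ~ U(−δ, δ); the log-Hastings ratio of the move is
    the sum of the log multipliers.  Proposals landing outside the
    uniform prior support are flagged invalid (auto-rejected).
    """
    config = config or ProposalConfig()
    delta = config.delta
    blocks = ["pi", "shapes", "lengths", "ratios"]
    block = blocks[rng.integers(len(blocks))]
    names = sorted(params.edge_params)
    scalar_keys: list[str] = []
    edge_keys: list[tuple[str, str]] = []
    if block == "pi":
        scalar_keys = ["pi"]
    elif block == "shapes":
        if params.k_gain > 1:
            scalar_keys.append("shape_gain")
        if params.k_loss > 1:
            scalar_keys.append("shape_loss")
        if not scalar_keys:
            scalar_keys = ["pi"]  # no free shapes: fall back to pi
    else:
        attr = "length" if block == "lengths" else "rate_ratio"
        pick = rng.random(len(names)) < config.subset_prob
        if not pick.any():
            pick[rng.integers(len(names))] = True
        edge_keys = [(n, attr) for n, p in zip(names, pick) if p]
    log_h = 0.0
    valid = True
    new_scalars: dict[str, float] = {}
    for k in scalar_keys:
        u = float(rng.uniform(-delta, delta))
        val = getattr(params, k) * np.exp(u)
        log_h += u
        hi = 1.0 if k == "pi" else SHAPE_MAX
        lo_ok = val > 0.0 or (k == "pi" and val >= 0.0)
        if not (lo_ok and val <= hi):
            valid = False
        new_scalars[k] = float(val)
    new_edges: dict[str, tuple[float, float]] = {}
    for n, attr in edge_keys:
        ep = params.edge_params[n]
        u = float(rng.uniform(-delta, delta))
        val = getattr(ep, attr) * np.exp(u)
        log_h += u
        hi = LENGTH_MAX if attr == "length" else 1.0
        if not (0.0 <= val <= hi):
            valid = False
        length, ratio = ep.length, ep.rate_ratio
        if attr == "length":
            length = float(val)
        else:
            ratio = float(val)
        new_edges[n] = (length, ratio)
    if delta == 0.0:
        log_h = 0.0
    if not valid:
        return Proposal(params=params, log_hastings=log_h, valid=False)
    newp = params.copy()
    for k, v in new_scalars.items():
        setattr(newp, k, v)
    for n, (length, ratio) in new_edges.items():
        newp.edge_params[n] = EdgeParams(length, ratio)
    return Proposal(params=newp, log_hastings=log_h, valid=True)


@dataclass
class ChainState:
    params: ModelParams
    log_likelihood: float
    step: int = 0


def accept_step(state: ChainState, proposal: Proposal, loglik_fn,
                rng: np.random.Generator) -> tuple[ChainState, bool]:
    """Metropolis–Hastings acceptance with flat priors inside support.

    Accepts with probability min{1, exp(Δ log L + log Hastings)};
    invalid (out-of-support) proposals and non-finite proposal
    likelihoods are always rejected.
    """
    if not np.isfinite(state.log_likelihood):
        raise MCMCError("current state has non-finite log-likelihood")
    if not proposal.valid:
        return replace(state, step=state.step + 1), False
    ll_new = loglik_fn(proposal.params)
    if not np.isfinite(ll_new):
        return replace(state, step=state.step + 1), False
    log_alpha = ll_new - state.log_likelihood + proposal.log_hastings
    if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
        return ChainState(params=proposal.params, log_likelihood=ll_new,
                          step=state.step + 1), True
    return replace(state, step=state.step + 1), False


# ---------------------------------------------------------------------
# stochastic mapping


@dataclass
class SiteHistory:
    """One sampled joint labeling of all tree nodes for one site."""

    labels: np.ndarray  # (n_nodes,) in {0,1}
    site_index: int
    category: int       # flat index into the k_gain x k_loss grid


def sample_histories(columns: np.ndarray, arrays: TreeArrays,
                     params: ModelParams, rng: np.random.Generator,
                     unique_decomposition: tuple[np.ndarray, np.ndarray]
                     | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stochastic mapping for a batch of columns.

    Returns ``(labels, cats)`` with ``labels`` of shape
    (n_sites, n_nodes) in {0,1} and ``cats`` the flat category index
    drawn per column from its posterior weights.  Labels at unambiguous
    leaves always equal the observations.  ``unique_decomposition``
    may supply a precomputed ``np.unique(columns, axis=1,
    return_inverse=True)`` pair to avoid re-sorting the table.
    """
    tree = arrays.tree
    n_sites = columns.shape[1]
    P, _, _ = edge_transition_tensor(tree, params)
    # prune once per distinct column, then fan back out to sites
    if unique_decomposition is None:
        uniq, inv = np.unique(columns, axis=1, return_inverse=True)
    else:
        uniq, inv = unique_decomposition
    Lu, logscale_u = conditional_likelihoods(uniq, arrays, P)
    prior = np.array([1.0 - params.pi, params.pi])
    with np.errstate(divide="ignore"):
        per_cat_u = np.log(Lu[tree.root] @ prior) + logscale_u  # (n_cat, n_uniq)
    from .model import _logsumexp0

    tot_u = _logsumexp0(per_cat_u)
    if np.any(~np.isfinite(tot_u)):
        raise MCMCError("column impossible under the current parameters")
    # category draw per column
    cum_u = np.cumsum(np.exp(per_cat_u - tot_u), axis=0)  # (n_cat, n_uniq)
    cum = cum_u[:, inv]
    u = rng.random(n_sites)
    cats = (u[None, :] > cum).sum(axis=0)
    cats = np.minimum(cats, cum.shape[0] - 1)
    labels = np.zeros((n_sites, tree.n_nodes), dtype=np.int8)
    # root draw
    Lr = Lu[tree.root][cats, inv, :]  # (n_sites, 2)
    p1 = prior[1] * Lr[:, 1]
    p0 = prior[0] * Lr[:, 0]
    labels[:, tree.root] = (rng.random(n_sites) * (p0 + p1) < p1).astype(np.int8)
    # preorder draws
    for v in tree.preorder():
        if v == tree.root:
            continue
        par = labels[:, tree.parent[v]]
        trow = P[cats, v, par, :]               # (n_sites, 2)
        Lv = Lu[v][cats, inv, :]                # (n_sites, 2)
        q = trow * Lv
        qs = q.sum(axis=1)
        if (qs <= 0).any():
            raise MCMCError("zero conditional probability during mapping")
        labels[:, v] = (rng.random(n_sites) * qs < q[:, 1]).astype(np.int8)
    return labels, cats


def sample_site_history(column: np.ndarray | list, tree: SpeciesTree,
                        params: ModelParams, rng: np.random.Generator,
                        species: list[str] | None = None) -> SiteHistory:
    """Draw one ancestral history for one column by stochastic mapping."""
    species = species or tree.leaf_names()
    arrays = TreeArrays.build(tree, species)
    col = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    labels, cats = sample_histories(col, arrays, params, rng)
    return SiteHistory(labels=labels[0], site_index=0, category=int(cats[0]))


def sample_all_absent(n_observed: int, tree: SpeciesTree, params: ModelParams,
                      rng: np.random.Generator,
                      arrays: TreeArrays | None = None
                      ) -> tuple[int, np.ndarray]:
    """Draw the unobservable-site count M and M all-absent histories.

    M ~ NegativeBinomial(N successes, failure prob p0), i.e.
    pmf C(N+m−1, m)·p0^m·(1−p0)^N, so E[M] = N·p0/(1−p0).  Returns
    (M, labels) with labels of shape (M, n_nodes); every history has
    label 0 at all leaves.
    """
    if arrays is None:
        arrays = TreeArrays.build(tree, tree.leaf_names())
    zero_col = np.zeros((tree.n_leaves, 1), dtype=np.int8)
    from .model import column_log_likelihoods

    _, marg = column_log_likelihoods(zero_col, arrays, params)
    p0 = float(np.exp(marg[0]))
    if p0 >= 1.0:
        raise ModelError("p_all_absent = 1: augmentation diverges")
    if p0 <= 0.0:
        return 0, np.zeros((0, tree.n_nodes), dtype=np.int8)
    m = int(rng.negative_binomial(n_observed, 1.0 - p0)) if n_observed > 0 else 0
    if m == 0:
        return 0, np.zeros((0, tree.n_nodes), dtype=np.int8)
    cols = np.zeros((tree.n_leaves, m), dtype=np.int8)
    decomp = (zero_col, np.zeros(m, dtype=np.int64))
    labels, _ = sample_histories(cols, arrays, params, rng,
                                 unique_decomposition=decomp)
    return m, labels


# ---------------------------------------------------------------------
# chains


@dataclass
class MCMCConfig:
    """Settings for :func:`run_chains`.

    Defaults are desk-scale: 4 chains with a potential-scale-reduction
    check, configurable up to the 100-chain convention.  ``init``
    warm-starts every chain at a given parameter set instead of a draw
    from the uniform priors.
    """

    n_chains: int = 4
    n_steps: int = 5000
    burnin: int = 2000
    thin: int = 5
    seed: int = 0
    delta: float = 0.5
    subset_prob: float = 0.2
    k_gain: int = 1
    k_loss: int = 4
    init: ModelParams | None = None
    adapt: bool = True
    observability_correction: bool = True
    augment_all_absent: bool = True


@dataclass
class SampleStore:
    """Retained joint posterior samples, per chain.

    Arrays are stacked over chains then retained steps:
    ``counts[c, t, u]`` is the total sampled intron count at node u
    (observed sites plus all-absent augmentation), ``gains``/``losses``
    the per-edge event tallies of the sampled histories, ``params`` the
    parameter vectors (columns in ``param_names`` order).
    """

    node_names: list[str]
    param_names: list[str]
    counts: np.ndarray      # (n_chains, n_ret, n_nodes)
    gains: np.ndarray       # (n_chains, n_ret, n_nodes)
    losses: np.ndarray      # (n_chains, n_ret, n_nodes)
    params: np.ndarray      # (n_chains, n_ret, n_params)
    loglik: np.ndarray      # (n_chains, n_ret)
    m_unobserved: np.ndarray  # (n_chains, n_ret)
    acceptance: np.ndarray  # (n_chains,)

    @property
    def n_retained(self) -> int:
        return self.counts.shape[0] * self.counts.shape[1]

    def pooled_counts(self) -> np.ndarray:
        return self.counts.reshape(-1, self.counts.shape[2])

    def pooled_params(self) -> np.ndarray:
        return self.params.reshape(-1, self.params.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: (chain, step, quantity, value)."""
        recs = []
        nc, nr, _ = self.counts.shape
        for c in range(nc):
            for t in range(nr):
                for u, name in enumerate(self.node_names):
                    recs.append((c, t, f"count.{name}", self.counts[c, t, u]))
                    recs.append((c, t, f"gain.{name}", self.gains[c, t, u]))
                    recs.append((c, t, f"loss.{name}", self.losses[c, t, u]))
                for p, name in enumerate(self.param_names):
                    recs.append((c, t, f"param.{name}", self.params[c, t, p]))
                recs.append((c, t, "loglik", self.loglik[c, t]))
                recs.append((c, t, "m_unobserved", self.m_unobserved[c, t]))
        return pd.DataFrame(recs, columns=["chain", "step", "quantity", "value"])

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_prior_params(tree: SpeciesTree, rng: np.random.Generator,
                       k_gain: int, k_loss: int) -> ModelParams:
    edges = {tree.names[u]: EdgeParams(rng.uniform(0, LENGTH_MAX),
                                       rng.uniform(0, 1))
             for u in tree.nonroot()}
    return ModelParams(
        pi=rng.uniform(0, 1),
        edge_params=edges,
        shape_gain=rng.uniform(_SHAPE_MIN, SHAPE_MAX),
        shape_loss=rng.uniform(_SHAPE_MIN, SHAPE_MAX),
        k_gain=k_gain, k_loss=k_loss,
    )


def _make_loglik(table: ProfileTable, tree: SpeciesTree,
                 correction: bool):
    arrays = TreeArrays.build(tree, table.species)
    if table.n_sites == 0 and not correction:
        return lambda params: 0.0
    uniq, weights = np.unique(table.entries, axis=1, return_counts=True)
    columns_ext = np.concatenate(
        [uniq, np.zeros((table.n_species, 1), dtype=np.int8)], axis=1
    )

    def loglik(params: ModelParams) -> float:
        from .model import column_log_likelihoods

        _, marginal = column_log_likelihoods(columns_ext, arrays, params)
        log_p0 = marginal[-1]
        ll = float(marginal[:-1] @ weights)
        if correction:
            if log_p0 >= 0.0:
                return -np.inf
            ll -= table.n_sites * np.log(-np.expm1(log_p0))
        return float(ll)

    return loglik


def run_chains(table: ProfileTable, tree: SpeciesTree,
               config: MCMCConfig | None = None) -> SampleStore:
    """Run the joint parameter/history sampler.

    Each chain starts from a prior draw (or ``config.init``), iterates
    propose/accept with burn-in-only step-size adaptation, and at every
    retained post-burn-in step draws all site histories plus the
    all-absent augmentation, recording per-node counts, per-edge event
    tallies, the parameter vector and the log-likelihood.  Fully
    reproducible given ``config.seed``.
    """
    config = config or MCMCConfig()
    arrays = TreeArrays.build(tree, table.species)
    loglik = _make_loglik(table, tree, config.observability_correction)
    table_decomp = (np.unique(table.entries, axis=1, return_inverse=True)
                    if table.n_sites else None)
    names = sorted({tree.names[u] for u in tree.nonroot()})
    param_names = list(ModelParams(
        pi=0.5, edge_params={n: EdgeParams(0.1, 0.1) for n in names},
        k_gain=config.k_gain, k_loss=config.k_loss).to_dict())
    n_ret = max(0, (config.n_steps - config.burnin)) // config.thin
    if n_ret == 0:
        raise MCMCError("no retained samples: increase n_steps past burnin")
    nn = tree.n_nodes
    counts = np.zeros((config.n_chains, n_ret, nn))
    gains = np.zeros((config.n_chains, n_ret, nn))
    losses = np.zeros((config.n_chains, n_ret, nn))
    pvals = np.zeros((config.n_chains, n_ret, len(param_names)))
    lls = np.zeros((config.n_chains, n_ret))
    ms = np.zeros((config.n_chains, n_ret))
    acc_rates = np.zeros(config.n_chains)
    parent = arrays.tree.parent
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        if config.init is not None:
            params0 = replace(config.init.copy(), k_gain=config.k_gain,
                              k_loss=config.k_loss)
        else:
            params0 = _draw_prior_params(tree, rng, config.k_gain, config.k_loss)
        ll0 = loglik(params0)
        tries = 0
        while not np.isfinite(ll0):
            params0 = _draw_prior_params(tree, rng, config.k_gain, config.k_loss)
            ll0 = loglik(params0)
            tries += 1
            if tries > 100:
                raise MCMCError("could not find a finite-likelihood start")
        state = ChainState(params=params0, log_likelihood=ll0)
        pconf = ProposalConfig(delta=config.delta, subset_prob=config.subset_prob)
        accepted = recent_acc = recent_n = 0
        post_burn_acc = post_burn_n = 0
        ret = 0
        for step in range(config.n_steps):
            prop = propose(state.params, rng, pconf)
            state, ok = accept_step(state, prop, loglik, rng)
            accepted += ok
            recent_acc += ok
            recent_n += 1
            if config.adapt and step < config.burnin and recent_n == 100:
                rate = recent_acc / recent_n
                pconf.delta = float(np.clip(
                    pconf.delta * np.exp(rate - 0.3), 1e-3, 5.0))
                recent_acc = recent_n = 0
            if step >= config.burnin:
                post_burn_acc += ok
                post_burn_n += 1
                if (step - config.burnin) % config.thin == 0 and ret < n_ret:
                    if table.n_sites:
                        labels, _ = sample_histories(
                            table.entries, arrays, state.params, rng,
                            unique_decomposition=table_decomp)
                        cnt = labels.sum(axis=0).astype(float)
                        g = ((labels[:, parent] == 0) & (labels == 1))
                        l = ((labels[:, parent] == 1) & (labels == 0))
                        g[:, tree.root] = False
                        l[:, tree.root] = False
                        gsum = g.sum(axis=0).astype(float)
                        lsum = l.sum(axis=0).astype(float)
                    else:
                        cnt = np.zeros(nn)
                        gsum = np.zeros(nn)
                        lsum = np.zeros(nn)
                    m = 0
                    if config.augment_all_absent and table.n_sites > 0:
                        m, aa = sample_all_absent(table.n_sites, tree,
                                                  state.params, rng,
                                                  arrays=arrays)
                        if m:
                            cnt += aa.sum(axis=0)
                            ga = ((aa[:, parent] == 0) & (aa == 1))
                            la = ((aa[:, parent] == 1) & (aa == 0))
                            ga[:, tree.root] = False
                            la[:, tree.root] = False
                            gsum += ga.sum(axis=0)
                            lsum += la.sum(axis=0)
                    counts[c, ret] = cnt
                    gains[c, ret] = gsum
                    losses[c, ret] = lsum
                    d = state.params.to_dict()
                    pvals[c, ret] = [d[k] for k in param_names]
                    lls[c, ret] = state.log_likelihood
                    ms[c, ret] = m
                    ret += 1
        acc_rates[c] = accepted / config.n_steps
        if table.n_sites > 0 and post_burn_n > 0 and \
                post_burn_acc / post_burn_n < 0.01:
            raise MCMCError(
                f"chain {c} appears stuck: post-burn-in acceptance "
                f"{post_burn_acc / post_burn_n:.3%}"
            )
    return SampleStore(
        node_names=list(tree.names), param_names=param_names,
        counts=counts, gains=gains, losses=losses, params=pvals,
        loglik=lls, m_unobserved=ms, acceptance=acc_rates,
    )


# ---------------------------------------------------------------------
# summaries


@dataclass
class PosteriorSummary:
    """Medians and central 95% intervals of the joint posterior."""

    node_stats: pd.DataFrame    # node, median, lo2.5, hi97.5 (+density cols)
    edge_stats: pd.DataFrame    # node, gain_median, loss_median, intervals
    param_stats: pd.DataFrame   # param, median, lo2.5, hi97.5, rhat


def potential_scale_reduction(chains: np.ndarray) -> float:
    """Gelman–Rubin R-hat for one scalar over (n_chains, n_samples)."""
    m, n = chains.shape
    if m < 2 or n < 2:
        return np.nan
    means = chains.mean(axis=1)
    b = n * means.var(ddof=1)
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _stats(x: np.ndarray) -> tuple[float, float, float]:
    return (float(np.median(x)), float(np.percentile(x, 2.5)),
            float(np.percentile(x, 97.5)))


def summarize(store: SampleStore, reference=None) -> PosteriorSummary:
    """Summarize a sample store: medians, 95% intervals, R-hat.

    ``reference`` (a :class:`intronevo.report.DensityReference`) adds
    density-unit columns to the node table.
    """
    if store.counts.size == 0:
        raise MCMCError("empty sample store")
    node_rows = []
    for u, name in enumerate(store.node_names):
        med, lo, hi = _stats(store.counts[:, :, u])
        row = {"node": name, "count_median": med,
               "count_lo": lo, "count_hi": hi}
        if reference is not None:
            from .report import counts_to_density

            row["density_median"] = counts_to_density(med, reference)
            row["density_lo"] = counts_to_density(lo, reference)
            row["density_hi"] = counts_to_density(hi, reference)
        node_rows.append(row)
    edge_rows = []
    for u, name in enumerate(store.node_names):
        gm, gl, gh = _stats(store.gains[:, :, u])
        lm, ll_, lh = _stats(store.losses[:, :, u])
        edge_rows.append({"node": name, "gain_median": gm, "gain_lo": gl,
                          "gain_hi": gh, "loss_median": lm, "loss_lo": ll_,
                          "loss_hi": lh})
    param_rows = []
    for p, name in enumerate(store.param_names):
        med, lo, hi = _stats(store.params[:, :, p])
        rhat = potential_scale_reduction(store.params[:, :, p])
        param_rows.append({"param": name, "median": med, "lo": lo, "hi": hi,
                           "rhat": rhat})
    return PosteriorSummary(
        node_stats=pd.DataFrame(node_rows).sort_values("node").reset_index(drop=True),
        edge_stats=pd.DataFrame(edge_rows).sort_values("node").reset_index(drop=True),
        param_stats=pd.DataFrame(param_rows),
    )
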