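"""Maximum-likelihood fitting and posterior ancestral reconstruction.

The ML route fixes one parameter vector (found by bounded quasi-Newton
search of the observability-conditioned likelihood) and reconstructs
ancestral presence by exact posterior probabilities: an up pass
(postorder conditional likelihoods) followed by a down pass (outside
probabilities) yields, for every site, the marginal presence
probability at each node and the joint parent/child distribution on
each edge, mixed over rate categories with per-site category weights.

Sites that never left a trace (all-absent profiles) are unobservable;
their expected number is E[M] = N·p0/(1−p0) and their posterior
reconstruction — conditioned on the all-zero column — is added to the
expected ancestral counts and branch events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    LENGTH_MAX,
    SHAPE_MAX,
    EdgeParams,
    ModelError,
    ModelParams,
    TreeArrays,
    column_log_likelihoods,
    conditional_likelihoods,
    default_params,
    edge_transition_tensor,
)
from .profiles import ProfileTable
from .trees import SpeciesTree

_PI_EPS = 1e-7
_LEN_EPS = 1e-9
_SHAPE_MIN = 1e-2


@dataclass
class NodePosterior:
    """Exact per-site posteriors at fixed parameters.

    ``presence[j, u]`` is P(ξ_j[u]=1 | column j); ``gain[j, v]`` and
    ``loss[j, v]`` are the posterior probabilities of a 0→1 (resp. 1→0)
    transition on the edge into node v (zero in the root slot).
    """

    node_names: list[str]
    site_ids: list[str]
    presence: np.ndarray
    gain: np.ndarray
    loss: np.ndarray


# ---------------------------------------------------------------------
# parameter vector packing


def _pack_layout(tree: SpeciesTree, params: ModelParams):
    names = [tree.names[u] for u in tree.nonroot()]
    free_sg = params.k_gain > 1
    free_sl = params.k_loss > 1
    return names, free_sg, free_sl


def _pack(params: ModelParams, tree: SpeciesTree) -> tuple[np.ndarray, list]:
    names, free_sg, free_sl = _pack_layout(tree, params)
    x = [params.pi]
    bounds = [(_PI_EPS, 1 - _PI_EPS)]
    if free_sg:
        x.append(params.shape_gain)
        bounds.append((_SHAPE_MIN, SHAPE_MAX))
    if free_sl:
        x.append(params.shape_loss)
        bounds.append((_SHAPE_MIN, SHAPE_MAX))
    for n in names:
        x.append(params.edge_params[n].length)
        bounds.append((_LEN_EPS, LENGTH_MAX))
    for n in names:
        x.append(params.edge_params[n].rate_ratio)
        bounds.append((0.0, 1.0))
    return np.array(x), bounds


def _unpack(x: np.ndarray, template: ModelParams, tree: SpeciesTree) -> ModelParams:
    names, free_sg, free_sl = _pack_layout(tree, template)
    i = 0
    pi = float(x[i]); i += 1
    sg = template.shape_gain
    sl = template.shape_loss
    if free_sg:
        sg = float(x[i]); i += 1
    if free_sl:
        sl = float(x[i]); i += 1
    m = len(names)
    lengths = x[i:i + m]; i += m
    ratios = x[i:i + m]
    edges = {n: EdgeParams(float(l), float(r))
             for n, l, r in zip(names, lengths, ratios)}
    return ModelParams(pi=pi, edge_params=edges, shape_gain=sg, shape_loss=sl,
                       k_gain=template.k_gain, k_loss=template.k_loss)


def _to_unconstrained(x: np.ndarray, bounds: list) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    frac = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(frac / (1 - frac))


def _to_constrained(z: np.ndarray, bounds: list) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _neg_log_likelihood(x, template, tree, columns_ext, arrays, weights,
                        n_sites):
    params = _unpack(x, template, tree)
    _, marginal = column_log_likelihoods(columns_ext, arrays, params)
    log_p0 = marginal[-1]
    if log_p0 >= 0.0:
        return np.inf
    ll = marginal[:-1] @ weights - n_sites * np.log(-np.expm1(log_p0))
    return -ll if np.isfinite(ll) else np.inf


def optimize_ml(
    table: ProfileTable,
    tree: SpeciesTree,
    init: ModelParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
    options: dict | None = None,
) -> tuple[ModelParams, float]:
    """Fit θ by maximizing the observability-conditioned likelihood.

    Runs a bounded L-BFGS-B search from ``init`` (default heuristic:
    π=0.5, lengths 0.5, ratios 0.2, shapes 1) plus ``n_starts − 1``
    random restarts drawn from the uniform priors, and keeps the best.
    Deterministic given (init, seed, options, data).

    Returns the fitted parameters and the achieved log-likelihood,
    which is never below the log-likelihood at ``init``.
    """
    if init is None:
        init = default_params(tree)
    arrays = TreeArrays.build(tree, table.species)
    # collapse duplicate columns (identical profiles share a likelihood)
    uniq, weights = np.unique(table.entries, axis=1, return_counts=True)
    # append the all-zero column so p0 is computed in the same pass
    columns_ext = np.concatenate(
        [uniq, np.zeros((table.n_species, 1), dtype=np.int8)], axis=1
    )
    args = (init, tree, columns_ext, arrays, weights, table.n_sites)
    x0, bounds = _pack(init, tree)
    f0 = _neg_log_likelihood(x0, *args)
    if not np.isfinite(f0):
        raise ModelError("non-finite likelihood at the initial parameters")
    opts = {"maxiter": 500, "ftol": 1e-9}
    opts.update(options or {})
    rng = np.random.default_rng(seed)
    starts = [x0]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    # optimize in smooth logit-transformed coordinates so the search
    # never steps outside the prior support
    def objective(z):
        return _neg_log_likelihood(_to_constrained(z, bounds), *args)

    best_x, best_f = x0, f0
    for s in starts:
        res = minimize(objective, _to_unconstrained(s, bounds),
                       method="L-BFGS-B", options=opts)
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = _to_constrained(res.x, bounds), res.fun
    return _unpack(best_x, init, tree), -best_f


# ---------------------------------------------------------------------
# exact posteriors (up-down pass)


def _updown(columns: np.ndarray, arrays: TreeArrays, params: ModelParams):
    """Inside-outside pass; returns everything posteriors need."""
    tree = arrays.tree
    P, _, _ = edge_transition_tensor(tree, params)
    L, logscale = conditional_likelihoods(columns, arrays, P)
    n_cat, n_sites = L.shape[1], L.shape[2]
    # messages M[v] from child v to its parent
    M = np.empty_like(L)
    for v in tree.nonroot():
        M[v] = np.einsum("cxy,csy->csx", P[:, v], L[v])
    O = np.empty_like(L)  # outside probabilities, normalized per node
    prior = np.array([1.0 - params.pi, params.pi])
    O[tree.root] = prior[None, None, :]
    for u in tree.preorder():
        ch = tree.children[u]
        if not ch:
            continue
        # prefix/suffix products of sibling messages
        m = len(ch)
        pre = np.ones((m + 1, n_cat, n_sites, 2))
        for i, v in enumerate(ch):
            pre[i + 1] = pre[i] * M[v]
        suf = np.ones((m + 1, n_cat, n_sites, 2))
        for i in range(m - 1, -1, -1):
            suf[i] = suf[i + 1] * M[ch[i]]
        for i, v in enumerate(ch):
            above = O[u] * pre[i] * suf[i + 1]  # (n_cat, n_sites, 2) over x
            Ov = np.einsum("csx,cxy->csy", above, P[:, v])
            norm = Ov.max(axis=2)
            norm = np.where(norm > 0, norm, 1.0)
            O[v] = Ov / norm[..., None]
    # per-site category weights from the root likelihoods
    with np.errstate(divide="ignore"):
        per_cat = np.log(L[tree.root] @ prior) + logscale
    w = np.exp(per_cat - logsumexp(per_cat, axis=0, keepdims=True))  # (n_cat, n_sites)
    return L, M, O, P, w


def node_posteriors(table: ProfileTable, tree: SpeciesTree,
                    params: ModelParams) -> NodePosterior:
    """Exact presence and edge-event posteriors for every site and node.

    Marginalizes over the rate-category grid with per-site category
    weights (each category pair weighted by its likelihood share for
    that column).
    """
    arrays = TreeArrays.build(tree, table.species)
    return _node_posteriors_columns(table.entries, arrays, params,
                                    [s.site_id for s in table.sites])


def _node_posteriors_columns(columns: np.ndarray, arrays: TreeArrays,
                             params: ModelParams,
                             site_ids: list[str]) -> NodePosterior:
    tree = arrays.tree
    L, M, O, P, w = _updown(columns, arrays, params)
    n_sites = columns.shape[1]
    presence = np.zeros((n_sites, tree.n_nodes))
    gain = np.zeros((n_sites, tree.n_nodes))
    loss = np.zeros((n_sites, tree.n_nodes))
    for u in range(tree.n_nodes):
        post = O[u] * L[u]  # (n_cat, n_sites, 2)
        tot = post.sum(axis=2)
        pc = post[..., 1] / np.where(tot > 0, tot, 1.0)
        presence[:, u] = (w * pc).sum(axis=0)
    for v in tree.nonroot():
        u = tree.parent[v]
        # outside of u seen from v: O_u times sibling messages
        sib = O[u].copy()
        for wch in tree.children[u]:
            if wch != v:
                sib = sib * M[wch]
        # joint over (x at u, y at v)
        J = sib[..., :, None] * P[:, v][:, None, :, :] * L[v][..., None, :]
        tot = J.sum(axis=(2, 3))
        tot = np.where(tot > 0, tot, 1.0)
        g = J[..., 0, 1] / tot
        l = J[..., 1, 0] / tot
        gain[:, v] = (w * g).sum(axis=0)
        loss[:, v] = (w * l).sum(axis=0)
    return NodePosterior(
        node_names=list(tree.names), site_ids=list(site_ids),
        presence=presence, gain=gain, loss=loss,
    )


def _all_absent_posterior(tree: SpeciesTree, params: ModelParams) -> NodePosterior:
    arrays = TreeArrays.build(tree, tree.leaf_names())
    col = np.zeros((tree.n_leaves, 1), dtype=np.int8)
    return _node_posteriors_columns(col, arrays, params, ["all-absent"])


def expected_all_absent(n_sites: int, tree: SpeciesTree,
                        params: ModelParams) -> float:
    """E[M] = N·p0/(1−p0): the expected number of unobservable sites."""
    from .model import p_all_absent

    p0 = p_all_absent(tree, params)
    if p0 >= 1.0:
        raise ModelError("p_all_absent = 1: expected unobserved count diverges")
    return n_sites * p0 / (1.0 - p0)


def expected_ancestral_counts(table: ProfileTable, tree: SpeciesTree,
                              params: ModelParams,
                              include_unobserved: bool = True) -> dict[str, float]:
    """Posterior-expected intron count at every node.

    Sums presence posteriors across observed sites and, when
    ``include_unobserved``, adds E[M] times the presence posterior
    conditioned on the all-absent column.
    """
    post = node_posteriors(table, tree, params)
    counts = post.presence.sum(axis=0)
    if include_unobserved and table.n_sites > 0:
        em = expected_all_absent(table.n_sites, tree, params)
        aa = _all_absent_posterior(tree, params)
        counts = counts + em * aa.presence[0]
    return dict(zip(tree.names, counts.tolist()))


def expected_branch_events(table: ProfileTable, tree: SpeciesTree,
                           params: ModelParams,
                           include_unobserved: bool = True
                           ) -> dict[str, tuple[float, float]]:
    """Expected (gains, losses) on the edge into each non-root node."""
    post = node_posteriors(table, tree, params)
    gains = post.gain.sum(axis=0)
    losses = post.loss.sum(axis=0)
    if include_unobserved and table.n_sites > 0:
        em = expected_all_absent(table.n_sites, tree, params)
        aa = _all_absent_posterior(tree, params)
        gains = gains + em * aa.gain[0]
        losses = losses + em * aa.loss[0]
    return {tree.names[v]: (float(gains[v]), float(losses[v]))
            for v in tree.nonroot()}


def site_history_surface(table: ProfileTable, tree: SpeciesTree,
                         params: ModelParams):
    """Per-site reconstruction surface: one row per (site, node).

    Columns: site id, gene, phase, node, presence probability and — for
    non-root nodes — the gain and loss probabilities on the edge into
    the node.  Suitable for per-gene history plots.
    """
    import pandas as pd

    post = node_posteriors(table, tree, params)
    rows = []
    for j, site in enumerate(table.sites):
        for u in range(tree.n_nodes):
            rows.append({
                "site": site.site_id,
                "gene": site.gene,
                "phase": site.phase,
                "node": tree.names[u],
                "p_present": post.presence[j, u],
                "p_gain": post.gain[j, u] if u != tree.root else 0.0,
                "p_loss": post.loss[j, u] if u != tree.root else 0.0,
            })
    return pd.DataFrame(rows)
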