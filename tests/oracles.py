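"""Independent brute-force oracles used by the tests.

Everything here recomputes model quantities by routes the package does
not use: matrix exponentials for edge transition laws, exhaustive
enumeration over all node labelings for likelihoods and posteriors,
and adaptive quadrature for Gamma bin means.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from intronevo.model import ModelParams
from intronevo.profiles import AMBIGUOUS
from intronevo.trees import SpeciesTree


def expm_transition(gain: float, loss: float, t: float = 1.0) -> np.ndarray:
    """2-state transition matrix by numerical matrix exponential."""
    Q = np.array([[-gain, gain], [loss, -loss]])
    return expm(Q * t)


def enum_site_likelihood(column, tree: SpeciesTree, params: ModelParams,
                         species: list[str], gamma: float = 1.0,
                         nu: float = 1.0) -> float:
    """Likelihood by summing over all 2^n_nodes labelings.

    Ambiguous leaves are marginalized implicitly: any labeling value is
    compatible with '*'.  Edge matrices come from the matrix
    exponential, not the package's closed form.
    """
    col = np.asarray(column)
    obs = {tree.leaf_index(s): int(c) for s, c in zip(species, col)}
    lengths, ratios = params.edge_arrays(tree)
    P = {}
    for v in tree.nonroot():
        a = gamma * lengths[v] * ratios[v]
        b = nu * lengths[v] * (1.0 - ratios[v])
        P[v] = expm_transition(a, b)
    prior = [1.0 - params.pi, params.pi]
    total = 0.0
    for labels in itertools.product((0, 1), repeat=tree.n_nodes):
        ok = all(labels[u] == c for u, c in obs.items() if c != AMBIGUOUS)
        if not ok:
            continue
        p = prior[labels[tree.root]]
        for v in tree.nonroot():
            p *= P[v][labels[tree.parent[v]], labels[v]]
        total += p
    return total


def enum_marginal_likelihood(column, tree, params, species) -> float:
    """Equal-weight category mixture of enumerated likelihoods."""
    gammas, nus = params.category_grid()
    vals = [enum_site_likelihood(column, tree, params, species, g, v)
            for g, v in zip(gammas, nus)]
    return float(np.mean(vals))


def enum_posteriors(column, tree, params, species):
    """Exact per-node presence and per-edge joint posteriors.

    Returns (presence, gain, loss) arrays over nodes, marginalized over
    the category grid with per-column category weights.
    """
    gammas, nus = params.category_grid()
    obs = {tree.leaf_index(s): int(c) for s, c in zip(species, column)}
    lengths, ratios = params.edge_arrays(tree)
    prior = [1.0 - params.pi, params.pi]
    n = tree.n_nodes
    pres = np.zeros((len(gammas), n))
    gain = np.zeros((len(gammas), n))
    loss = np.zeros((len(gammas), n))
    liks = np.zeros(len(gammas))
    for k, (g, v_) in enumerate(zip(gammas, nus)):
        P = {}
        for v in tree.nonroot():
            a = g * lengths[v] * ratios[v]
            b = v_ * lengths[v] * (1.0 - ratios[v])
            P[v] = expm_transition(a, b)
        for labels in itertools.product((0, 1), repeat=n):
            ok = all(labels[u] == c for u, c in obs.items() if c != AMBIGUOUS)
            if not ok:
                continue
            p = prior[labels[tree.root]]
            for v in tree.nonroot():
                p *= P[v][labels[tree.parent[v]], labels[v]]
            liks[k] += p
            for u in range(n):
                if labels[u] == 1:
                    pres[k, u] += p
            for v in tree.nonroot():
                pu, pv = labels[tree.parent[v]], labels[v]
                if (pu, pv) == (0, 1):
                    gain[k, v] += p
                elif (pu, pv) == (1, 0):
                    loss[k, v] += p
    w = liks / liks.sum()
    pres = (w[:, None] * pres / liks[:, None]).sum(axis=0)
    gain = (w[:, None] * gain / liks[:, None]).sum(axis=0)
    loss = (w[:, None] * loss / liks[:, None]).sum(axis=0)
    return pres, gain, loss


def quadrature_gamma_bin_means(shape: float, k: int) -> np.ndarray:
    """Mean of a mean-1 Gamma within each equal-probability bin."""
    scale = 1.0 / shape
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=scale)
    edges[-1] = np.inf
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda x: x * gamma_dist.pdf(x, a=shape, scale=scale),
                      lo, hi, limit=200)
        out.append(val * k)
    return np.asarray(out)


def random_instance(rng, n_leaves_max=5, n_ambig_max=3, k_loss_max=2,
                    k_gain_max=1):
    """Random small tree + params + column for oracle comparisons."""
    from intronevo.model import EdgeParams
    from intronevo.simulate import random_tree

    n_leaves = int(rng.integers(2, n_leaves_max + 1))
    tree = random_tree(n_leaves, rng)
    edges = {tree.names[u]: EdgeParams(float(rng.uniform(0, 3)),
                                       float(rng.uniform(0, 1)))
             for u in tree.nonroot()}
    params = ModelParams(
        pi=float(rng.uniform(0.05, 0.95)), edge_params=edges,
        shape_gain=float(rng.uniform(0.3, 5)),
        shape_loss=float(rng.uniform(0.3, 5)),
        k_gain=int(rng.integers(1, k_gain_max + 1)),
        k_loss=int(rng.integers(1, k_loss_max + 1)),
    )
    species = tree.leaf_names()
    column = rng.integers(0, 2, size=n_leaves)
    n_amb = int(rng.integers(0, min(n_ambig_max, n_leaves) + 1))
    if n_amb:
        idx = rng.choice(n_leaves, size=n_amb, replace=False)
        column[idx] = AMBIGUOUS
    return tree, params, species, column
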