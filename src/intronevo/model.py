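"""Branch-heterogeneous two-state Markov model of intron evolution.

Each intron site evolves independently on the species tree as a binary
character (0 = absent, 1 = present).  The edge into node *v* carries a
*length* ℓ ∈ [0, 10] (expected total-event intensity) and a *rate ratio*
r ∈ [0, 1] (the gain fraction of the total intensity), so the site's
gain intensity on that edge is a = γ·ℓ·r and the loss intensity is
b = ν·ℓ·(1−r), where γ and ν are site-specific multipliers drawn from
discretized mean-1 Gamma distributions.  The root carries a presence
probability π.

The two-state continuous-time chain gives the edge transition
probabilities

    P(0→1) = a/(a+b)·(1 − e^{−(a+b)}),   P(1→0) = b/(a+b)·(1 − e^{−(a+b)}),

with the identity matrix in the a+b → 0 limit.

Because a column with no presence in any terminal taxon can never enter
the data, the dataset likelihood is conditioned on observability: each
column contributes log L(column) − log(1 − p0), where p0 is the
probability of an all-absent profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .profiles import ProfileTable
from .trees import SpeciesTree

#: prior support bounds for the model parameters
LENGTH_MAX = 10.0
SHAPE_MAX = 10.0


class ModelError(ValueError):
    """Raised for invalid parameters or degenerate models."""


@dataclass
class EdgeParams:
    """Length/rate-ratio parametrization of one edge.

    ``length`` is the expected total (gain+loss) intensity on the edge at
    unit rate multipliers; ``rate_ratio`` is gain/(gain+loss).
    """

    length: float
    rate_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.length <= LENGTH_MAX):
            raise ModelError(f"edge length {self.length} outside [0, {LENGTH_MAX}]")
        if not (0.0 <= self.rate_ratio <= 1.0):
            raise ModelError(f"rate ratio {self.rate_ratio} outside [0, 1]")

    @property
    def gain(self) -> float:
        return self.length * self.rate_ratio

    @property
    def loss(self) -> float:
        return self.length * (1.0 - self.rate_ratio)

    @classmethod
    def from_intensities(cls, gain: float, loss: float) -> "EdgeParams":
        total = gain + loss
        ratio = 0.5 if total == 0 else gain / total
        return cls(length=total, rate_ratio=ratio)


@dataclass
class ModelParams:
    """Full parameter vector θ of the gain/loss model.

    ``edge_params`` maps non-root node names to the :class:`EdgeParams`
    of the edge above them.  ``k_gain=1`` disables gain-rate variation
    (likewise for loss); by default only loss rates vary across sites
    (four categories), the configuration with demonstrable impact on
    model fit for intron data.
    """

    pi: float
    edge_params: dict[str, EdgeParams]
    shape_gain: float = 1.0
    shape_loss: float = 1.0
    k_gain: int = 1
    k_loss: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ModelError(f"pi {self.pi} outside [0, 1]")
        for name, shape in (("shape_gain", self.shape_gain),
                            ("shape_loss", self.shape_loss)):
            if not (0.0 < shape <= SHAPE_MAX):
                raise ModelError(f"{name} {shape} outside (0, {SHAPE_MAX}]")
        if self.k_gain < 1 or self.k_loss < 1:
            raise ModelError("category counts must be >= 1")

    def copy(self) -> "ModelParams":
        return ModelParams(
            pi=self.pi,
            edge_params={k: EdgeParams(v.length, v.rate_ratio)
                         for k, v in self.edge_params.items()},
            shape_gain=self.shape_gain,
            shape_loss=self.shape_loss,
            k_gain=self.k_gain,
            k_loss=self.k_loss,
        )

    # -- array form keyed by tree node index -------------------------

    def edge_arrays(self, tree: SpeciesTree) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, ratios) indexed by tree node; root entries are 0."""
        lengths = np.zeros(tree.n_nodes)
        ratios = np.zeros(tree.n_nodes)
        for u in tree.nonroot():
            ep = self.edge_params[tree.names[u]]
            lengths[u] = ep.length
            ratios[u] = ep.rate_ratio
        return lengths, ratios

    def category_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Site-rate category pairs as flat arrays (gammas, nus).

        The k_gain gain multipliers and k_loss loss multipliers form an
        independent k_gain × k_loss grid with equal weights.
        """
        if self.shape_gain <= 0 or self.shape_loss <= 0:
            raise ModelError("shape must be > 0")
        return _category_grid_cached(float(self.shape_gain), self.k_gain,
                                     float(self.shape_loss), self.k_loss)

    # -- flat key-value serialization ---------------------------------

    def to_dict(self) -> dict:
        d = {
            "pi": float(self.pi),
            "shape_gain": float(self.shape_gain),
            "shape_loss": float(self.shape_loss),
            "k_gain": int(self.k_gain),
            "k_loss": int(self.k_loss),
        }
        for name, ep in sorted(self.edge_params.items()):
            d[f"edge.{name}.length"] = float(ep.length)
            d[f"edge.{name}.rate_ratio"] = float(ep.rate_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        edges: dict[str, dict] = {}
        for key, val in d.items():
            if key.startswith("edge."):
                prefix, attr = key.rsplit(".", 1)
                name = prefix[len("edge."):]
                edges.setdefault(name, {})[attr] = float(val)
        edge_params = {
            name: EdgeParams(length=v["length"], rate_ratio=v["rate_ratio"])
            for name, v in edges.items()
        }
        return cls(
            pi=float(d["pi"]),
            edge_params=edge_params,
            shape_gain=float(d.get("shape_gain", 1.0)),
            shape_loss=float(d.get("shape_loss", 1.0)),
            k_gain=int(d.get("k_gain", 1)),
            k_loss=int(d.get("k_loss", 4)),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_params(tree: SpeciesTree, pi: float = 0.5, length: float = 0.5,
                   rate_ratio: float = 0.2, **kw) -> ModelParams:
    """Heuristic parameter set used as an optimizer start."""
    edges = {tree.names[u]: EdgeParams(length, rate_ratio) for u in tree.nonroot()}
    return ModelParams(pi=pi, edge_params=edges, **kw)


# ---------------------------------------------------------------------
# primitives


def transition_probs(edge: EdgeParams, gamma: float = 1.0,
                     nu: float = 1.0) -> np.ndarray:
    """2×2 transition matrix over {0 absent, 1 present} for one edge.

    ``gamma`` and ``nu`` are the site-specific gain and loss multipliers.
    """
    if gamma <= 0 or nu <= 0:
        raise ModelError("rate multipliers must be positive")
    a = gamma * edge.gain
    b = nu * edge.loss
    return _transition_matrix(a, b)


def _transition_matrix(a: float, b: float) -> np.ndarray:
    tot = a + b
    if tot == 0.0:
        return np.eye(2)
    decay = -np.expm1(-tot)  # 1 - e^{-(a+b)}
    p01 = (a / tot) * decay
    p10 = (b / tot) * decay
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def discretize_gamma(shape: float, k: int) -> np.ndarray:
    """Equal-weight discretization of a mean-1 Gamma into k multipliers.

    Uses the mean of each equal-probability bin (Yang's mean method),
    then renormalizes so the arithmetic mean is exactly 1.  ``k=1``
    returns ``[1.0]`` regardless of shape.
    """
    if k < 1:
        raise ModelError("k must be >= 1")
    if shape <= 0:
        raise ModelError("shape must be > 0")
    return _discretize_gamma_cached(float(shape), int(k)).copy()


@lru_cache(maxsize=4096)
def _category_grid_cached(shape_gain: float, k_gain: int, shape_loss: float,
                          k_loss: int) -> tuple[np.ndarray, np.ndarray]:
    g = _discretize_gamma_cached(shape_gain, k_gain)
    v = _discretize_gamma_cached(shape_loss, k_loss)
    gg, vv = np.meshgrid(g, v, indexing="ij")
    return gg.ravel(), vv.ravel()


@lru_cache(maxsize=4096)
def _discretize_gamma_cached(shape: float, k: int) -> np.ndarray:
    if k == 1:
        return np.array([1.0])
    scale = 1.0 / shape  # mean 1
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=scale)
    # E[X; X<=t] = shape*scale * gammainc(shape+1, t/scale)
    cum = gammainc(shape + 1, edges / scale)
    cum[0], cum[-1] = 0.0, 1.0
    means = k * np.diff(cum)  # shape*scale == 1
    return means / means.mean()


# ---------------------------------------------------------------------
# pruning likelihood engine


@dataclass
class TreeArrays:
    """Flattened tree traversal data reused across likelihood calls."""

    tree: SpeciesTree
    leaf_idx: np.ndarray          # node index of each table row's species
    is_leaf: np.ndarray
    children_flat: np.ndarray     # all children, grouped by parent
    child_ptr: np.ndarray         # child_ptr[u]:child_ptr[u+1] slices children_flat

    @classmethod
    def build(cls, tree: SpeciesTree, species: list[str]) -> "TreeArrays":
        try:
            leaf_idx = np.array([tree.leaf_index(s) for s in species])
        except KeyError as exc:
            raise ModelError(f"species {exc.args[0]!r} not a tree leaf") from exc
        if len(set(species)) != tree.n_leaves:
            raise ModelError("table species do not cover the tree leaf set")
        is_leaf = np.array([tree.is_leaf(u) for u in range(tree.n_nodes)])
        flat, ptr = [], [0]
        for u in range(tree.n_nodes):
            flat.extend(tree.children[u])
            ptr.append(len(flat))
        return cls(tree=tree, leaf_idx=leaf_idx, is_leaf=is_leaf,
                   children_flat=np.array(flat, dtype=np.int64),
                   child_ptr=np.array(ptr, dtype=np.int64))


def edge_transition_tensor(tree: SpeciesTree, params: ModelParams
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-category per-edge transition matrices.

    Returns ``(P, gammas, nus)`` where ``P`` has shape
    ``(n_cat, n_nodes, 2, 2)`` (the root slot holds the identity).
    """
    lengths, ratios = params.edge_arrays(tree)
    gammas, nus = params.category_grid()
    a = gammas[:, None] * (lengths * ratios)[None, :]
    b = nus[:, None] * (lengths * (1.0 - ratios))[None, :]
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        decay = -np.expm1(-tot)
        p01 = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0) * decay, 0.0)
        p10 = np.where(tot > 0, b / np.where(tot > 0, tot, 1.0) * decay, 0.0)
    P = np.empty(a.shape + (2, 2))
    P[..., 0, 0] = 1.0 - p01
    P[..., 0, 1] = p01
    P[..., 1, 0] = p10
    P[..., 1, 1] = 1.0 - p10
    return P, gammas, nus


_LEAF_LIK = np.array([[1.0, 0.0],   # observed 0
                      [0.0, 1.0],   # observed 1
                      [1.0, 1.0]])  # ambiguous '*'

try:  # jit-compiled pruning kernel; numpy path below is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _prune_kernel(P, leaf_state, is_leaf, children_flat, child_ptr):
        n_cat = P.shape[0]
        n_nodes = P.shape[1]
        n_sites = leaf_state.shape[1]
        L = np.empty((n_nodes, n_cat, n_sites, 2))
        logscale = np.zeros((n_cat, n_sites))
        for u in range(n_nodes):
            if is_leaf[u]:
                for c in range(n_cat):
                    for s in range(n_sites):
                        st = leaf_state[u, s]
                        L[u, c, s, 0] = 1.0 if st != 1 else 0.0
                        L[u, c, s, 1] = 1.0 if st != 0 else 0.0
                continue
            for c in range(n_cat):
                for s in range(n_sites):
                    L[u, c, s, 0] = 1.0
                    L[u, c, s, 1] = 1.0
            for k in range(child_ptr[u], child_ptr[u + 1]):
                v = children_flat[k]
                for c in range(n_cat):
                    p00 = P[c, v, 0, 0]
                    p01 = P[c, v, 0, 1]
                    p10 = P[c, v, 1, 0]
                    p11 = P[c, v, 1, 1]
                    for s in range(n_sites):
                        m0 = p00 * L[v, c, s, 0] + p01 * L[v, c, s, 1]
                        m1 = p10 * L[v, c, s, 0] + p11 * L[v, c, s, 1]
                        L[u, c, s, 0] *= m0
                        L[u, c, s, 1] *= m1
            for c in range(n_cat):
                for s in range(n_sites):
                    m = L[u, c, s, 0]
                    if L[u, c, s, 1] > m:
                        m = L[u, c, s, 1]
                    if m > 0.0:
                        logscale[c, s] += np.log(m)
                        L[u, c, s, 0] /= m
                        L[u, c, s, 1] /= m
        return L, logscale

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def conditional_likelihoods(columns: np.ndarray, arrays: TreeArrays,
                            P: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Postorder conditional likelihoods L[u:x] for every node.

    Parameters
    ----------
    columns : int array, shape (n_species, n_sites)
        Entry codes 0/1/2 in the table's species row order.
    P : array, shape (n_cat, n_nodes, 2, 2)
        Edge transition matrices per rate category.

    Returns
    -------
    L : array, shape (n_nodes, n_cat, n_sites, 2)
        Scaled conditional likelihoods.
    logscale : array, shape (n_cat, n_sites)
        Per-(category, site) log of the accumulated scaling factor, so the
        true conditional likelihood at the root is
        ``L[root] * exp(logscale)``.
    """
    tree = arrays.tree
    n_cat = P.shape[0]
    n_sites = columns.shape[1]
    leaf_state = np.zeros((tree.n_nodes, n_sites), dtype=np.int8)
    leaf_state[arrays.leaf_idx] = columns
    if _HAVE_NUMBA:
        return _prune_kernel(np.ascontiguousarray(P), leaf_state,
                             arrays.is_leaf, arrays.children_flat,
                             arrays.child_ptr)
    L = np.empty((tree.n_nodes, n_cat, n_sites, 2))
    logscale = np.zeros((n_cat, n_sites))
    for u in tree.postorder():
        if arrays.is_leaf[u]:
            L[u] = _LEAF_LIK[leaf_state[u]][None, :, :]
            continue
        acc = np.ones((n_cat, n_sites, 2))
        for v in tree.children[u]:
            # message to parent: M[x] = sum_y P_v[x,y] * L_v[y]
            acc = acc * np.einsum("cxy,csy->csx", P[:, v], L[v])
        # rescale to avoid underflow on deep trees
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        logscale += np.log(m)
        L[u] = acc / m[..., None]
    return L, logscale


def column_log_likelihoods(columns: np.ndarray, arrays: TreeArrays,
                           params: ModelParams
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-category and marginal log-likelihoods of each column.

    Returns ``(per_cat, marginal)`` of shapes ``(n_cat, n_sites)`` and
    ``(n_sites,)``; the marginal is the equal-weight mixture over the
    rate-category grid.
    """
    P, _, _ = edge_transition_tensor(arrays.tree, params)
    L, logscale = conditional_likelihoods(columns, arrays, P)
    root = arrays.tree.root
    prior = np.array([1.0 - params.pi, params.pi])
    rootlik = L[root] @ prior  # (n_cat, n_sites)
    with np.errstate(divide="ignore"):
        per_cat = np.log(rootlik) + logscale
    marginal = _logsumexp0(per_cat) - np.log(per_cat.shape[0])
    return per_cat, marginal


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0, tolerating -inf columns."""
    m = a.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(a - safe).sum(axis=0))
    return np.where(np.isfinite(m), out, m)


def _column_matrix(table: ProfileTable, tree: SpeciesTree) -> tuple[np.ndarray, TreeArrays]:
    arrays = TreeArrays.build(tree, table.species)
    return table.entries, arrays


def site_likelihood(column: np.ndarray | list, tree: SpeciesTree,
                    params: ModelParams, species: list[str],
                    gamma: float = 1.0, nu: float = 1.0) -> float:
    """Likelihood of one column at fixed rate multipliers (γ, ν).

    ``column`` holds codes 0/1/2 ordered as ``species``; '*' entries are
    marginalized (conditional likelihood (1, 1) at that leaf).
    """
    col = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    arrays = TreeArrays.build(tree, species)
    fixed = ModelParams(
        pi=params.pi, edge_params=params.edge_params,
        shape_gain=params.shape_gain, shape_loss=params.shape_loss,
        k_gain=1, k_loss=1,
    )
    P, _, _ = edge_transition_tensor(tree, fixed)
    if gamma != 1.0 or nu != 1.0:
        lengths, ratios = params.edge_arrays(tree)
        a = gamma * lengths * ratios
        b = nu * lengths * (1 - ratios)
        for u in tree.nonroot():
            P[0, u] = _transition_matrix(a[u], b[u])
    L, logscale = conditional_likelihoods(col, arrays, P)
    prior = np.array([1.0 - params.pi, params.pi])
    return float((L[tree.root][0, 0] @ prior) * np.exp(logscale[0, 0]))


def marginal_site_likelihood(column: np.ndarray | list, tree: SpeciesTree,
                             params: ModelParams, species: list[str]) -> float:
    """Column likelihood averaged over the rate-category grid."""
    col = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    arrays = TreeArrays.build(tree, species)
    _, marginal = column_log_likelihoods(col, arrays, params)
    return float(np.exp(marginal[0]))


def p_all_absent(tree: SpeciesTree, params: ModelParams) -> float:
    """Probability p0 that a site leaves no trace in any terminal taxon."""
    species = tree.leaf_names()
    col = np.zeros(len(species), dtype=np.int8)
    return marginal_site_likelihood(col, tree, params, species)


def dataset_log_likelihood(table: ProfileTable, tree: SpeciesTree,
                           params: ModelParams) -> float:
    """Observability-conditioned log-likelihood of a filtered table.

    Each column contributes its marginal log-likelihood minus
    log(1 − p0); p0 = 1 (no observable column possible) is an error.
    """
    columns, arrays = _column_matrix(table, tree)
    _, marginal = column_log_likelihoods(columns, arrays, params)
    p0 = p_all_absent(tree, params)
    if p0 >= 1.0:
        raise ModelError("p_all_absent = 1: model admits no observable column")
    return float(marginal.sum() - table.n_sites * np.log1p(-p0))
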