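"""Phylogenetic-signal statistics and tree utilities.

Two statistics are provided, matching the standard comparative-methods
toolkit for community data:

* Fritz-Purvis **D** for binary traits (e.g. seed-predator incidence).
  The observed sum of sister-clade differences is scaled between its
  expectations under (i) random shuffling of tip labels (D = 1) and
  (ii) a Brownian threshold model (D = 0); D < 0 indicates extreme
  clumping, D > 1 overdispersion.
* **Blomberg's K** for continuous traits (richness, predation rate).
  K compares the observed trait variance to the variance expected under
  Brownian motion given the tree's covariance structure; K = 1 under
  Brownian evolution, K << 1 when close relatives are no more similar
  than distant ones.

Trees are dendropy objects throughout; internally they are converted to
index arrays so the permutation/simulation nulls are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "SignalResultBinary",
    "SignalResultContinuous",
    "TreeArrays",
    "tree_to_arrays",
    "patristic_distances",
    "phylo_covariance",
    "graft_at_genus",
    "genus_of",
    "brownian_tips",
    "threshold_binary",
    "fritz_purvis_D",
    "blomberg_K",
]


@dataclass
class SignalResultBinary:
    D: float
    p_D_less_1: float
    p_D_greater_0: float
    n_permutations: int
    d_obs: float


@dataclass
class SignalResultContinuous:
    K: float
    p: float
    n_randomisations: int


def genus_of(species: str) -> str:
    """Genus token of a binomial (text before the first space/underscore)."""
    return species.replace("_", " ").split()[0]


@dataclass
class TreeArrays:
    """Array encoding of a rooted binary tree.

    Tips are indices ``0..n-1`` (order given by ``labels``); internal
    nodes ``n..2n-2`` appear in postorder in ``children`` so a single
    forward pass visits children before parents.
    """

    labels: list[str]
    children: np.ndarray  # (n-1, 2) child indices per internal node
    edge_length: np.ndarray  # (2n-1,) length of edge above each node (root: 0)
    parent: np.ndarray  # (2n-1,) parent index, root -> -1

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        n = self.n_tips
        depth = np.zeros(2 * n - 1)
        # internal nodes in reverse postorder = parents before children
        for j in range(self.children.shape[0] - 1, -1, -1):
            node = n + j
            for c in self.children[j]:
                depth[c] = depth[node] + self.edge_length[c]
        return depth


def tree_to_arrays(tree: dendropy.Tree) -> TreeArrays:
    """Convert a dendropy tree to :class:`TreeArrays`.

    Polytomies are resolved arbitrarily with zero-length edges; missing
    edge lengths are treated as zero.
    """
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    leaves = sorted(work.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    n = len(labels)
    index = {id(nd): i for i, nd in enumerate(leaves)}
    children = np.zeros((n - 1, 2), dtype=np.int64)
    edge_length = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    next_internal = n
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            edge_length[index[id(nd)]] = nd.edge.length or 0.0
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:  # root of an already-binary tree can be unary
            if len(kids) == 1:
                # collapse unary node: splice child upward
                index[id(nd)] = index[id(kids[0])]
                edge_length[index[id(nd)]] += nd.edge.length or 0.0
                continue
            raise ValueError("tree could not be resolved to binary")
        j = next_internal - n
        idx = next_internal
        next_internal += 1
        index[id(nd)] = idx
        children[j] = [index[id(kids[0])], index[id(kids[1])]]
        edge_length[idx] = nd.edge.length or 0.0
        parent[children[j][0]] = idx
        parent[children[j][1]] = idx
    return TreeArrays(labels, children[: next_internal - n], edge_length, parent)


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs tip distances (sum of branch lengths along the path)."""
    arr = tree_to_arrays(tree)
    C = _covariance_from_arrays(arr)
    depth = np.diag(C)
    dist = depth[:, None] + depth[None, :] - 2 * C
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=arr.labels, columns=arr.labels)


def _covariance_from_arrays(arr: TreeArrays) -> np.ndarray:
    """C[i, j] = shared root-to-MRCA path length of tips i and j."""
    n = arr.n_tips
    depth = arr.node_depths()
    C = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for j in range(arr.children.shape[0]):
        node = n + j
        a, b = arr.children[j]
        ta, tb = tipsets.pop(int(a)), tipsets.pop(int(b))
        C[np.ix_(ta, tb)] = depth[node]
        C[np.ix_(tb, ta)] = depth[node]
        tipsets[node] = np.concatenate([ta, tb])
    C[np.diag_indices(n)] = depth[:n]
    return C


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance matrix implied by the tree."""
    arr = tree_to_arrays(tree)
    return pd.DataFrame(_covariance_from_arrays(arr), index=arr.labels, columns=arr.labels)


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------


def graft_at_genus(tree: dendropy.Tree, species: str, genus: str | None = None) -> dendropy.Tree:
    """Attach a missing species at the stem of its genus clade.

    The new tip is bound to the midpoint of the edge subtending the MRCA
    of its congeners (for a single congener: the midpoint of that tip's
    terminal edge) with a pendant length chosen so its root-to-tip depth
    equals the congeners' mean depth — an ultrametric input therefore
    stays ultrametric.  Raises ``ValueError`` when no congener is in the
    tree; such species must be dropped from signal analyses instead.
    """
    genus = genus or genus_of(species)
    work = tree.clone(depth=1)
    work.is_rooted = True
    congeners = [
        leaf for leaf in work.leaf_node_iter() if genus_of(leaf.taxon.label) == genus
    ]
    if not congeners:
        raise ValueError(f"no congener of genus {genus!r} in the tree")

    depths = {}
    for leaf in work.leaf_node_iter():
        d, nd = 0.0, leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths[leaf.taxon.label] = d
    target_depth = float(np.mean([depths[c.taxon.label] for c in congeners]))

    if len(congeners) == 1:
        attach_node = congeners[0]
    else:
        attach_node = work.mrca(taxa=[c.taxon for c in congeners])

    parent = attach_node.parent_node
    taxon = work.taxon_namespace.require_taxon(label=species)
    if parent is None:
        # genus spans the whole tree: bind directly at the root
        new_tip = attach_node.new_child(taxon=taxon, edge_length=target_depth)
    else:
        stem = attach_node.edge.length or 0.0
        node_depth = _node_depth(parent) + stem / 2
        parent.remove_child(attach_node)
        mid = parent.new_child(edge_length=stem / 2)
        mid.add_child(attach_node)
        attach_node.edge.length = stem / 2
        new_tip = mid.new_child(
            taxon=taxon, edge_length=max(target_depth - node_depth, 0.0)
        )
    del new_tip
    work.update_bipartitions(suppress_unifurcations=False)
    return work


def _node_depth(node: dendropy.Node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


# ---------------------------------------------------------------------------
# Brownian simulation helpers
# ---------------------------------------------------------------------------


def brownian_tips(arr: TreeArrays, n_sets: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n_sets`` Brownian traits (unit rate, root value 0).

    Returns an (n_sets, n_tips) array; tip value = sum of independent
    N(0, branch length) increments along the root-to-tip path.
    """
    n = arr.n_tips
    total = 2 * n - 1
    incr = rng.normal(size=(n_sets, total)) * np.sqrt(arr.edge_length)
    values = np.zeros((n_sets, total))
    values[:, total - 1] = 0.0  # root
    for j in range(arr.children.shape[0] - 1, -1, -1):
        node = n + j
        for c in arr.children[j]:
            values[:, c] = values[:, node] + incr[:, c]
    return values[:, :n]


def threshold_binary(values: np.ndarray, n_ones: int) -> np.ndarray:
    """Mark the ``n_ones`` largest entries per row as state 1."""
    order = np.argsort(values, axis=-1)
    out = np.zeros_like(values, dtype=np.int64)
    np.put_along_axis(out, order[..., -n_ones:], 1, axis=-1)
    return out


def _sister_difference_sum(arr: TreeArrays, tips: np.ndarray) -> np.ndarray:
    """d = sum over internal nodes of |v_left - v_right|.

    Node values are the successive equal-weight averages of daughter
    values, computed tips-down (postorder).  ``tips`` has shape
    (n_sets, n_tips); returns (n_sets,).
    """
    n = arr.n_tips
    n_sets = tips.shape[0]
    vals = np.empty((n_sets, 2 * n - 1))
    vals[:, :n] = tips
    d = np.zeros(n_sets)
    for j in range(arr.children.shape[0]):
        a, b = arr.children[j]
        d += np.abs(vals[:, a] - vals[:, b])
        vals[:, n + j] = 0.5 * (vals[:, a] + vals[:, b])
    return d


def fritz_purvis_D(
    tree: dendropy.Tree,
    binary_trait: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SignalResultBinary:
    """Fritz-Purvis D for a binary trait on a rooted tree.

    ``binary_trait`` is indexed by tip label with values in {0, 1}; every
    indexed species must be a tip (tips without data are pruned).  The
    permutation null shuffles tip labels; the Brownian null simulates
    unit-rate Brownian motion and thresholds at the observed prevalence.

    ``p_D_less_1`` is the proportion of shuffled values with d <= d_obs
    (evidence of any clumping); ``p_D_greater_0`` the proportion of
    Brownian values with d >= d_obs.
    """
    trait = binary_trait.dropna().astype(int)
    if trait.nunique() < 2:
        raise ValueError("trait is monomorphic; D is undefined")
    work = tree.clone(depth=1)
    keep = set(trait.index)
    taxa = [t for t in work.taxon_namespace if t.label in keep]
    if len(taxa) < len(keep):
        missing = keep - {t.label for t in taxa}
        raise ValueError(f"trait species missing from tree: {sorted(missing)[:5]}")
    work.retain_taxa(taxa)
    arr = tree_to_arrays(work)
    x = trait.reindex(arr.labels).to_numpy()

    rng = np.random.default_rng(seed)
    d_obs = float(_sister_difference_sum(arr, x[None, :])[0])

    shuffles = np.array([rng.permutation(x) for _ in range(n_perm)])
    d_r = _sister_difference_sum(arr, shuffles)

    n_ones = int(x.sum())
    bm = brownian_tips(arr, n_perm, rng)
    d_b = _sister_difference_sum(arr, threshold_binary(bm, n_ones))

    denom = d_r.mean() - d_b.mean()
    if abs(denom) < 1e-12:
        raise ValueError("degenerate scaling: random and Brownian means coincide")
    D = (d_obs - d_b.mean()) / denom
    return SignalResultBinary(
        D=float(D),
        p_D_less_1=float((d_r <= d_obs).mean()),
        p_D_greater_0=float((d_b >= d_obs).mean()),
        n_permutations=n_perm,
        d_obs=d_obs,
    )


def blomberg_K(
    tree: dendropy.Tree,
    continuous_trait: pd.Series,
    n_rand: int = 999,
    seed: int | None = None,
) -> SignalResultContinuous:
    """Blomberg's K with a tip-shuffling randomisation test.

    With C the Brownian covariance matrix of the pruned tree,
    a-hat = (1'C^-1 x)/(1'C^-1 1), MSE0 = sum((x - a)^2)/(n-1),
    MSE = (x - a)' C^-1 (x - a)/(n-1) and

        K = (MSE0 / MSE) / [ (tr C - n / (1'C^-1 1)) / (n - 1) ].

    The p-value is the proportion of tip-shuffled datasets (observed
    included) whose MSE is <= the observed MSE — smaller MSE means the
    trait fits the tree better than a random arrangement.
    """
    trait = continuous_trait.dropna().astype(float)
    if trait.var() <= 0:
        raise ValueError("trait variance must be positive")
    work = tree.clone(depth=1)
    keep = set(trait.index)
    taxa = [t for t in work.taxon_namespace if t.label in keep]
    if len(taxa) < len(keep):
        missing = keep - {t.label for t in taxa}
        raise ValueError(f"trait species missing from tree: {sorted(missing)[:5]}")
    work.retain_taxa(taxa)
    arr = tree_to_arrays(work)
    C = _covariance_from_arrays(arr)
    n = arr.n_tips
    x = trait.reindex(arr.labels).to_numpy()

    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError:
        C = C + 1e-8 * np.eye(n)
        try:
            cho = linalg.cho_factor(C)
        except linalg.LinAlgError as err:
            raise ValueError(
                "singular phylogenetic covariance (zero-length cherries?)"
            ) from err

    Cinv1 = linalg.cho_solve(cho, np.ones(n))
    s1 = Cinv1.sum()  # 1' C^-1 1

    def mse_of(X: np.ndarray) -> np.ndarray:
        # X: (n, m) columns of trait arrangements
        a = (Cinv1 @ X) / s1
        R = X - a
        return np.einsum("im,im->m", R, linalg.cho_solve(cho, R)) / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.column_stack([x] + [rng.permutation(x) for _ in range(n_rand)])
    mses = mse_of(perms)
    mse_obs = mses[0]
    mse0 = float(((x - (Cinv1 @ x) / s1) ** 2).sum() / (n - 1))
    expected_ratio = (np.trace(C) - n / s1) / (n - 1)
    K = (mse0 / mse_obs) / expected_ratio
    p = float((mses <= mse_obs).mean())
    return SignalResultContinuous(K=float(K), p=p, n_randomisations=n_rand)
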