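"""Potential for apparent competition (PAC) between plant species.

For a quantitative web with link weights ``alpha[i, k]`` (seeds of plant
i killed by predator k), the PAC entry

    d_ij = sum_k  (alpha_ik / sum_l alpha_il) * (alpha_jk / sum_m alpha_mk)

is the probability that a seed predator attacking plant i developed on
plant j: the share of i's predator load contributed by predator k, times
the share of k's production derived from j.  Rows sum to one, the matrix
is generally asymmetric, and it is invariant to rescaling all weights by
a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .io import QuantitativeWeb
from .signal import patristic_distances

__all__ = ["PACMatrix", "pac_matrix", "pac_exceedance", "pac_phylo_correlation"]


@dataclass
class PACMatrix:
    plants: list[str]
    d: np.ndarray  # (n, n), rows sum to 1


def pac_matrix(web) -> PACMatrix:
    """Compute the PAC matrix of a non-empty quantitative web."""
    if isinstance(web, QuantitativeWeb):
        alpha, plants = web.alpha, web.plants
    else:
        alpha = np.asarray(web, dtype=float)
        plants = [f"plant_{i}" for i in range(alpha.shape[0])]
    if alpha.size == 0:
        raise ValueError("empty web")
    row_tot = alpha.sum(axis=1, keepdims=True)
    col_tot = alpha.sum(axis=0, keepdims=True)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError("every plant and predator must have a positive total")
    load_share = alpha / row_tot  # P[predator k | attack on i]
    origin_share = alpha / col_tot  # P[developed on j | predator k]
    return PACMatrix(plants=list(plants), d=load_share @ origin_share.T)


def pac_exceedance(pac: PACMatrix, threshold: float = 0.1) -> dict:
    """Count ordered off-diagonal plant pairs with PAC strictly above threshold."""
    d = pac.d
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_pairs = n * (n - 1)
    n_exceed = int((d[off] > threshold).sum())
    return {
        "n_pairs": n_pairs,
        "n_exceed": n_exceed,
        "fraction": n_exceed / n_pairs if n_pairs else float("nan"),
    }


def pac_phylo_correlation(
    pac: PACMatrix, tree: dendropy.Tree
) -> dict:
    """Spearman correlation of positive off-diagonal PAC with patristic distance.

    Plant species absent from the tree are dropped (their count is
    reported); pairs with PAC = 0 are excluded, matching the convention
    that only realised sharing is informative.  The p-value uses the
    standard t approximation and treats pairs as independent — the
    pairwise non-independence inherent to distance data is unmodelled.
    """
    dist = patristic_distances(tree)
    present = [p for p in pac.plants if p in dist.index]
    n_dropped = len(pac.plants) - len(present)
    if len(present) < 3:
        raise ValueError("need >= 3 plants present in both the PAC matrix and tree")
    idx = [pac.plants.index(p) for p in present]
    d = pac.d[np.ix_(idx, idx)]
    pd_mat = dist.loc[present, present].to_numpy()
    n = len(present)
    off = ~np.eye(n, dtype=bool)
    mask = off & (d > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable (PAC > 0) pairs")
    rho, p = stats.spearmanr(d[mask], pd_mat[mask])
    return {
        "rho": float(rho),
        "p_value": float(p),
        "n_pairs_used": int(mask.sum()),
        "n_plants_dropped": n_dropped,
    }
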