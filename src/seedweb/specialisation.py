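"""Network- and species-level specialisation statistics.

The species-level index d' and the network-level index H2' standardise
Kullback-Leibler / Shannon quantities between their minimum and maximum
attainable under fixed integer marginal totals, so both live in [0, 1]
with 0 = perfectly opportunistic (partners used in proportion to their
availability) and 1 = maximally specialised.

The marginal-constrained extrema are found exactly by dynamic
programming / bounded enumeration whenever the table is small enough for
that to be feasible, and otherwise by the conventional greedy
(minimum-entropy) and largest-remainder proportional (maximum-entropy)
integer fills.  Real-valued link weights are first scaled and rounded to
an integer grand total, since the null models underlying the indices are
defined on integer event counts; `` 0 * ln 0 `` is 0 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset, QuantitativeWeb

__all__ = [
    "connectance",
    "d_prime",
    "d_prime_all",
    "H2_prime",
    "diet_richness",
    "chao1_coverage",
    "Chao1Result",
    "compare_orders_dprime",
    "specialisation_report",
    "integerise",
]

DEFAULT_INTEGER_TOTAL = 10_000
_EXACT_STATE_LIMIT = 2_000_000  # DP state-space budget before heuristic fallback


def _as_matrix(web) -> np.ndarray:
    if isinstance(web, QuantitativeWeb):
        return web.alpha
    return np.asarray(web, dtype=float)


def connectance(web) -> float:
    """Realised links divided by all possible consumer x resource links."""
    m = _as_matrix(web)
    if m.size == 0:
        raise ValueError("empty web")
    return float((m > 0).sum() / m.size)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def integerise(matrix: np.ndarray, total: int | None = None) -> np.ndarray:
    """Scale a nonnegative matrix to integer counts with a fixed grand total.

    If ``total`` is None and the matrix is already integral it is returned
    as ints; otherwise it is scaled so the grand total becomes ``total``
    (default 10 000) and rounded by largest remainder, preserving the
    grand total exactly and keeping every positive cell positive.
    """
    m = np.asarray(matrix, dtype=float)
    if total is None:
        if np.allclose(m, np.round(m)):
            return np.round(m).astype(np.int64)
        total = DEFAULT_INTEGER_TOTAL
    s = m.sum()
    if s <= 0:
        raise ValueError("matrix grand total must be positive")
    scaled = m * (total / s)
    base = np.floor(scaled).astype(np.int64)
    # keep observed links present after rounding
    base[(m > 0) & (base == 0)] = 1
    deficit = int(total - base.sum())
    if deficit > 0:
        remainders = (scaled - base).ravel()
        order = np.argsort(-remainders, kind="stable")[:deficit]
        flat = base.ravel()
        flat[order] += 1
        base = flat.reshape(m.shape)
    elif deficit < 0:
        # bumping zero-cells to 1 can overshoot; take back from largest cells
        flat = base.ravel()
        order = np.argsort(-flat, kind="stable")
        i = 0
        while deficit < 0 and i < flat.size:
            if flat[order[i]] > 1:
                flat[order[i]] -= 1
                deficit += 1
            else:
                i += 1
        base = flat.reshape(m.shape)
    return base


# ---------------------------------------------------------------------------
# d' (Kullback-Leibler specialisation of one consumer)
# ---------------------------------------------------------------------------


def _d_value(alloc: np.ndarray, q: np.ndarray) -> float:
    """d = sum_i p_i ln(p_i / q_i) for an integer allocation."""
    A = alloc.sum()
    if A == 0:
        return 0.0
    p = alloc / A
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


def _enumerate_compositions(total: int, caps: tuple[int, ...]):
    """All allocations of ``total`` units over len(caps) cells, cell i <= caps[i]."""
    n = len(caps)

    def rec(i: int, remaining: int, prefix: list[int]):
        if i == n - 1:
            if remaining <= caps[i]:
                yield prefix + [remaining]
            return
        tail_cap = sum(caps[i + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(caps[i], remaining)
        for v in range(lo, hi + 1):
            yield from rec(i + 1, remaining - v, prefix + [v])

    yield from rec(0, total, [])


def _n_compositions_bound(total: int, n_cells: int) -> float:
    return math.comb(total + n_cells - 1, n_cells - 1)


def _d_extrema(A: int, caps: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """Min and max of d over integer allocations of A bounded by caps."""
    caps = np.minimum(caps, A)
    if _n_compositions_bound(A, len(caps)) <= 200_000:
        dmin, dmax = math.inf, -math.inf
        for alloc in _enumerate_compositions(int(A), tuple(int(c) for c in caps)):
            d = _d_value(np.array(alloc), q)
            dmin = min(dmin, d)
            dmax = max(dmax, d)
        return dmin, dmax
    # heuristics: greedy rarest-first fill for the max, capped proportional
    # allocation with largest-remainder rounding for the min
    order = np.lexsort((np.arange(len(q)), q))
    alloc_max = np.zeros(len(q), dtype=np.int64)
    remaining = int(A)
    for i in order:
        take = min(int(caps[i]), remaining)
        alloc_max[i] = take
        remaining -= take
        if remaining == 0:
            break
    target = A * q
    alloc_min = np.minimum(np.floor(target).astype(np.int64), caps.astype(np.int64))
    while alloc_min.sum() < A:
        room = caps - alloc_min
        frac = np.where(room > 0, target - alloc_min, -np.inf)
        alloc_min[int(np.argmax(frac))] += 1
    return _d_value(alloc_min, q), _d_value(alloc_max, q)


def d_prime(web, consumer_index: int, integer_total: int | None = None) -> float:
    """Standardised specialisation d' of one consumer column.

    ``integer_total`` rescales real-valued webs to that integer grand
    total before computing the marginal-constrained extrema (by default
    integral webs are used as-is and real webs are scaled to 10 000; when
    the web was built from rearing data the natural choice is the total
    number of reared individuals).
    """
    return d_prime_all(web, integer_total=integer_total)[consumer_index]


def d_prime_all(web, integer_total: int | None = None) -> np.ndarray:
    """d' for every consumer column of the web."""
    m = integerise(_as_matrix(web), integer_total)
    row_tot = m.sum(axis=1)
    grand = m.sum()
    q = row_tot / grand
    out = np.empty(m.shape[1])
    for k in range(m.shape[1]):
        A = int(m[:, k].sum())
        if A == 0:
            raise ValueError(f"consumer column {k} has zero total")
        d_obs = _d_value(m[:, k], q)
        dmin, dmax = _d_extrema(A, row_tot, q)
        if dmax - dmin <= 1e-12:
            out[k] = 0.0
        else:
            out[k] = min(1.0, max(0.0, (d_obs - dmin) / (dmax - dmin)))
    return out


# ---------------------------------------------------------------------------
# H2' (network-level two-dimensional Shannon specialisation)
# ---------------------------------------------------------------------------


def _h2(matrix: np.ndarray) -> float:
    m = matrix.sum()
    if m <= 0:
        return 0.0
    return float(-_xlogx(matrix / m).sum())


def _h2_extrema_exact(
    rows: tuple[int, ...], cols: tuple[int, ...]
) -> tuple[float, float] | None:
    """Exact entropy extrema over integer tables with the given marginals.

    Dynamic programme over rows with the remaining column totals as
    state; the entropy is cell-separable so partial sums compose.
    Returns None when the state space exceeds the budget.
    """
    state_space = math.prod(c + 1 for c in cols)
    if state_space * len(rows) > _EXACT_STATE_LIMIT:
        return None
    grand = sum(rows)
    logm = math.log(grand)

    def cell_term(n: int) -> float:
        # contribution -(n/m) ln(n/m); summed over cells this is H2
        return 0.0 if n == 0 else -(n / grand) * (math.log(n) - logm)

    @lru_cache(maxsize=None)
    def best(i: int, remaining: tuple[int, ...]) -> tuple[float, float]:
        if i == len(rows):
            return (0.0, 0.0)
        lo_hi = []
        for alloc in _enumerate_compositions(rows[i], remaining):
            term = sum(cell_term(v) for v in alloc)
            nxt = tuple(r - v for r, v in zip(remaining, alloc))
            sub_lo, sub_hi = best(i + 1, nxt)
            lo_hi.append((term + sub_lo, term + sub_hi))
        lo = min(v[0] for v in lo_hi)
        hi = max(v[1] for v in lo_hi)
        return lo, hi

    # quick feasibility-and-size guard on row compositions
    for r in rows:
        if _n_compositions_bound(r, len(cols)) > 200_000:
            best.cache_clear()
            return None
    lo, hi = best(0, cols)
    best.cache_clear()
    return lo, hi


def _h2_min_greedy(rows: np.ndarray, cols: np.ndarray) -> float:
    """Minimum-entropy heuristic: pair off largest remaining marginals."""
    r = rows.astype(np.int64).copy()
    c = cols.astype(np.int64).copy()
    fill = []
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        v = min(r[i], c[j])
        fill.append(v)
        r[i] -= v
        c[j] -= v
    grand = rows.sum()
    arr = np.array(fill, dtype=float)
    return float(-_xlogx(arr / grand).sum())


def _h2_max_proportional(rows: np.ndarray, cols: np.ndarray) -> float:
    """Maximum-entropy heuristic: proportional fill, largest-remainder ints."""
    grand = rows.sum()
    expected = np.outer(rows, cols) / grand
    base = np.floor(expected).astype(np.int64)
    row_def = rows - base.sum(axis=1)
    col_def = cols - base.sum(axis=0)
    frac = expected - base
    while row_def.sum() > 0:
        # place one unit in the highest-remainder cell whose row & col need it
        mask = np.outer(row_def > 0, col_def > 0)
        cand = np.where(mask, frac, -np.inf)
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        base[i, j] += 1
        frac[i, j] -= 1.0
        row_def[i] -= 1
        col_def[j] -= 1
    return _h2(base.astype(float))


def H2_prime(web, integer_total: int | None = None) -> float:
    """Network-level standardised specialisation H2' in [0, 1].

    1 on a perfectly specialised (block-diagonal) web, 0 when link
    weights are proportional to the product of the marginals.  A web with
    a single cell (or marginals that admit only one table) has no room to
    deviate and returns 1 by convention.
    """
    m = integerise(_as_matrix(web), integer_total)
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    if m.size == 1:
        return 1.0
    exact = _h2_extrema_exact(tuple(int(v) for v in rows), tuple(int(v) for v in cols))
    if exact is not None:
        h2_min, h2_max = exact
    else:
        h2_min = _h2_min_greedy(rows, cols)
        h2_max = _h2_max_proportional(rows, cols)
    h2_obs = _h2(m.astype(float))
    if h2_max - h2_min <= 1e-12:
        return 1.0
    return float(min(1.0, max(0.0, (h2_max - h2_obs) / (h2_max - h2_min))))


# ---------------------------------------------------------------------------
# diet richness, Chao1, order comparison
# ---------------------------------------------------------------------------


def diet_richness(dataset: Dataset, min_individuals: int = 10) -> pd.DataFrame:
    """Host-plant counts per seed-predator species from the full rearing data.

    Species with fewer than ``min_individuals`` reared individuals are
    excluded (documented diet breadth depends strongly on sampling
    effort).  With ``min_individuals=1`` the returned table carries a
    ``sampling_class`` column (singleton / 2-9 / >=10) so histograms can
    show the contribution of poorly sampled species per richness bin.
    """
    em = dataset.emergences
    em = em[em["is_seed_predator"]]
    em = em.merge(
        dataset.rearing[["sample_id", "plant_species"]], on="sample_id", how="left"
    )
    per = em.groupby("insect_species").agg(
        richness=("plant_species", "nunique"),
        n_individuals=("count", "sum"),
        insect_order=("insect_order", "first"),
    )
    per["sampling_class"] = pd.cut(
        per["n_individuals"],
        bins=[0, 1, 9, np.inf],
        labels=["singleton", "2-9", ">=10"],
    )
    return per[per["n_individuals"] >= min_individuals]


@dataclass
class Chao1Result:
    S_obs: int
    F1: int
    F2: int
    S_est: float
    coverage: float


def chao1_coverage(
    association_counts, bias_corrected: bool = True
) -> Chao1Result:
    """Chao1 interaction-richness estimate and sampling coverage.

    Each distinct plant x predator association counts as one "species"
    with abundance equal to the number of reared individuals.  The
    bias-corrected estimator ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``
    remains finite when no doubletons were seen; the classic
    ``S_obs + F1^2 / (2 F2)`` form is available with
    ``bias_corrected=False``.
    """
    counts = np.asarray(list(association_counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("need at least one association")
    if (counts < 1).any():
        raise ValueError("association counts must be >= 1")
    S_obs = counts.size
    F1 = int((counts == 1).sum())
    F2 = int((counts == 2).sum())
    if bias_corrected:
        S_est = S_obs + F1 * (F1 - 1) / (2 * (F2 + 1))
    else:
        S_est = S_obs + (F1 * F1 / (2 * F2) if F2 > 0 else F1 * (F1 - 1) / 2)
    return Chao1Result(S_obs, F1, F2, float(S_est), float(S_obs / S_est))


def compare_orders_dprime(d_by_order: dict[str, "np.ndarray"]) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) on d' between two orders.

    Returns both sample conventions of the statistic (``W_first`` counts
    wins of the first group, ``W_second`` of the second); exact p for
    small tie-free samples, normal approximation with tie correction
    otherwise (scipy's default switching rule).
    """
    if len(d_by_order) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, a), (name_b, b) = d_by_order.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "groups": (name_a, name_b),
        "W_first": float(res.statistic),
        "W_second": float(a.size * b.size - res.statistic),
        "p_value": float(res.pvalue),
    }


def specialisation_report(
    web: QuantitativeWeb,
    dataset: Dataset | None = None,
    integer_total: int | None = None,
) -> dict:
    """All network-level statistics for a web (plus Chao1 if data given)."""
    d_all = d_prime_all(web, integer_total=integer_total)
    report = {
        "n_plants": web.n_plants,
        "n_predators": web.n_predators,
        "n_links": int((web.alpha > 0).sum()),
        "connectance": connectance(web),
        "H2_prime": H2_prime(web, integer_total=integer_total),
        "d_prime": pd.Series(d_all, index=web.predators),
        "median_d_prime": float(np.median(d_all)),
    }
    if dataset is not None:
        from .assembly import list_associations

        assoc = list_associations(dataset)
        chao = chao1_coverage(assoc["n_individuals"])
        report["chao1"] = chao
    return report
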