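"""Exact inference for contingency tables.

Implements the two-sided Fisher exact test for 2x2 tables, its r x c
generalization (the Freeman-Halton test) by pruned enumeration over all
tables with the observed margins, and a fixed-margin Monte-Carlo estimator
for tables whose enumeration is infeasible.  Also provides the all-pairs
2x2 decomposition, p-value colour binning, and deterministic hierarchical
clustering orders for heatmap display.

Two-sided convention
--------------------
All tests use probability ordering: the p-value sums the null probabilities
of every margin-compatible table whose probability does not exceed that of
the observed table, with a relative tie tolerance of 1e-7 (the convention of
the standard R implementation).  Under independence with fixed margins the
probability of a table ``n`` with row margins ``r``, column margins ``c``
and total ``N`` is the multivariate hypergeometric mass

    P(n) = (prod_i r_i!) (prod_j c_j!) / (N! prod_ij n_ij!).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.cluster.hierarchy import linkage, leaves_list

from .records import InputError

__all__ = [
    "ExactTestResult",
    "InfeasibleEnumerationError",
    "fisher_2x2",
    "fisher_rxc_exact",
    "fisher_rxc_mc",
    "fisher_rxc_auto",
    "all_pairs_2x2",
    "bin_pvalue",
    "heatmap_order",
    "PVALUE_BINS",
]

TIE_TOL = 1e-7


class InfeasibleEnumerationError(RuntimeError):
    """Enumeration would exceed the node budget; use fisher_rxc_mc instead."""


@dataclass
class ExactTestResult:
    p: float
    method: str  # 'exact-2x2' | 'exact-rxc-enumeration' | 'monte-carlo'
    mc_reps: int | None = None
    mc_se: float | None = None
    tables_enumerated: int | None = None


def _as_int_matrix(table) -> np.ndarray:
    a = np.asarray(table)
    if a.ndim != 2:
        raise InputError("contingency table must be two-dimensional")
    if not np.all(np.isfinite(a.astype(float))):
        raise InputError("contingency table contains non-finite entries")
    ai = np.asarray(np.rint(a), dtype=np.int64)
    if not np.allclose(a.astype(float), ai):
        raise InputError("contingency table entries must be integers")
    if (ai < 0).any():
        raise InputError("contingency table entries must be non-negative")
    if ai.sum() == 0:
        raise InputError("contingency table total must be positive")
    return ai


def fisher_2x2(table) -> ExactTestResult:
    """Two-sided Fisher exact test on a 2x2 table of non-negative counts."""
    a = _as_int_matrix(table)
    if a.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got shape {a.shape}")
    n = int(a.sum())
    r1 = int(a[0].sum())
    c1 = int(a[:, 0].sum())
    if r1 in (0, n) or c1 in (0, n):
        # one empty margin: only one table is compatible
        return ExactTestResult(p=1.0, method="exact-2x2", tables_enumerated=1)
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    # log P(k) for the (0,0) cell; margins fixed
    logp = (
        gammaln(r1 + 1) + gammaln(n - r1 + 1) + gammaln(c1 + 1)
        + gammaln(n - c1 + 1) - gammaln(n + 1)
        - gammaln(ks + 1) - gammaln(r1 - ks + 1) - gammaln(c1 - ks + 1)
        - gammaln(n - r1 - c1 + ks + 1)
    )
    obs = logp[int(a[0, 0]) - kmin]
    mask = logp <= obs + math.log1p(TIE_TOL)
    p = float(np.exp(logp[mask]).sum())
    return ExactTestResult(
        p=min(1.0, p), method="exact-2x2", tables_enumerated=len(ks)
    )


def _strip_empty(a: np.ndarray) -> np.ndarray:
    a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
    return a


def fisher_rxc_exact(
    table, *, max_nodes: int = 5_000_000
) -> ExactTestResult:
    """Freeman-Halton exact test on an r x c table by pruned enumeration.

    Enumerates tables with the observed margins column by column, memoizing
    for every partial state (column index, remaining row margins) the total
    null probability of its completions together with the extreme attainable
    log-probabilities.  A depth-first pass then accumulates the two-sided
    p-value, adding whole subtrees when every completion is at least as
    extreme as the observed table and pruning subtrees in which none is.
    This visits only a small fraction of the margin-compatible tables.

    Raises
    ------
    InfeasibleEnumerationError
        if more than ``max_nodes`` allocation edges are visited; callers
        should fall back to :func:`fisher_rxc_mc`.
    """
    a = _strip_empty(_as_int_matrix(table))
    if a.shape[0] < 2 or a.shape[1] < 2:
        # degenerate after dropping empty margins: single block, p = 1
        return ExactTestResult(
            p=1.0, method="exact-rxc-enumeration", tables_enumerated=1
        )
    if a.shape == (2, 2):
        res = fisher_2x2(a)
        return ExactTestResult(
            p=res.p, method="exact-rxc-enumeration",
            tables_enumerated=res.tables_enumerated,
        )

    # the shorter axis becomes the row/state axis (branching per column is
    # polynomial in the row count); columns sorted ascending to keep early
    # branching narrow
    if a.shape[0] > a.shape[1]:
        a = a.T
    order = np.argsort(a.sum(axis=0))
    a = a[:, order]
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    ncols = len(cols)
    lg = gammaln(np.arange(int(a.sum()) + 2))

    # suffix column sums for feasibility pruning
    suffix = np.concatenate([np.cumsum(cols[::-1])[::-1][1:], [0]])

    budget = [max_nodes]

    def allocations(colsum: int, rem: tuple[int, ...], after: int):
        """Yield all splits of colsum over rows with caps rem, keeping each
        residual row margin coverable by the remaining columns."""
        r = len(rem)
        alloc = [0] * r

        def rec(i: int, left: int):
            budget[0] -= 1
            if budget[0] < 0:
                raise InfeasibleEnumerationError(
                    "enumeration node budget exceeded; use fisher_rxc_mc"
                )
            if i == r - 1:
                if left <= rem[i] and rem[i] - left <= after:
                    alloc[i] = left
                    yield tuple(alloc)
                return
            lo = max(0, left - sum(rem[i + 1:]))
            hi = min(rem[i], left)
            for v in range(lo, hi + 1):
                if rem[i] - v > after:
                    continue
                alloc[i] = v
                yield from rec(i + 1, left - v)

        yield from rec(0, colsum)

    # phase 1: for every reachable state (column index, remaining row
    # margins) compute the log-total probability weight of its completions,
    # the extreme attainable suffix weights, and the outgoing edges
    # (allocation weight, child state).
    memo: dict[
        tuple[int, tuple[int, ...]],
        tuple[float, float, float, list[tuple[float, tuple[int, ...]]]],
    ] = {}

    def stats(j, rem):
        if j == ncols:
            return (0.0, 0.0, 0.0, [])
        key = (j, rem)
        hit = memo.get(key)
        if hit is not None:
            return hit
        logs: list[float] = []
        edges: list[tuple[float, tuple[int, ...]]] = []
        mn = math.inf
        mx = -math.inf
        for alloc in allocations(int(cols[j]), rem, int(suffix[j])):
            w = -float(sum(lg[v + 1] for v in alloc))
            child_rem = tuple(x - v for x, v in zip(rem, alloc))
            child = stats(j + 1, child_rem)
            logs.append(w + child[0])
            edges.append((w, child_rem))
            mn = min(mn, w + child[1])
            mx = max(mx, w + child[2])
        if not logs:
            out = (-math.inf, math.inf, -math.inf, [])
        else:
            m = max(logs)
            out = (m + math.log(sum(math.exp(x - m) for x in logs)), mn, mx,
                   edges)
        memo[key] = out
        return out

    rem0 = tuple(int(x) for x in rows)
    stats(0, rem0)

    logconst = float(lg[rows + 1].sum() + lg[cols + 1].sum() - lg[a.sum() + 1])
    w_obs = -float(lg[a + 1].sum())
    thresh = w_obs + math.log1p(TIE_TOL)

    # phase 2: DFS over cached edges accumulating P(T) for tables whose
    # weight is at or below the threshold; whole subtrees are added or
    # pruned via the phase-1 bounds
    total_p = 0.0

    def dfs(j: int, rem: tuple[int, ...], w: float) -> None:
        nonlocal total_p
        st = memo[(j, rem)] if j < ncols else (0.0, 0.0, 0.0, [])
        if st[0] == -math.inf:
            return
        if w + st[1] > thresh:
            return  # even the most extreme completion is less extreme
        if w + st[2] <= thresh:
            total_p += math.exp(logconst + w + st[0])
            return
        for wa, child_rem in st[3]:
            dfs(j + 1, child_rem, w + wa)

    dfs(0, rem0, 0.0)
    return ExactTestResult(
        p=min(1.0, total_p),
        method="exact-rxc-enumeration",
        tables_enumerated=len(memo),
    )


def fisher_rxc_mc(table, reps: int = 1_000_000, seed: int = 0) -> ExactTestResult:
    """Monte-Carlo Freeman-Halton test by fixed-margin table sampling.

    Tables are drawn from the null (multivariate hypergeometric) distribution
    given the observed margins using sequential conditional sampling of the
    cells, row by row -- each cell is a univariate hypergeometric draw given
    what remains of its row and column margins.  The estimate uses the
    add-one correction  p_hat = (1 + #extreme) / (reps + 1)  so it is never
    exactly zero.
    """
    if not isinstance(reps, (int, np.integer)) or reps < 1000:
        raise InputError(f"reps must be an integer >= 1000, got {reps!r}")
    a = _strip_empty(_as_int_matrix(table))
    if a.shape[0] < 2 or a.shape[1] < 2:
        return ExactTestResult(
            p=1.0, method="monte-carlo", mc_reps=int(reps), mc_se=0.0
        )
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = int(a.sum())
    lg = gammaln(np.arange(n + 2))
    w_obs = -float(lg[a + 1].sum())
    thresh = w_obs + math.log1p(TIE_TOL)

    rng = np.random.default_rng(seed)
    nrow, ncol = a.shape
    extreme = 0
    batch = 200_000
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        colrem = np.tile(cols, (b, 1)).astype(np.int64)
        w = np.zeros(b)
        for i in range(nrow - 1):
            rowleft = np.full(b, int(rows[i]), dtype=np.int64)
            totleft = colrem.sum(axis=1)
            for j in range(ncol - 1):
                good = colrem[:, j].copy()
                x = rng.hypergeometric(good, totleft - good, rowleft)
                w -= lg[x + 1]
                colrem[:, j] = good - x
                rowleft -= x
                totleft -= good
            w -= lg[rowleft + 1]  # last column of the row is forced
            colrem[:, -1] -= rowleft
        w -= lg[colrem + 1].sum(axis=1)  # last row is forced
        extreme += int((w <= thresh).sum())
        done += b

    p = (1 + extreme) / (reps + 1)
    se = math.sqrt(p * (1 - p) / reps)
    return ExactTestResult(p=p, method="monte-carlo", mc_reps=int(reps), mc_se=se)


def fisher_rxc_auto(
    table, *, reps: int = 1_000_000, seed: int = 0,
    max_nodes: int = 5_000_000,
) -> ExactTestResult:
    """Exact enumeration when feasible, Monte-Carlo fallback otherwise."""
    try:
        return fisher_rxc_exact(table, max_nodes=max_nodes)
    except InfeasibleEnumerationError:
        return fisher_rxc_mc(table, reps=reps, seed=seed)


def all_pairs_2x2(table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher p for every row-pair x column-pair 2x2 sub-table.

    For an r x c input the result has C(r,2) rows and C(c,2) columns, each
    labelled ``"A-B"`` from the pair of input labels; a 4x5 table yields the
    60 post-hoc comparisons of the pairwise decomposition.
    """
    df = pd.DataFrame(table)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise InputError("all_pairs_2x2 requires at least a 2x2 table")
    row_pairs = list(itertools.combinations(df.index, 2))
    col_pairs = list(itertools.combinations(df.columns, 2))
    out = pd.DataFrame(
        index=[f"{a}-{b}" for a, b in row_pairs],
        columns=[f"{a}-{b}" for a, b in col_pairs],
        dtype=float,
    )
    for (r1, r2) in row_pairs:
        for (c1, c2) in col_pairs:
            sub = df.loc[[r1, r2], [c1, c2]].to_numpy()
            # an empty sub-table carries no evidence either way
            p = 1.0 if sub.sum() == 0 else fisher_2x2(sub).p
            out.loc[f"{r1}-{r2}", f"{c1}-{c2}"] = p
    return out


# Fig-style display bins: half-open on the right except the last.
PVALUE_BINS = [
    (0.0, 0.05, "red"),
    (0.05, 0.1, "pink"),
    (0.1, 0.2, "white"),
    (0.2, 0.4, "light blue"),
    (0.4, 1.0, "dark blue"),
]

BIN_COLOURS = {
    "red": "#d73027",
    "pink": "#fbb4ae",
    "white": "#ffffff",
    "light blue": "#abd9e9",
    "dark blue": "#4575b4",
}


def bin_pvalue(p: float) -> str:
    """Map a p-value to its heatmap colour category.

    Bins: [0, 0.05) red; [0.05, 0.1) pink; [0.1, 0.2) white;
    [0.2, 0.4) light blue; [0.4, 1.0] dark blue.
    """
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise InputError(f"p-value must be in [0, 1], got {p}")
    for lo, hi, colour in PVALUE_BINS[:-1]:
        if lo <= p < hi:
            return colour
    return PVALUE_BINS[-1][2]


def heatmap_order(pmat: pd.DataFrame) -> tuple[list, list]:
    """Deterministic clustered display order for a p-value matrix.

    Complete-linkage hierarchical clustering on Euclidean distances, applied
    to rows and to columns independently; input rows/columns are first sorted
    by label so ties in the linkage break identically across runs.  Returns
    the row and column labels in leaf order.
    """
    df = pd.DataFrame(pmat).astype(float)
    if df.isna().any().any():
        raise InputError("p-value matrix contains missing values")
    df = df.sort_index(axis=0).sort_index(axis=1)

    def order(axis_df: pd.DataFrame) -> list:
        if axis_df.shape[0] < 2:
            return list(axis_df.index)
        z = linkage(axis_df.to_numpy(), method="complete", metric="euclidean")
        return [axis_df.index[i] for i in leaves_list(z)]

    return order(df), order(df.T)
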