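"""Exact-inference engine: oracles, invariances and display helpers."""

import itertools
import math
import subprocess
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from lungbm import exact
from lungbm.records import InputError


# --- independent brute-force oracle ---------------------------------------

def _factorial(n: int) -> int:
    return math.factorial(n)


def _table_prob(t: np.ndarray) -> Fraction:
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    num = Fraction(1)
    for r in rows:
        num *= _factorial(int(r))
    for c in cols:
        num *= _factorial(int(c))
    den = Fraction(_factorial(n))
    for v in t.ravel():
        den *= _factorial(int(v))
    return num / den


def brute_force_fisher(table) -> float:
    """Exact two-sided p by full enumeration with rational arithmetic."""
    obs = np.asarray(table, dtype=int)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    r, c = obs.shape
    p_obs = _table_prob(obs)
    total = Fraction(0)

    def rec(i, remaining_cols, acc):
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if (last >= 0).all() and last.sum() == rows[i]:
                t = np.vstack([acc, last])
                if _table_prob(t) <= p_obs:
                    total += _table_prob(t)
            return
        for combo in itertools.product(
            *(range(min(int(rows[i]), int(m)) + 1) for m in remaining_cols)
        ):
            if sum(combo) != rows[i]:
                continue
            rec(i + 1, remaining_cols - np.array(combo),
                acc + [np.array(combo)])

    rec(0, cols.copy(), [])
    return float(total)


def _random_table(rng, shape, nmax):
    while True:
        t = rng.integers(0, nmax + 1, shape)
        if t.sum() > 0 and t.sum() <= 30:
            return t


# --- 2x2 ------------------------------------------------------------------

def test_balanced_2x2_is_one():
    assert exact.fisher_2x2([[5, 5], [5, 5]]).p == 1.0


@pytest.mark.parametrize(
    "table",
    [
        [[9, 13], [5, 0]],   # parietal vs temporal, PD-L1 neg vs pos
        [[6, 17], [5, 0]],
        [[5, 0], [5, 7]],
        [[6, 17], [6, 3]],
    ],
)
def test_2x2_matches_brute_force_and_scipy(table):
    p = exact.fisher_2x2(table).p
    assert p == pytest.approx(brute_force_fisher(table), abs=1e-12)
    assert p == pytest.approx(
        scipy.stats.fisher_exact(table, alternative="two-sided")[1], rel=1e-6
    )


def test_2x2_random_tables_match_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(40):
        t = _random_table(rng, (2, 2), 8)
        assert exact.fisher_2x2(t).p == pytest.approx(
            brute_force_fisher(t), abs=1e-10
        )


def test_2x2_rejects_bad_input():
    with pytest.raises(InputError):
        exact.fisher_2x2([[1, -1], [2, 3]])
    with pytest.raises(InputError):
        exact.fisher_2x2([[0, 0], [0, 0]])
    with pytest.raises(InputError):
        exact.fisher_2x2([[1, 2, 3], [4, 5, 6]])


# --- r x c enumeration ----------------------------------------------------

def test_rxc_random_small_tables_match_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(15):
        t = _random_table(rng, (3, 3), 4)
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        assert exact.fisher_rxc_exact(t).p == pytest.approx(
            brute_force_fisher(t), abs=1e-9
        )


def test_rxc_reduces_to_2x2():
    rng = np.random.default_rng(3)
    for _ in range(30):
        t = _random_table(rng, (2, 2), 10)
        assert abs(
            exact.fisher_rxc_exact(t).p - exact.fisher_2x2(t).p
        ) < 1e-12


def test_rxc_zero_row_margin_dropped():
    res = exact.fisher_rxc_exact([[3, 4], [0, 0], [2, 1]])
    expected = exact.fisher_2x2([[3, 4], [2, 1]]).p
    assert res.p == pytest.approx(expected, abs=1e-12)


def test_rxc_degenerate_single_row_is_one():
    assert exact.fisher_rxc_exact([[3, 4, 1], [0, 0, 0]]).p == 1.0


def test_rxc_permutation_and_transpose_invariance():
    rng = np.random.default_rng(5)
    t = np.array([[4, 1, 3], [2, 5, 0], [1, 2, 6]])
    p0 = exact.fisher_rxc_exact(t).p
    for _ in range(5):
        rp = rng.permutation(3)
        cp = rng.permutation(3)
        assert exact.fisher_rxc_exact(t[rp][:, cp]).p == pytest.approx(
            p0, rel=1e-9
        )
    assert exact.fisher_rxc_exact(t.T).p == pytest.approx(p0, rel=1e-9)


def test_rxc_infeasible_enumeration_refused():
    big = np.full((5, 6), 40)
    with pytest.raises(exact.InfeasibleEnumerationError):
        exact.fisher_rxc_exact(big, max_nodes=1000)
    # the auto router falls back to Monte Carlo
    res = exact.fisher_rxc_auto(big, reps=2000, seed=0, max_nodes=1000)
    assert res.method == "monte-carlo"


def test_rxc_agrees_with_R_reference():
    """Cross-check the enumeration against R's fisher.test on a 3x4 table."""
    t = [[4, 1, 3, 2], [2, 5, 0, 1], [1, 2, 6, 3]]
    ours = exact.fisher_rxc_exact(t).p
    script = (
        "cat(fisher.test(matrix(c(4,1,3,2, 2,5,0,1, 1,2,6,3),"
        "nrow=3,byrow=TRUE))$p.value)"
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120, check=True,
        ).stdout
    except (FileNotFoundError, subprocess.SubprocessError):
        pytest.skip("Rscript unavailable")
    assert ours == pytest.approx(float(out.strip()), rel=1e-6)


# --- Monte Carlo ----------------------------------------------------------

def test_mc_concordant_with_exact():
    rng = np.random.default_rng(9)
    ok = 0
    trials = 20
    for i in range(trials):
        t = rng.integers(0, 6, (3, 3))
        t += 1  # keep margins positive
        p_exact = exact.fisher_rxc_exact(t).p
        res = exact.fisher_rxc_mc(t, reps=20_000, seed=100 + i)
        if abs(res.p - p_exact) <= 3 * max(res.mc_se, 1e-12):
            ok += 1
    assert ok >= trials - 1


def test_mc_deterministic_under_seed():
    t = [[6, 9, 5], [4, 3, 2], [17, 13, 1]]
    r1 = exact.fisher_rxc_mc(t, reps=5000, seed=4)
    r2 = exact.fisher_rxc_mc(t, reps=5000, seed=4)
    assert r1.p == r2.p
    assert r1.mc_se > 0


def test_mc_rejects_bad_reps():
    with pytest.raises(InputError):
        exact.fisher_rxc_mc([[1, 2], [3, 4]], reps=10)


def test_exact_test_conservative_under_null():
    """Rejection rate at alpha=0.05 stays at or below nominal (with
    simulation slack) for fixed-margin null tables."""
    rng = np.random.default_rng(12)
    rows = [20, 15, 15]
    cols = np.array([18, 17, 15])
    rejections = 0
    sims = 300
    for _ in range(sims):
        colrem = cols.copy()
        t = []
        for ri in rows[:-1]:
            draw = rng.multivariate_hypergeometric(colrem, ri)
            t.append(draw)
            colrem = colrem - draw
        t.append(colrem)
        p = exact.fisher_rxc_exact(np.array(t)).p
        if p < 0.05:
            rejections += 1
    rate = rejections / sims
    assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / sims)


# --- decomposition and display --------------------------------------------

def test_all_pairs_counts_and_reduction():
    df = pd.DataFrame(
        np.arange(20).reshape(4, 5) + 1,
        index=list("ABCD"), columns=list("vwxyz"),
    )
    pairs = exact.all_pairs_2x2(df)
    assert pairs.shape == (6, 10)
    assert pairs.size == 60
    two = pd.DataFrame([[3, 5], [2, 7]], index=["A", "B"], columns=["x", "y"])
    p = exact.all_pairs_2x2(two)
    assert p.shape == (1, 1)
    assert p.iloc[0, 0] == pytest.approx(
        exact.fisher_2x2(two.to_numpy()).p, abs=1e-12
    )


def test_all_pairs_label_equivariant():
    df = pd.DataFrame(
        [[4, 1, 3], [2, 5, 0], [1, 2, 6]],
        index=list("ABC"), columns=list("xyz"),
    )
    base = sorted(exact.all_pairs_2x2(df).to_numpy().ravel())
    shuffled = df.loc[["C", "A", "B"], ["z", "x", "y"]]
    assert sorted(
        exact.all_pairs_2x2(shuffled).to_numpy().ravel()
    ) == pytest.approx(base)


@pytest.mark.parametrize(
    "p,colour",
    [
        (0.0, "red"), (0.03, "red"), (0.049999, "red"),
        (0.05, "pink"), (0.099, "pink"),
        (0.1, "white"), (0.199, "white"),
        (0.2, "light blue"), (0.399, "light blue"),
        (0.4, "dark blue"), (1.0, "dark blue"),
    ],
)
def test_pvalue_bins(p, colour):
    assert exact.bin_pvalue(p) == colour


def test_pvalue_bin_rejects_out_of_range():
    with pytest.raises(InputError):
        exact.bin_pvalue(1.5)
    with pytest.raises(InputError):
        exact.bin_pvalue(-0.01)


def test_heatmap_order_groups_duplicates():
    df = pd.DataFrame(
        {"c1": [0.1, 0.9, 0.1], "c2": [0.2, 0.8, 0.2], "c3": [0.5, 0.5, 0.5]},
        index=["a", "b", "a2"],
    )
    rows, cols = exact.heatmap_order(df)
    ia, ia2 = rows.index("a"), rows.index("a2")
    assert abs(ia - ia2) == 1  # identical rows end up adjacent
    assert exact.heatmap_order(df) == exact.heatmap_order(df)  # deterministic


def test_heatmap_order_single_row_identity():
    df = pd.DataFrame([[0.1, 0.5, 0.9]], index=["only"], columns=list("abc"))
    rows, _ = exact.heatmap_order(df)
    assert rows == ["only"]


def test_heatmap_order_rejects_missing():
    df = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]])
    with pytest.raises(InputError):
        exact.heatmap_order(df)


# --- property-based: p-values are valid probabilities ----------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=8), min_size=2,
                 max_size=2),
        min_size=2, max_size=2,
    )
)
def test_2x2_pvalue_in_unit_interval(rows):
    t = np.array(rows)
    if t.sum() == 0:
        return
    p = exact.fisher_2x2(t).p
    assert 0.0 < p <= 1.0
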