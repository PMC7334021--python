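"""Cohort statistics against enumeration / linear-algebra oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from ttl5sim.stats import (
    CohortTable,
    ContingencyTable,
    fisher_exact_2x2,
    ks_two_sample,
    linear_fit_ftest,
    split_two_groups_1d,
    two_sample_t,
)


# -- independent oracles ----------------------------------------------------


from _oracles import fisher_oracle, ks_d_oracle  # noqa: E402


def split_cost_oracle(values):
    """Minimal two-cluster within-SS over all sorted splits."""
    s = np.sort(np.asarray(values, float))
    best = math.inf
    for k in range(1, len(s)):
        a, b = s[:k], s[k:]
        cost = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        best = min(best, cost)
    return best


def labels_cost(values, labels):
    v = np.asarray(values, float)
    cost = 0.0
    for lab in np.unique(labels):
        grp = v[labels == lab]
        cost += np.sum((grp - grp.mean()) ** 2)
    return cost


# -- Fisher ------------------------------------------------------------------


def test_fisher_bac_firing_table():
    """The published BAC-firing table 10/21 vs 1/18 gives p = 4.6e-3."""
    r = fisher_exact_2x2(ContingencyTable(((10, 11), (1, 17))))
    assert float(f"{r.p_value:.2g}") == pytest.approx(4.6e-3)


def test_fisher_degenerate_and_exact_cases():
    r = fisher_exact_2x2(ContingencyTable(((0, 5), (0, 7))))
    assert r.p_value == pytest.approx(1.0)
    r2 = fisher_exact_2x2(ContingencyTable(((3, 0), (0, 3))))
    assert r2.p_value == pytest.approx(0.1, abs=1e-12)


@settings(deadline=None, max_examples=120)
@given(st.tuples(*[st.integers(0, 8)] * 4))
def test_fisher_matches_enumeration(cells):
    a, b, c, d = cells
    if a + b + c + d == 0 or (a + b == 0 or c + d == 0
                              or a + c == 0 or b + d == 0):
        return
    r = fisher_exact_2x2(ContingencyTable(((a, b), (c, d))))
    assert r.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


@settings(deadline=None, max_examples=60)
@given(st.tuples(*[st.integers(0, 6)] * 4))
def test_fisher_row_col_swap_invariance(cells):
    a, b, c, d = cells
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    p1 = fisher_exact_2x2(ContingencyTable(((a, b), (c, d)))).p_value
    p2 = fisher_exact_2x2(ContingencyTable(((d, c), (b, a)))).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


# -- t test ------------------------------------------------------------------


def test_t_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r = two_sample_t(x, x)
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_t_from_published_summaries():
    """Trunk-length summaries (409±64, n=22) vs (313±65, n=26) -> t ≈ 5.13."""
    r = two_sample_t(summary_a=(409.0, 64.0, 22), summary_b=(313.0, 65.0, 26))
    assert r.statistic == pytest.approx(5.13, abs=0.02)
    assert r.extras["df"] == 46


def test_t_against_permutation_null():
    rng = np.random.default_rng(11)
    x = np.array([1.2, 3.1, 0.4])
    y = np.array([4.0, 5.5, 4.8])
    r = two_sample_t(x, y)
    pooled = np.concatenate([x, y])
    obs = abs(np.mean(x) - np.mean(y))
    count = 0
    n_perm = 20000
    for _ in range(n_perm):
        rng.shuffle(pooled)
        count += abs(pooled[:3].mean() - pooled[3:].mean()) >= obs - 1e-12
    p_perm = count / n_perm
    # permutation p for n=3+3 is coarse (granularity 1/10); t's p must land
    # within a few grid steps of the exhaustive-permutation estimate
    assert abs(r.p_value - p_perm) < 0.12


# -- KS ----------------------------------------------------------------------


def test_ks_identical_and_separated():
    x = np.array([1.0, 2.0, 3.0])
    assert ks_two_sample(x, x).statistic == pytest.approx(0.0)
    assert ks_two_sample(x, x).p_value == pytest.approx(1.0)
    r = ks_two_sample(np.array([0.0, 1.0]), np.array([10.0, 11.0]))
    assert r.statistic == pytest.approx(1.0)


@settings(deadline=None, max_examples=80)
@given(
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
)
def test_ks_d_matches_bruteforce(xs, ys):
    x, y = np.array(xs), np.array(ys)
    r = ks_two_sample(x, y)
    assert r.statistic == pytest.approx(ks_d_oracle(x, y), abs=1e-12)


# -- 1-D split ---------------------------------------------------------------


def test_split_perfectly_separated():
    labels, boundary = split_two_groups_1d([0.0, 0.0, 10.0, 10.0])
    assert list(labels) == [0, 0, 1, 1]
    assert boundary == pytest.approx(5.0)


def test_split_all_equal_single_cluster():
    labels, boundary = split_two_groups_1d([2.0, 2.0, 2.0])
    assert boundary is None
    assert set(labels) == {0}


@settings(deadline=None, max_examples=80)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2,
                max_size=12))
def test_split_globally_optimal(values):
    v = np.array(values)
    if np.ptp(v) == 0:
        return
    labels, _ = split_two_groups_1d(v)
    assert labels_cost(v, labels) == pytest.approx(split_cost_oracle(v),
                                                   rel=1e-9, abs=1e-9)


def test_split_beats_lloyd():
    rng = np.random.default_rng(5)
    v = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1.5, 15)])
    labels, _ = split_two_groups_1d(v)
    best_exact = labels_cost(v, labels)
    for seed in range(10):
        r2 = np.random.default_rng(seed)
        centers = r2.choice(v, 2, replace=False)
        for _ in range(50):
            lab = (np.abs(v[:, None] - centers[None, :])).argmin(axis=1)
            new = np.array([v[lab == k].mean() if np.any(lab == k)
                            else centers[k] for k in range(2)])
            if np.allclose(new, centers):
                break
            centers = new
        assert best_exact <= labels_cost(v, lab) + 1e-9


def test_split_duplicate_stability():
    v = [1.0, 2.0, 8.0, 9.0]
    base, _ = split_two_groups_1d(v)
    dup, _ = split_two_groups_1d(v + [2.0])
    assert list(dup[:4]) == list(base)


# -- linear fit --------------------------------------------------------------


def test_linear_fit_perfect_and_flat():
    x = np.arange(10.0)
    r = linear_fit_ftest(x, 2.0 * x + 1.0)
    assert r.extras["r2"] == pytest.approx(1.0)
    assert r.p_value == pytest.approx(0.0, abs=1e-12)
    flat = linear_fit_ftest(x, np.full(10, 3.3))
    assert flat.extras["r2"] == pytest.approx(0.0, abs=1e-12)
    assert flat.p_value == pytest.approx(1.0)


def test_linear_fit_normal_equations_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(size=12)
    y = 1.7 * x + rng.normal(size=12)
    r = linear_fit_ftest(x, y)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yhat = X @ beta
    r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    assert r.extras["slope"] == pytest.approx(beta[1], abs=1e-12)
    assert r.extras["intercept"] == pytest.approx(beta[0], abs=1e-12)
    assert r.extras["r2"] == pytest.approx(r2, abs=1e-12)


def test_linear_fit_errors():
    with pytest.raises(ValueError):
        linear_fit_ftest([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        linear_fit_ftest([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# -- cohort table ------------------------------------------------------------


def test_cohort_table_validation(tmp_path):
    rows = [{"cell_id": "a", "area": "V1", "max_adp_integral": 90.0,
             "trunk_length_um": 400.0},
            {"cell_id": "b", "area": "V2m", "max_adp_integral": 40.0,
             "trunk_length_um": 310.0}]
    tab = CohortTable(rows)
    path = tmp_path / "cohort.csv"
    tab.to_csv(path)
    back = CohortTable.from_csv(path)
    assert len(back.frame) == 2
    with pytest.raises(ValueError, match="area"):
        CohortTable([{"cell_id": "x", "area": "V3",
                      "max_adp_integral": 1.0}])
    with pytest.raises(ValueError, match="missing"):
        CohortTable([{"cell_id": "x", "area": "V1"}])
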