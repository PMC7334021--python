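"""Two-population cohort statistics.

The comparisons used on per-neuron tables: Fisher's exact test on 2x2
counts (BAC-firing / cfADP proportions), pooled-variance two-sample t
(trunk lengths, burst metrics; Welch available), two-sample
Kolmogorov-Smirnov (maximum-ADP distributions), globally optimal 1-D
two-group clustering (cfADP classification), and ordinary least squares
with an F-test (length vs ADP relationship).

Standard tests are delegated to scipy.stats; the 1-D two-cluster split is
solved exactly by exhaustive search over the n-1 sorted-order thresholds
(for one dimension this finds the global k-means optimum, unlike Lloyd
iterations which depend on initialization).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "CohortTable",
    "TestResult",
    "fisher_exact_2x2",
    "two_sample_t",
    "ks_two_sample",
    "split_two_groups_1d",
    "linear_fit_ftest",
]

AREA_LABELS = ("V1", "V2m")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 non-negative integer counts (group x outcome)."""

    counts: tuple

    def __post_init__(self):
        a = np.asarray(self.counts)
        if a.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if a.sum() == 0:
            raise ValueError("at least one entry must be positive")
        object.__setattr__(
            self, "counts", tuple(tuple(int(x) for x in row) for row in a)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)
    inputs_digest: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:12]


class CohortTable:
    """Per-neuron records for the two-population analysis.

    Thin wrapper over a pandas DataFrame with columns ``cell_id``, ``area``
    (V1/V2m), ``trunk_length_um`` (optional NaN), ``max_adp_integral``,
    optional burst metrics, and provenance metadata in ``.meta``.
    """

    REQUIRED = ("cell_id", "area", "max_adp_integral")

    def __init__(self, frame, meta: dict | None = None):
        import pandas as pd

        self.frame = pd.DataFrame(frame)
        self.meta = dict(meta or {})
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        bad = set(self.frame["area"].unique()) - set(AREA_LABELS)
        if bad:
            raise ValueError(f"unknown area labels: {sorted(bad)}")

    def by_area(self, column: str) -> dict[str, np.ndarray]:
        out = {}
        for area in AREA_LABELS:
            vals = self.frame.loc[self.frame["area"] == area, column]
            out[area] = vals.dropna().to_numpy(dtype=float)
        return out

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        return cls(pd.read_csv(path))


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test (sum of tables with probability <=
    the observed one, the convention of common statistical software)."""
    a = table.array
    if np.any(a.sum(axis=0) == 0) or np.any(a.sum(axis=1) == 0):
        return TestResult("fisher_exact", np.nan, 1.0,
                          {"warning": "empty margin"}, _digest(a))
    odds, p = sps.fisher_exact(a, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p),
                      {"table": table.counts}, _digest(a))


def two_sample_t(
    sample_a=None,
    sample_b=None,
    summary_a: tuple | None = None,
    summary_b: tuple | None = None,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t test, raw-sample or summary-statistic ((mean, sd, n)).

    Pooled-variance Student by default; ``equal_var=False`` gives Welch.
    """
    if summary_a is not None:
        m1, s1, n1 = summary_a
        m2, s2, n2 = summary_b
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                        equal_var=equal_var)
        df = n1 + n2 - 2
        dig = _digest(np.array([m1, s1, n1, m2, s2, n2], float))
    else:
        x, y = np.asarray(sample_a, float), np.asarray(sample_b, float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need n >= 2 per group")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            # degenerate: no variance anywhere
            equal_means = np.isclose(x.mean(), y.mean())
            return TestResult("t_test", 0.0 if equal_means else np.inf,
                              1.0 if equal_means else 0.0,
                              {"degenerate": True}, _digest(x, y))
        t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        df = len(x) + len(y) - 2
        dig = _digest(x, y)
    return TestResult("t_test" if equal_var else "welch_t",
                      float(t), float(p), {"df": int(df)}, dig)


def ks_two_sample(sample_a, sample_b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b|,
    asymptotic p with the effective-n correction."""
    x, y = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need n >= 1 per group")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult("ks_2samp", float(res.statistic), float(res.pvalue),
                      {"D": float(res.statistic)}, _digest(x, y))


def split_two_groups_1d(values):
    """Globally optimal two-cluster split of 1-D data (exact k-means, k=2).

    Scans all n-1 thresholds in sorted order and minimizes the
    within-cluster sum of squares. Deterministic and seed-free. Returns
    ``(labels, boundary)`` where labels are 0 (low) / 1 (high) in the input
    order and boundary is the midpoint between the two clusters' facing
    extremes. All-equal input returns a single cluster (labels all 0,
    boundary None).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    order = np.argsort(v, kind="stable")
    s = v[order]
    if s[0] == s[-1]:
        return np.zeros(len(v), dtype=int), None

    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    n = len(s)
    best_cost, best_k = np.inf, None
    for k in range(1, n):  # low cluster = s[:k]
        if s[k - 1] == s[k]:
            continue  # equal values may not straddle the boundary
        c1 = csq[k - 1] - csum[k - 1] ** 2 / k
        c2 = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = c1 + c2
        if cost < best_cost:
            best_cost, best_k = cost, k
    labels = np.zeros(n, dtype=int)
    labels[order[best_k:]] = 1
    boundary = 0.5 * (s[best_k - 1] + s[best_k])
    return labels, float(boundary)


def linear_fit_ftest(x, y) -> TestResult:
    """OLS fit of y on x with the regression F test.

    F = (n-2) r² / (1-r²) on (1, n-2) degrees of freedom; the two-sided p
    is the upper tail of that F distribution (equivalently, the slope's t
    test p-value).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    n = len(x)
    if np.std(y) == 0:
        return TestResult("linear_fit_f", 0.0, 1.0,
                          {"slope": 0.0, "intercept": float(y[0]),
                           "r2": 0.0, "df": n - 2}, _digest(x, y))
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    if r2 >= 1.0:
        f, p = np.inf, 0.0
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(sps.f.sf(f, 1, n - 2))
    return TestResult("linear_fit_f", float(f), p,
                      {"slope": float(res.slope),
                       "intercept": float(res.intercept),
                       "r2": float(r2), "df": n - 2},
                      _digest(x, y))
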