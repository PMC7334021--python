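"""Brute-force oracles shared by the statistics and acceptance tests."""

import numpy as np
from scipy.special import comb


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def ks_d_oracle(x, y):
    """sup |ECDF_x - ECDF_y| by evaluating at every data point."""
    pts = np.concatenate([x, y])
    d = 0.0
    for p in pts:
        d = max(d, abs(np.mean(x <= p) - np.mean(y <= p)))
    return d
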