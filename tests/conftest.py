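from fractions import Fraction
from math import comb

import numpy as np
import pytest

from psmeta import published_clade_table


@pytest.fixture(scope="session")
def published_table():
    """Published 7-gene x 3-clade matrix of branch-level p-values."""
    return published_clade_table()


# Published "Combined" column: Fisher combination of each row's clade-level
# p-values (NA and exact-1.0 entries excluded), printed at 3 s.f.
PUBLISHED_COMBINED = {
    "MTERF1": 3.12e-05,
    "RARS2": 2.52e-04,
    "MRPL30": 2.28e-03,
    "FASTKD2": 3.16e-04,
    "FASTKD5": 8.89e-03,
    "TFB2M": 2.73e-03,
    "NDUFA9": 4.85e-03,
}


def bh_oracle(p):
    """Textbook BH step-up, computed naively: adj_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(
            min(p[order[j]] * n / (j + 1) for j in range(i, n)), 1.0
        )
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Big-rational inclusive upper tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    denom = comb(N, n)
    upper = min(K, n)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), upper + 1))
    return Fraction(total, denom)


def hypergeom_pmf_exact(N: int, K: int, n: int) -> dict[int, Fraction]:
    denom = comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    return {i: Fraction(comb(K, i) * comb(N - K, n - i), denom) for i in range(lo, hi + 1)}
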