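"""Shared fixtures and independent test oracles.

The oracles here are deliberately written from first principles
(recursive edit distance, comb-based hypergeometric enumeration) so the
package implementations are checked against an independent route.
"""

from __future__ import annotations

import math
from functools import lru_cache

import pytest

from tcrep.simulate import CohortConfig, generate_cohort


def lev_oracle(a: str, b: str) -> int:
    """Exhaustive memoised edit-script recursion (independent of the
    package's iterative DP)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration with math.comb."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values()
                        if p <= p_obs * (1 + 1e-9)))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused across fast unit tests."""
    return generate_cohort(CohortConfig(
        seed=11, clones_per_patient=60, total_templates=180,
        reference_repertoire_size=3000, n_reference_records=200))


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return small_cohort.labels()
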