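"""Shared fixtures and brute-force statistical oracles.

The oracles enumerate the exact null distributions directly (hypergeometric
tables, binomial tails, Mann-Whitney labelings) and are kept independent of
the library code paths they are used to check.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

import casteseq as cs


# -- enumeration oracles -------------------------------------------------------


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums the hypergeometric probability of every table whose probability is
    at most that of the observed table (minimum-likelihood convention).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-9))


def binomial_tail_oracle(k: int, n: int) -> float:
    """One-sided P(X >= k) for X ~ Binomial(n, 1/2), by direct summation."""
    return sum(comb(n, j) for j in range(k, n + 1)) / 2**n


def mannwhitney_two_sided_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all labelings.

    Requires tie-free data.  Doubles the smaller tail of the exact U
    distribution (observed value included in both tails), capped at 1.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in idx)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


# -- fixtures ------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_design() -> cs.SimDesign:
    """A reduced copy of the default study design (fast to simulate)."""
    return cs.SimDesign(
        n_features=600,
        depth_range=(90_000, 110_000),
        de_spec={
            "mid": (cs.DEBlock(20, "Q"), cs.DEBlock(30, "W")),
            "late": (cs.DEBlock(12, "Q"), cs.DEBlock(5, "W")),
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_design):
    return cs.simulate_counts(small_design)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    matrix, _ = small_sim
    return cs.subsample_normalize(matrix, seed=7)


@pytest.fixture()
def tiny_matrix():
    """A hand-sized normalized matrix: 3 features, mid stage, 3 Q + 3 W reps."""
    samples = ["MQ1", "MQ2", "MQ3", "MW1", "MW2", "MW3"]
    counts = pd.DataFrame(
        {
            "MQ1": [10, 10, 5],
            "MQ2": [12, 20, 5],
            "MQ3": [15, 15, 5],
            "MW1": [16, 15, 5],
            "MW2": [18, 25, 5],
            "MW3": [20, 18, 5],
        },
        index=pd.Index(["gA", "gB", "gC"], name="feature_id"),
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "stage": "mid",
            "caste": ["Q"] * 3 + ["W"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    ).set_index("sample_id")
    return cs.CountMatrix(counts=counts, metadata=meta, normalized=True)
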