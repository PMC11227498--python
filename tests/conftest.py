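import math

import numpy as np
import pytest

from ihcsub.cohort import build_fixture_cohort
from ihcsub.synthdata import CohortSimConfig, generate_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic 190-case cohort matching the printed tables."""
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def default_synthetic_cohort():
    """Default-config synthetic cohort at the default seed."""
    return generate_cohort(CohortSimConfig())


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def enumerate_tables(row_sums, col_sums):
    """Yield every non-negative integer matrix with the given margins."""
    rows = list(row_sums)
    cols = list(col_sums)

    def rec(i, colrem, acc):
        if i == len(rows) - 1:
            if all(v >= 0 for v in colrem) and sum(colrem) == rows[i]:
                yield acc + [list(colrem)]
            return
        for comp in compositions(rows[i], colrem):
            newrem = [c - v for c, v in zip(colrem, comp)]
            yield from rec(i + 1, newrem, acc + [comp])

    yield from rec(0, cols, [])


def compositions(total, caps):
    """All splits of `total` over len(caps) cells with per-cell caps."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield [total]
        return
    for v in range(min(total, caps[0]) + 1):
        for rest in compositions(total - v, caps[1:]):
            yield [v] + rest


def table_prob(cells, row_sums, col_sums, n):
    num = 1.0
    for s in row_sums:
        num *= math.factorial(s)
    for s in col_sums:
        num *= math.factorial(s)
    den = math.factorial(n)
    for row in cells:
        for v in row:
            den *= math.factorial(v)
    return num / den


def freeman_halton_oracle(counts):
    """Exhaustive Freeman-Halton p by naive enumeration (small n only)."""
    counts = [list(map(int, row)) for row in np.asarray(counts)]
    row_sums = [sum(r) for r in counts]
    col_sums = [sum(c) for c in zip(*counts)]
    n = sum(row_sums)
    p_obs = table_prob(counts, row_sums, col_sums, n)
    total = 0.0
    for cells in enumerate_tables(row_sums, col_sums):
        p = table_prob(cells, row_sums, col_sums, n)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def ward_greedy_oracle(points):
    """Greedy dESS agglomeration by explicit ESS recomputation.

    Same tie-break as the implementation: lexicographically smallest
    (min leaf index, max leaf index) pair of cluster representatives.
    Returns the merge sequence as (rep_a, rep_b, height) triples.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]

    def ess(idx):
        sub = x[list(idx)]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(x))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                delta = ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
                ra, rb = min(clusters[a]), min(clusters[b])
                key = (delta, min(ra, rb), max(ra, rb))
                if best is None or key < (best[0], best[1], best[2]):
                    best = (delta, min(ra, rb), max(ra, rb), a, b)
        delta, ra, rb, a, b = best
        merges.append((ra, rb, delta))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
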