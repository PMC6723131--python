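"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from kernblup import SimConfig
from kernblup.simulate import simulate_dataset


def random_pedigree(rng, n_founders=12, n_extra=38, max_gen=4):
    """Random acyclic pedigree: founders then matings among earlier individuals.

    Returns a topologically sorted list of (id, sire, dam) with ≥3
    generations (later individuals can pick recent parents).
    """
    records = [(f"F{i}", None, None) for i in range(n_founders)]
    for k in range(n_extra):
        hi = len(records)
        s, d = rng.choice(hi, size=2, replace=False)
        # occasionally a single known parent
        dam = records[d][0] if rng.random() > 0.1 else None
        records.append((f"X{k}", records[s][0], dam))
    return records


def kinship_oracle(records):
    """Naive recursive computation of the numerator relationship matrix.

    Independent of the tabular implementation: a(i,j) computed top-down by
    recursive descent on the later-positioned argument, memoized.
    """
    pos = {r[0]: k for k, r in enumerate(records)}
    parents = {r[0]: (r[1], r[2]) for r in records}
    memo = {}

    def a(x, y):
        if x is None or y is None:
            return 0.0
        if pos[x] > pos[y]:
            x, y = y, x
        key = (x, y)
        if key in memo:
            return memo[key]
        sy, dy = parents[y]
        if x == y:
            val = 1.0 + 0.5 * a(sy, dy)
        else:
            val = 0.5 * (a(x, sy) + a(x, dy))
        memo[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        n = len(records)
        ids = [r[0] for r in records]
        M = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                M[i, j] = M[j, i] = a(ids[i], ids[j])
    finally:
        sys.setrecursionlimit(old)
    return M


@pytest.fixture(scope="session")
def small_dataset():
    """~250-line, 4-year dataset with pedigree+genomic+interaction signal."""
    cfg = SimConfig(
        seed=11,
        n_founders=40,
        n_families=50,
        p_markers=200,
        variance_fractions={"E": 0.30, "A": 0.25, "G": 0.15, "AE": 0.10, "Res": 0.20},
    )
    ped, markers, pheno, truth = simulate_dataset(cfg)
    return cfg, ped, markers, pheno, truth
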