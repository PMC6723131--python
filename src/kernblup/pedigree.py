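"""Pedigree records and the numerator relationship matrix A.

``A[i, j]`` is twice the kinship coefficient: the expected additive genetic
relationship between individuals i and j implied by the pedigree.  It is the
covariance structure of the additive line effect a_j ~ N(0, A σ²_a).  We use
the tabular (Wright/Henderson) recursion, processing individuals in an order
where parents precede offspring:

    a(i, j) = 0.5 * (a(j, sire_i) + a(j, dam_i))      for j before i
    a(i, i) = 1 + 0.5 * a(sire_i, dam_i)              (inbreeding 1 + F_i)

with missing-parent terms set to 0.  Inbreeding is accumulated, not assumed
away — selfed or line-bred records raise the diagonal above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import Kernel

__all__ = ["PedigreeTable", "topo_sort_pedigree", "build_A"]

#: tokens in pedigree files that denote an unknown parent
UNKNOWN_TOKENS = {"", "0", "NA", "na", None}


def _norm_parent(p):
    return None if p in UNKNOWN_TOKENS else p


@dataclass
class PedigreeTable:
    """Ordered pedigree records ``(id, sire, dam)`` with ``None`` = unknown.

    A founder is any individual with both parents unknown.  ``generation_depth``
    is informational metadata (depth of recorded ancestry), not used by the
    algorithms.
    """

    records: list
    generation_depth: int | None = None

    def __post_init__(self):
        self.records = [
            (i, _norm_parent(s), _norm_parent(d)) for (i, s, d) in self.records
        ]
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pedigree ids: {dup[:5]}")

    @property
    def ids(self) -> list:
        return [r[0] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def is_sorted(self) -> bool:
        """True if every known parent appears before its offspring."""
        seen = set()
        for i, s, d in self.records:
            for p in (s, d):
                if p is not None and p not in seen:
                    return False
            seen.add(i)
        return True


def topo_sort_pedigree(
    ped: PedigreeTable, auto_insert_founders: bool = False
) -> PedigreeTable:
    """Reorder records so parents precede offspring (stable Kahn's algorithm).

    Ties keep input order.  Parents that never appear as an individual raise
    an error, unless ``auto_insert_founders`` is set, in which case they are
    prepended as founders (in first-reference order).
    """
    records = list(ped.records)
    known = {r[0] for r in records}
    undefined: dict = {}
    for i, s, d in records:
        for p in (s, d):
            if p is not None and p not in known:
                undefined.setdefault(p, None)
    if undefined:
        if not auto_insert_founders:
            raise ValueError(
                f"parent id(s) never defined as individuals: "
                f"{list(undefined)[:5]} (set auto_insert_founders to add them)"
            )
        records = [(p, None, None) for p in undefined] + records
        known |= set(undefined)

    pos = {r[0]: k for k, r in enumerate(records)}
    parents = {r[0]: tuple(p for p in r[1:] if p is not None) for r in records}
    indeg = {i: sum(1 for _ in ps) for i, ps in parents.items()}
    children: dict = {i: [] for i in known}
    for i, ps in parents.items():
        for p in ps:
            children[p].append(i)

    import heapq

    ready = [pos[i] for i, dg in indeg.items() if dg == 0]
    heapq.heapify(ready)
    out = []
    placed = set()
    while ready:
        k = heapq.heappop(ready)
        rec = records[k]
        out.append(rec)
        placed.add(rec[0])
        for c in children[rec[0]]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, pos[c])
    if len(out) != len(records):
        # at least one cycle: walk parent links among leftovers to name one member
        leftover = next(i for i, _, _ in records if i not in placed)
        seen_walk = []
        cur = leftover
        while cur not in seen_walk:
            seen_walk.append(cur)
            cur = next(p for p in parents[cur] if p not in placed)
        raise ValueError(f"pedigree cycle detected involving {cur!r}")
    return PedigreeTable(out, generation_depth=ped.generation_depth)


def build_A(ped: PedigreeTable) -> Kernel:
    """Numerator relationship matrix by the tabular method.

    Requires a topologically sorted pedigree (raises otherwise — call
    :func:`topo_sort_pedigree` first).  Founders get a(i,i) = 1; an individual
    with related parents gets a(i,i) = 1 + F_i with F_i = 0.5·a(sire, dam);
    a single known parent contributes only its own recursion term.
    """
    if not ped.is_sorted():
        raise ValueError("pedigree is not sorted; run topo_sort_pedigree first")
    n = len(ped)
    idx = {i: k for k, (i, _, _) in enumerate(ped.records)}
    A = np.zeros((n, n))
    for k, (ind, s, d) in enumerate(ped.records):
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        if k > 0:
            row = np.zeros(k)
            if si is not None:
                row += 0.5 * A[si, :k]
            if di is not None:
                row += 0.5 * A[di, :k]
            A[k, :k] = row
            A[:k, k] = row
        inb = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[k, k] = 1.0 + inb
    return Kernel(name="A", entity_ids=ped.ids, matrix=A)
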