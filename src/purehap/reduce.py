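"""Polynomial-time model-size reduction for the class representative ILP.

The class index set has structure that lets many variables be dropped or
fixed before the ILP is built, without changing the optimal value:

* *conflict removals* — genotype p can never share a haplotype with the
  representative of class q when, at some SNP, one of them is certainly
  homozygous wild-type (0) and the other certainly homozygous mutant (2):
  no correction can reconcile a shared site value there.  Both the primary
  class and its dummy companion are removed.  A masked cell on either side
  voids the certainty, so the reduction is mask-aware.
* *pair cuts* — when genotype p is certainly heterozygous at SNP j while
  two candidate classes' representatives both certainly force site j to
  the same value, p cannot belong to both classes at once (the two class
  sites could not sum to 1).
* *site fixing* — a class site is fixed to 0 (or 1) when its
  representative's entry at that SNP is a certain 0 (or 2), since the
  representative belongs to every class it represents.

All three are sound: they only forbid assignments that violate the
haplotype sum operator, so the optimum is preserved (tested against the
exhaustive oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .datamodel import ErrorMask, GenotypeMatrix


@dataclass(frozen=True)
class ReductionPlan:
    """Variables to drop or fix before building the ILP.

    ``removed_memberships`` holds (genotype p, class q) pairs never
    instantiated; ``pair_cuts`` holds (p, q, q') triples forbidding joint
    membership; ``fixed_sites`` maps (class q, SNP j) to a forced site
    value.  Classes are 0-based: q < n primary, q >= n the dummy companion
    of q - n.  A genotype's own representative classes are never removed.
    """

    removed_memberships: frozenset[tuple[int, int]] = frozenset()
    pair_cuts: frozenset[tuple[int, int, int]] = frozenset()
    fixed_sites: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def is_removed(self, p: int, q: int) -> bool:
        return (p, q) in self.removed_memberships


def certain_conflict(
    p_row: Sequence[int],
    q_row: Sequence[int],
    mask_p: Sequence[int],
    mask_q: Sequence[int],
    j: int,
) -> bool:
    """True iff genotypes p and q certainly cannot share a haplotype
    because of SNP j: entries {0, 2} with both cells unmasked."""
    if len(p_row) != len(q_row):
        raise ValueError("rows must have equal length")
    if mask_p[j] or mask_q[j]:
        return False
    return {int(p_row[j]), int(q_row[j])} == {0, 2}


def _has_conflict(p_row, q_row, mask_p, mask_q) -> bool:
    for j in range(len(p_row)):
        if certain_conflict(p_row, q_row, mask_p, mask_q, j):
            return True
    return False


def compute_reduction_plan(G: GenotypeMatrix, M: ErrorMask | None = None) -> ReductionPlan:
    """Derive the full reduction plan for an instance in O(n^2 m + n m c^2)
    time (c = candidate classes per genotype); no exponential enumeration."""
    g = np.asarray(G.entries)
    n, m = g.shape
    mask = np.zeros((n, m), dtype=np.int8) if M is None else np.asarray(M.entries)

    removed: set[tuple[int, int]] = set()
    for p in range(n):
        for r in range(p):
            if _has_conflict(g[p], g[r], mask[p], mask[r]):
                removed.add((p, r))
                removed.add((p, n + r))

    fixed: dict[tuple[int, int], int] = {}
    for r in range(n):
        for j in range(m):
            if mask[r, j]:
                continue
            if g[r, j] == 0:
                fixed[(r, j)] = 0
                fixed[(n + r, j)] = 0
            elif g[r, j] == 2:
                fixed[(r, j)] = 1
                fixed[(n + r, j)] = 1

    cuts: set[tuple[int, int, int]] = set()
    for p in range(n):
        candidates = [
            q for q in list(range(p + 1)) + list(range(n, n + p + 1)) if (p, q) not in removed
        ]
        for j in range(m):
            if g[p, j] != 1 or mask[p, j]:
                continue
            for value in (0, 1):
                forced = [q for q in candidates if fixed.get((q, j)) == value]
                for qa, qb in combinations(forced, 2):
                    cuts.add((p, qa, qb))

    return ReductionPlan(
        removed_memberships=frozenset(removed),
        pair_cuts=frozenset(cuts),
        fixed_sites=fixed,
    )
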