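"""Exhaustive exact solver for tiny instances: the ground truth the ILP is
tested against.

The oracle enumerates, per masked cell, "no correction" plus each allowed
delta; keeps correction profiles whose count lies in [L, U]; and for each
corrected matrix searches the Cartesian product of every genotype's
resolving pairs for the smallest set of distinct haplotypes.  A corrected
row that became degenerate is resolved only by its doubled haplotype
h + h (which counts once toward the objective).  The search is a depth
first walk over genotypes ordered by fewest resolving pairs; the optional
bound (``prune=True``) abandons a branch once the haplotypes already
committed reach the best complete solution found, which never changes the
optimum.  The enumeration works directly on resolving pairs, independent
of the class representative encoding it certifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .datamodel import (
    Correction,
    ErrorMask,
    GenotypeMatrix,
    Haplotype,
    PhasingSolution,
    allowed_corrections,
    doubled_resolution,
    enumerate_resolving_pairs,
    is_degenerate,
)

MAX_N = 6
MAX_M = 8


class OracleLimitError(ValueError):
    """Raised when an instance exceeds the exhaustive-search guardrail."""


@dataclass
class OracleResult:
    optimum: int
    witness: PhasingSolution
    explored: int


def oracle_solve(
    G: GenotypeMatrix | np.ndarray,
    M: ErrorMask | np.ndarray | None = None,
    L: int = 0,
    U: int | None = None,
    prune: bool = True,
    max_n: int = MAX_N,
    max_m: int = MAX_M,
) -> OracleResult:
    """Exact minimum distinct-haplotype count by brute force."""
    g = np.asarray(G.entries if isinstance(G, GenotypeMatrix) else G)
    n, m = g.shape
    if n > max_n or m > max_m:
        raise OracleLimitError(
            f"instance {n}x{m} exceeds the oracle guardrail {max_n}x{max_m}"
        )
    mask = (
        np.zeros((n, m), dtype=np.int8)
        if M is None
        else np.asarray(M.entries if isinstance(M, ErrorMask) else M)
    )
    cells = [(p, j) for p in range(n) for j in range(m) if mask[p, j]]
    if U is None:
        U = len(cells)
    if not 0 <= L <= U:
        raise ValueError(f"correction bounds must satisfy 0 <= L <= U, got L={L}, U={U}")

    best_count = 2 * n + 1
    best_haps: list[Haplotype] | None = None
    best_assign: list[tuple[Haplotype, Haplotype]] | None = None
    best_profile: tuple[int, ...] | None = None
    explored = 0

    cell_options = [(None, *sorted(allowed_corrections(int(g[p, j])))) for p, j in cells]
    for profile in product(*cell_options) if cells else [()]:
        applied = [d for d in profile if d is not None]
        if not L <= len(applied) <= U:
            continue
        corrected = g.copy()
        for (p, j), d in zip(cells, profile):
            if d is not None:
                corrected[p, j] += d
        row_options: list[list[tuple[Haplotype, Haplotype]]] = []
        for p in range(n):
            row = corrected[p]
            if is_degenerate(row):
                h = doubled_resolution(row)
                row_options.append([(h, h)])
            else:
                row_options.append(sorted(enumerate_resolving_pairs(row)))
        order = sorted(range(n), key=lambda p: len(row_options[p]))

        def dfs(idx: int, used: set[Haplotype], chosen: dict[int, tuple[Haplotype, Haplotype]]):
            nonlocal best_count, best_haps, best_assign, best_profile, explored
            if prune and len(used) >= best_count:
                return
            if idx == n:
                explored += 1
                if len(used) < best_count:
                    best_count = len(used)
                    best_haps = sorted(used)
                    best_assign = [chosen[p] for p in range(n)]
                    best_profile = profile
                return
            p = order[idx]
            for ha, hb in row_options[p]:
                added = [h for h in (ha, hb) if h not in used]
                used.update(added)
                chosen[p] = (ha, hb)
                dfs(idx + 1, used, chosen)
                del chosen[p]
                for h in set(added):
                    used.discard(h)

        dfs(0, set(), {})

    assert best_haps is not None and best_assign is not None and best_profile is not None
    hap_index = {h: i for i, h in enumerate(best_haps)}
    assignment = [
        tuple(sorted((hap_index[ha], hap_index[hb]))) for ha, hb in best_assign
    ]
    corrections = [
        Correction(
            genotype_index=p + 1,
            snp_index=j + 1,
            delta=d,
            corrected_value=int(g[p, j]) + d,
        )
        for (p, j), d in zip(cells, best_profile)
        if d is not None
    ]
    witness = PhasingSolution(
        haplotypes=list(best_haps),
        assignment=assignment,  # type: ignore[arg-type]
        corrections=corrections,
        objective=best_count,
    )
    return OracleResult(optimum=best_count, witness=witness, explored=explored)
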