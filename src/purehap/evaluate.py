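"""Solution verification and the haplotype-set recovery accuracy measure.

Accuracy compares the haplotype set inferred under uncertainty against
the set inferred from the same clean data: the fraction of reference
haplotypes recovered exactly, ``|reference & estimated| / |reference|``.
A ratio of 1 means the uncertain-data solve recovered the full clean-data
set; under alternate optima the ratio is solver-dependent, so experiments
fix the backend and report rather than assert per-instance values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crm_ilp import solve_pph
from .datamodel import (
    ErrorMask,
    GenotypeMatrix,
    Haplotype,
    PhasingSolution,
    allowed_corrections,
    apply_corrections,
)
from .simulate import SimulationConfig, generate_genotypes, generate_haplotype_pool, generate_mask

logger = logging.getLogger(__name__)


def verify_solution(
    G: GenotypeMatrix | np.ndarray,
    M: ErrorMask | np.ndarray | None,
    L: int,
    U: int | None,
    sol: PhasingSolution,
) -> list[str]:
    """Check a phasing against an instance; returns violations (empty = valid)."""
    g = np.asarray(G.entries if isinstance(G, GenotypeMatrix) else G)
    n, m = g.shape
    mask = (
        np.zeros((n, m), dtype=np.int8)
        if M is None
        else np.asarray(M.entries if isinstance(M, ErrorMask) else M)
    )
    if U is None:
        U = int(mask.sum())
    violations: list[str] = []

    if len(set(sol.haplotypes)) != len(sol.haplotypes):
        violations.append("listed haplotypes are not pairwise distinct")
    for i, h in enumerate(sol.haplotypes):
        if len(h) != m or any(b not in (0, 1) for b in h):
            violations.append(f"haplotype {i + 1} is not a binary vector of length {m}")
    if sol.objective != len(sol.haplotypes):
        violations.append(
            f"objective {sol.objective} != {len(sol.haplotypes)} listed haplotypes"
        )
    if len(sol.assignment) != n:
        violations.append(f"assignment covers {len(sol.assignment)} of {n} genotypes")

    seen_cells: set[tuple[int, int]] = set()
    for c in sol.corrections:
        p, j = c.genotype_index - 1, c.snp_index - 1
        if not (0 <= p < n and 0 <= j < m):
            violations.append(f"correction at out-of-range cell ({c.genotype_index},{c.snp_index})")
            continue
        if not mask[p, j]:
            violations.append(f"correction at unmasked cell ({c.genotype_index},{c.snp_index})")
        if (p, j) in seen_cells:
            violations.append(f"two corrections at cell ({c.genotype_index},{c.snp_index})")
        seen_cells.add((p, j))
        if c.delta not in allowed_corrections(int(g[p, j])):
            violations.append(
                f"delta {c.delta:+d} not allowed for entry {int(g[p, j])} "
                f"at ({c.genotype_index},{c.snp_index})"
            )
        elif c.corrected_value != int(g[p, j]) + c.delta:
            violations.append(
                f"corrected value mismatch at ({c.genotype_index},{c.snp_index})"
            )
    if not L <= len(sol.corrections) <= U:
        violations.append(
            f"correction count {len(sol.corrections)} outside bounds [{L},{U}]"
        )
    if violations:
        return violations

    corrected = apply_corrections(g, mask, sol.corrections)
    for p, (a, b) in enumerate(sol.assignment):
        if not (0 <= a < len(sol.haplotypes) and 0 <= b < len(sol.haplotypes)):
            violations.append(f"genotype {p + 1} references a missing haplotype")
            continue
        ha, hb = sol.haplotypes[a], sol.haplotypes[b]
        if any(int(v) != x + y for v, x, y in zip(corrected[p], ha, hb)):
            violations.append(f"genotype {p + 1}: assigned pair does not sum to its corrected row")
    return violations


def accuracy(reference: Iterable[Haplotype], estimated: Iterable[Haplotype]) -> float:
    """Fraction of reference haplotypes recovered exactly."""
    ref = {tuple(int(b) for b in h) for h in reference}
    est = {tuple(int(b) for b in h) for h in estimated}
    if not ref:
        raise ValueError("reference haplotype set is empty")
    return len(ref & est) / len(ref)


@dataclass
class ReplicateRecord:
    replicate: int
    error_ratio: float
    reference_count: int
    shared_count: int
    accuracy: float
    pph_objective: int
    pphud_objective: int


def accuracy_experiment(
    config: SimulationConfig,
    ratios: Sequence[float],
    replicates: int,
    seed: int,
    backend: str = "highs",
    time_limit: float | None = None,
) -> pd.DataFrame:
    """Recovery experiment: per replicate, phase the clean instance (the
    reference set), then re-phase under masks of increasing density and
    score the recovered fraction.  Returns one row per error ratio with
    mean/max/min accuracy in percent.  Replicates hitting the solver time
    limit are recorded and excluded from the aggregates with a warning.
    """
    records: list[ReplicateRecord] = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        sub = child.spawn(2 + len(ratios))
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in sub]
        pool = generate_haplotype_pool(config.pool_size, config.m, seeds[0])
        genotypes = generate_genotypes(
            pool, config.n, mode=config.mode,
            concentration=config.concentration, seed=seeds[1],
        )
        clean = solve_pph(
            genotypes, None, backend=backend, time_limit=time_limit,
        )
        if clean.status != "optimal" or clean.solution is None:
            warnings.warn(f"replicate {rep}: clean-data solve ended {clean.status}; excluded")
            continue
        reference = set(clean.solution.haplotypes)
        for ratio, mask_seed in zip(ratios, seeds[2:]):
            mask = generate_mask(genotypes.n, genotypes.m, ratio, mask_seed)
            uncertain = solve_pph(
                genotypes, mask, backend=backend, time_limit=time_limit,
            )
            if uncertain.status != "optimal" or uncertain.solution is None:
                warnings.warn(
                    f"replicate {rep} ratio {ratio}: solve ended {uncertain.status}; excluded"
                )
                continue
            estimated = set(uncertain.solution.haplotypes)
            records.append(
                ReplicateRecord(
                    replicate=rep,
                    error_ratio=ratio,
                    reference_count=len(reference),
                    shared_count=len(reference & estimated),
                    accuracy=accuracy(reference, estimated),
                    pph_objective=clean.objective,
                    pphud_objective=uncertain.objective,
                )
            )
        logger.info("replicate %d done (reference set of %d)", rep, len(reference))

    frame = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for ratio in ratios:
        sub = frame[frame.error_ratio == ratio] if not frame.empty else frame
        if sub.empty:
            rows.append({"error_ratio": ratio, "mean": np.nan, "max": np.nan, "min": np.nan, "replicates": 0})
        else:
            pct = sub.accuracy * 100.0
            rows.append(
                {
                    "error_ratio": ratio,
                    "mean": float(pct.mean()),
                    "max": float(pct.max()),
                    "min": float(pct.min()),
                    "replicates": int(len(sub)),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["records"] = frame
    return table
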