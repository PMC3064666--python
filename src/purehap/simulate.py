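"""Synthetic benchmark instances: haplotype pools, genotype pairing, masks.

Emulates the classic phasing benchmark construction: a pool of distinct
haplotypes stands in for a coalescent sample; genotypes are componentwise
sums of randomly paired pool members, either with uniform parent
frequencies ("uniform" datasets) or with a skewed frequency vector drawn
once per run ("nonuniform" datasets).  Error masks mark an exact number of
uncertain entries, ``round(error_ratio * n * m)``, placed uniformly
without replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .datamodel import ErrorMask, GenotypeMatrix, Haplotype, validate_genotype_matrix

#: Error ratios used throughout the benchmark-style experiments.
STANDARD_ERROR_RATIOS = (0.01, 0.05, 0.10, 0.15)


class SimulationError(RuntimeError):
    """Raised when the generator cannot satisfy its contract."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults follow the smallest benchmark condition (50 genotypes of 10
    SNPs, uniform pairing) with a pool of 10 distinct haplotypes, kept
    below the genotype count as in low-recombination populations where the
    parsimony criterion is informative.  ``concentration`` is the symmetric
    Dirichlet parameter for nonuniform pool frequencies (smaller = more
    skewed); it is ignored in uniform mode.
    """

    pool_size: int = 10
    m: int = 10
    n: int = 50
    mode: Literal["uniform", "nonuniform"] = "uniform"
    concentration: float = 0.3
    error_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise SimulationError("pool_size must be >= 2")
        if self.m >= 1 and self.pool_size > 2**self.m:
            raise SimulationError(f"pool_size {self.pool_size} exceeds 2^m = {2**self.m}")
        if not 0.0 <= self.error_ratio <= 1.0:
            raise SimulationError("error_ratio must lie in [0, 1]")
        if self.mode not in ("uniform", "nonuniform"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.concentration <= 0:
            raise SimulationError("concentration must be positive")


def generate_haplotype_pool(pool_size: int, m: int, seed: int) -> list[Haplotype]:
    """``pool_size`` distinct binary haplotypes of length ``m``, i.i.d.
    uniform over distinct vectors; deterministic per seed."""
    if pool_size > 2**m:
        raise SimulationError(f"cannot draw {pool_size} distinct haplotypes of length {m}")
    rng = np.random.default_rng(seed)
    if m <= 24:
        # Uniform without replacement over all 2^m vectors: same law as
        # Bernoulli(0.5) rows with duplicate rejection, but always terminates.
        codes = rng.choice(2**m, size=pool_size, replace=False)
        pool = [tuple((int(c) >> (m - 1 - j)) & 1 for j in range(m)) for c in codes]
    else:
        seen: set[Haplotype] = set()
        pool = []
        while len(pool) < pool_size:
            h = tuple(int(b) for b in rng.integers(0, 2, size=m))
            if h not in seen:
                seen.add(h)
                pool.append(h)
    return pool


def generate_genotypes(
    pool: Sequence[Haplotype],
    n: int,
    mode: str = "uniform",
    concentration: float = 0.3,
    seed: int = 0,
    max_retries_per_row: int = 1000,
) -> GenotypeMatrix:
    """Pair pool haplotypes into ``n`` distinct non-degenerate genotypes.

    Uniform mode draws both parents uniformly from the pool; nonuniform
    mode draws them from a frequency vector sampled once per run from a
    symmetric Dirichlet(concentration).  Degenerate rows (equal parents at
    every heterozygous-capable site) and duplicate rows are rejected and
    resampled within a bounded retry budget.
    """
    pool = [tuple(int(b) for b in h) for h in pool]
    if len(set(pool)) != len(pool):
        raise SimulationError("pool haplotypes must be distinct")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        weights = np.full(len(pool), 1.0 / len(pool))
    elif mode == "nonuniform":
        weights = rng.dirichlet(np.full(len(pool), float(concentration)))
    else:
        raise SimulationError(f"unknown mode {mode!r}")

    rows: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    budget = max_retries_per_row * n
    while len(rows) < n:
        if budget <= 0:
            raise SimulationError(
                f"could not generate {n} distinct non-degenerate genotypes "
                f"from a pool of {len(pool)} within the retry budget"
            )
        budget -= 1
        a, b = rng.choice(len(pool), size=2, p=weights)
        row = tuple(x + y for x, y in zip(pool[a], pool[b]))
        if 1 not in row or row in seen:
            continue
        seen.add(row)
        rows.append(row)
    return validate_genotype_matrix(np.array(rows, dtype=np.int8))


def generate_mask(n: int, m: int, error_ratio: float, seed: int) -> ErrorMask:
    """Exact-count mask: ``round(error_ratio * n * m)`` ones placed
    uniformly without replacement (round half up)."""
    if not 0.0 <= error_ratio <= 1.0:
        raise SimulationError("error_ratio must lie in [0, 1]")
    k = int(math.floor(error_ratio * n * m + 0.5))
    rng = np.random.default_rng(seed)
    flat = np.zeros(n * m, dtype=np.int8)
    if k:
        flat[rng.choice(n * m, size=k, replace=False)] = 1
    return ErrorMask(entries=flat.reshape(n, m))


def inject_errors(G: GenotypeMatrix | np.ndarray, M: ErrorMask | np.ndarray, seed: int) -> np.ndarray:
    """Corrupt each masked entry to a uniformly chosen *different* value in
    {0,1,2}; supports recovery experiments where masked data is truly wrong."""
    g = np.array(G.entries if isinstance(G, GenotypeMatrix) else G, dtype=np.int8)
    mask = np.asarray(M.entries if isinstance(M, ErrorMask) else M)
    if mask.shape != g.shape:
        raise SimulationError(f"mask shape {mask.shape} != genotype shape {g.shape}")
    rng = np.random.default_rng(seed)
    for p, j in zip(*np.nonzero(mask)):
        choices = [v for v in (0, 1, 2) if v != g[p, j]]
        g[p, j] = choices[rng.integers(0, len(choices))]
    return g


def generate_instance(config: SimulationConfig) -> tuple[GenotypeMatrix, ErrorMask, list[Haplotype]]:
    """One full instance per config: pool, genotypes, mask.  Sub-seeds are
    derived from ``config.seed`` so each stage is independently stable."""
    ss = np.random.SeedSequence(config.seed)
    s_pool, s_geno, s_mask = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    pool = generate_haplotype_pool(config.pool_size, config.m, s_pool)
    genotypes = generate_genotypes(
        pool, config.n, mode=config.mode, concentration=config.concentration, seed=s_geno
    )
    mask = generate_mask(genotypes.n, genotypes.m, config.error_ratio, s_mask)
    return genotypes, mask, pool
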