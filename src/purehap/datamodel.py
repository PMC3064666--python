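"""Core domain types and resolution semantics for pure parsimony haplotyping.

A *genotype* is a string over ``{0, 1, 2}``: 0 and 2 mark sites homozygous
for the wild-type and mutant allele respectively, 1 marks heterozygous
sites.  A *haplotype* is a binary string of the same length; an unordered
pair of haplotypes *resolves* a genotype when their componentwise sum
equals it.  A genotype with ``k`` heterozygous sites is resolved by exactly
``2**(k-1)`` distinct unordered pairs, and a *degenerate* genotype (no
heterozygous site) is excluded from the problem input.

Uncertain entries are marked by a binary *error mask*; a masked entry may
be corrected by a bounded integer delta before resolution (0 -> +1/+2,
2 -> -1/-2, 1 -> +1/-1), so that the corrected value is again in
``{0, 1, 2}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: A haplotype: immutable binary site vector, hashable for set arithmetic.
Haplotype = tuple[int, ...]

GENOTYPE_ALPHABET = frozenset({0, 1, 2})
MASK_ALPHABET = frozenset({0, 1})

#: Admissible corrections per original entry value (delta = 0 is the
#: always-available "no correction" and is never listed).
_ALLOWED_DELTAS = {0: frozenset({+1, +2}), 1: frozenset({+1, -1}), 2: frozenset({-1, -2})}


class InvalidGenotypeError(ValueError):
    """Raised when an input matrix violates the genotype alphabet or shape."""


class DegenerateGenotypeError(InvalidGenotypeError):
    """Raised for a genotype row without any heterozygous (1) entry."""


class InvalidCorrectionError(ValueError):
    """Raised when a correction targets an unmasked cell or uses a bad delta."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Validated n x m genotype matrix over {0,1,2}.

    ``kept_rows`` records which rows of the raw input survived duplicate
    removal, so that a mask supplied for the raw input can be aligned.
    """

    entries: np.ndarray
    kept_rows: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=np.int8))
        self.entries.setflags(write=False)
        if not self.kept_rows:
            object.__setattr__(self, "kept_rows", tuple(range(self.entries.shape[0])))

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])

    @property
    def m(self) -> int:
        return int(self.entries.shape[1])

    def row(self, p: int) -> np.ndarray:
        return self.entries[p]


@dataclass(frozen=True)
class ErrorMask:
    """Binary n x m matrix marking uncertain genotype entries (1 = uncertain)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=np.int8))
        self.entries.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])

    @property
    def m(self) -> int:
        return int(self.entries.shape[1])

    @property
    def num_masked(self) -> int:
        return int(self.entries.sum())

    def masked_cells(self) -> list[tuple[int, int]]:
        """0-based (row, column) positions of uncertain entries, row-major."""
        rows, cols = np.nonzero(self.entries)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class Correction:
    """A single applied correction at a masked cell (1-based indices)."""

    genotype_index: int
    snp_index: int
    delta: int
    corrected_value: int


@dataclass
class PhasingSolution:
    """A phasing: distinct haplotypes, one unordered pair per genotype,
    the corrections applied, and the distinct-haplotype objective.

    ``assignment[p]`` holds 0-based indices into ``haplotypes``; the two
    indices coincide when a (corrected) degenerate genotype is resolved by
    a doubled haplotype h + h.
    """

    haplotypes: list[Haplotype]
    assignment: list[tuple[int, int]]
    corrections: list[Correction]
    objective: int


def _as_int_matrix(raw) -> np.ndarray:
    arr = np.asarray(raw)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidGenotypeError(f"expected a non-empty 2-D matrix, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise InvalidGenotypeError("matrix entries must be integers")
        arr = arr.astype(np.int64)
    return arr


def validate_genotype_matrix(raw) -> GenotypeMatrix:
    """Validate a raw matrix as PPH input.

    Entries outside {0,1,2} and degenerate rows (no heterozygous site)
    raise; duplicate rows are dropped with a warning, since the class
    representative formulation presumes pairwise-distinct genotypes.
    """
    arr = _as_int_matrix(raw)
    bad = set(np.unique(arr)) - GENOTYPE_ALPHABET
    if bad:
        raise InvalidGenotypeError(f"genotype entries outside {{0,1,2}}: {sorted(bad)}")
    degenerate = np.nonzero(~(arr == 1).any(axis=1))[0]
    if degenerate.size:
        raise DegenerateGenotypeError(
            f"degenerate genotype (no heterozygous site) at row(s) {(degenerate + 1).tolist()}"
        )
    seen: dict[tuple, int] = {}
    kept: list[int] = []
    for i, row in enumerate(arr):
        key = tuple(int(v) for v in row)
        if key in seen:
            continue
        seen[key] = i
        kept.append(i)
    if len(kept) < arr.shape[0]:
        warnings.warn(
            f"removed {arr.shape[0] - len(kept)} duplicate genotype row(s)",
            UserWarning,
            stacklevel=2,
        )
    return GenotypeMatrix(entries=arr[kept].astype(np.int8), kept_rows=tuple(kept))


def validate_error_mask(raw, genotypes: GenotypeMatrix) -> ErrorMask:
    """Validate a raw binary mask against a validated genotype matrix.

    A mask with one row per *raw* genotype row is subset to the rows the
    genotype validation kept, so masks written alongside pre-dedup inputs
    stay aligned.
    """
    arr = _as_int_matrix(raw)
    bad = set(np.unique(arr)) - MASK_ALPHABET
    if bad:
        raise InvalidGenotypeError(f"mask entries outside {{0,1}}: {sorted(bad)}")
    if arr.shape[1] != genotypes.m:
        raise InvalidGenotypeError(
            f"mask has {arr.shape[1]} columns, genotypes have {genotypes.m}"
        )
    if arr.shape[0] == genotypes.n:
        pass
    elif arr.shape[0] > genotypes.n and arr.shape[0] > max(genotypes.kept_rows):
        arr = arr[list(genotypes.kept_rows)]
    else:
        raise InvalidGenotypeError(
            f"mask has {arr.shape[0]} rows, genotypes have {genotypes.n}"
        )
    return ErrorMask(entries=arr.astype(np.int8))


def is_degenerate(g: Sequence[int]) -> bool:
    """True when the genotype row has no heterozygous (1) entry."""
    return not any(int(v) == 1 for v in g)


def is_resolved(g: Sequence[int], ha: Sequence[int], hb: Sequence[int]) -> bool:
    """True iff g_j = ha_j + hb_j at every site."""
    if not (len(g) == len(ha) == len(hb)):
        raise ValueError("genotype and haplotypes must have equal length")
    return all(int(gj) == int(a) + int(b) for gj, a, b in zip(g, ha, hb))


def enumerate_resolving_pairs(g: Sequence[int]) -> set[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs whose sum is ``g``.

    Exactly ``2**(k-1)`` pairs for ``k`` heterozygous sites: both members
    are 0 where g=0 and 1 where g=2; at heterozygous sites the members are
    complementary, with the first such site fixed to break the pair order.
    """
    g = [int(v) for v in g]
    het = [j for j, v in enumerate(g) if v == 1]
    if not het:
        raise DegenerateGenotypeError("degenerate genotype has no resolving pair split")
    base = [0 if v == 0 else 1 if v == 2 else None for v in g]
    pairs: set[tuple[Haplotype, Haplotype]] = set()
    free = het[1:]
    for bits in range(1 << len(free)):
        ha = list(base)
        ha[het[0]] = 0
        for idx, j in enumerate(free):
            ha[j] = (bits >> idx) & 1
        hb = [gj - a for gj, a in zip(g, ha)]
        pair = tuple(sorted((tuple(ha), tuple(hb))))
        pairs.add(pair)  # type: ignore[arg-type]
    return pairs


def doubled_resolution(g: Sequence[int]) -> Haplotype:
    """The single haplotype h with h + h = g, for a degenerate row."""
    if not is_degenerate(g):
        raise ValueError("only a degenerate row is resolved by a doubled haplotype")
    return tuple(int(v) // 2 for v in g)


def allowed_corrections(entry: int) -> frozenset[int]:
    """Admissible deltas for a genotype entry (delta=0 is implicit)."""
    entry = int(entry)
    if entry not in _ALLOWED_DELTAS:
        raise InvalidGenotypeError(f"genotype entry {entry} outside {{0,1,2}}")
    return _ALLOWED_DELTAS[entry]


def apply_corrections(
    G: GenotypeMatrix | np.ndarray,
    M: ErrorMask | np.ndarray,
    corrections: Iterable[Correction],
) -> np.ndarray:
    """Return the corrected genotype matrix (the input is not modified).

    Each correction must target a masked cell, use a delta admissible for
    the original entry, and no cell may be corrected twice.  Corrected rows
    are allowed to become degenerate.
    """
    g = np.array(G.entries if isinstance(G, GenotypeMatrix) else G, dtype=np.int8)
    mask = np.asarray(M.entries if isinstance(M, ErrorMask) else M)
    if mask.shape != g.shape:
        raise InvalidGenotypeError(f"mask shape {mask.shape} != genotype shape {g.shape}")
    seen: set[tuple[int, int]] = set()
    for c in corrections:
        p, j = c.genotype_index - 1, c.snp_index - 1
        if not (0 <= p < g.shape[0] and 0 <= j < g.shape[1]):
            raise InvalidCorrectionError(f"correction position ({c.genotype_index},{c.snp_index}) out of range")
        if not mask[p, j]:
            raise InvalidCorrectionError(
                f"correction at unmasked cell ({c.genotype_index},{c.snp_index})"
            )
        if (p, j) in seen:
            raise InvalidCorrectionError(
                f"two corrections at cell ({c.genotype_index},{c.snp_index})"
            )
        seen.add((p, j))
        if c.delta not in allowed_corrections(int(g[p, j])):
            raise InvalidCorrectionError(
                f"delta {c.delta:+d} not allowed for entry {int(g[p, j])}"
            )
        new = int(g[p, j]) + c.delta
        if c.corrected_value != new:
            raise InvalidCorrectionError(
                f"corrected value {c.corrected_value} != {int(g[p, j])}{c.delta:+d}"
            )
        g[p, j] = new
    return g
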