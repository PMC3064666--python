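"""Plain-text serialization: matrix files and sectioned solution reports.

Matrix files carry no header; one row per non-blank line, symbols either
contiguous (``2112``) or whitespace-separated (``2 1 1 2``).  Solution
reports are line-oriented ASCII with labeled sections (see
:func:`write_solution` for the exact layout, which round-trips bytewise).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

from .datamodel import (
    Correction,
    GenotypeMatrix,
    ErrorMask,
    Haplotype,
    InvalidGenotypeError,
    PhasingSolution,
)

GENOTYPE_SYMBOLS = frozenset("012")
MASK_SYMBOLS = frozenset("01")
HAPLOTYPE_SYMBOLS = frozenset("01")


class SolutionFormatError(ValueError):
    """Raised for malformed solution-report files."""


def _open_source(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="ascii")
    return source


def _open_sink(sink) -> tuple[TextIO, bool]:
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="ascii"), True
    return sink, False


def read_matrix(source, alphabet: Iterable[str] = GENOTYPE_SYMBOLS) -> np.ndarray:
    """Parse a text matrix; rows must be equal length, symbols in ``alphabet``."""
    alphabet = frozenset(alphabet)
    fh = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            tokens = stripped.split() if any(ch.isspace() for ch in stripped) else list(stripped)
            for tok in tokens:
                if tok not in alphabet:
                    raise InvalidGenotypeError(
                        f"line {lineno}: symbol {tok!r} outside alphabet {sorted(alphabet)}"
                    )
            rows.append([int(tok) for tok in tokens])
    finally:
        if close:
            fh.close()
    if not rows:
        raise InvalidGenotypeError("empty matrix input")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise InvalidGenotypeError(f"ragged input: row {i + 1} has {len(row)} symbols, expected {width}")
    return np.array(rows, dtype=np.int8)


def write_matrix(matrix, sink) -> None:
    """Write a matrix in the contiguous-symbol dialect, one row per line."""
    arr = np.asarray(matrix)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidGenotypeError("cannot write an empty or non-2D matrix")
    fh, close = _open_sink(sink)
    try:
        for row in arr:
            fh.write("".join(str(int(v)) for v in row))
            fh.write("\n")
    finally:
        if close:
            fh.close()


def matrix_to_text(matrix) -> str:
    buf = io.StringIO()
    write_matrix(matrix, buf)
    return buf.getvalue()


def write_solution(sol: PhasingSolution, sink, *, n: int | None = None, m: int | None = None,
                   status: str = "optimal") -> None:
    """Write a sectioned ASCII solution report.

    Layout (bytewise stable)::

        PUREHAP SOLUTION 1
        n <genotypes> m <snps>
        objective <distinct haplotypes>
        corrections <count>
        status <status>
        HAPLOTYPES
        <one binary string per haplotype>
        ASSIGNMENT
        <genotype index> <haplotype index> <haplotype index>
        CORRECTIONS
        <genotype index> <snp index> <original value> <corrected value>
        END

    All indices are 1-based.
    """
    n = len(sol.assignment) if n is None else n
    m = len(sol.haplotypes[0]) if sol.haplotypes else (0 if m is None else m)
    fh, close = _open_sink(sink)
    try:
        fh.write("PUREHAP SOLUTION 1\n")
        fh.write(f"n {n} m {m}\n")
        fh.write(f"objective {sol.objective}\n")
        fh.write(f"corrections {len(sol.corrections)}\n")
        fh.write(f"status {status}\n")
        fh.write("HAPLOTYPES\n")
        for h in sol.haplotypes:
            fh.write("".join(str(int(b)) for b in h) + "\n")
        fh.write("ASSIGNMENT\n")
        for p, (a, b) in enumerate(sol.assignment, start=1):
            fh.write(f"{p} {a + 1} {b + 1}\n")
        fh.write("CORRECTIONS\n")
        for c in sol.corrections:
            original = c.corrected_value - c.delta
            fh.write(f"{c.genotype_index} {c.snp_index} {original} {c.corrected_value}\n")
        fh.write("END\n")
    finally:
        if close:
            fh.close()


def read_solution(source) -> PhasingSolution:
    """Parse a solution report written by :func:`write_solution`."""
    fh = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        lines = [ln.rstrip("\n") for ln in fh]
    finally:
        if close:
            fh.close()
    it = iter(lines)

    def expect(prefix: str) -> str:
        try:
            line = next(it)
        except StopIteration:
            raise SolutionFormatError(f"unexpected end of file, expected {prefix!r}")
        if not line.startswith(prefix):
            raise SolutionFormatError(f"expected section {prefix!r}, got {line!r}")
        return line

    expect("PUREHAP SOLUTION 1")
    header = expect("n ").split()
    n, m = int(header[1]), int(header[3])
    objective = int(expect("objective ").split()[1])
    n_corr = int(expect("corrections ").split()[1])
    expect("status ")
    expect("HAPLOTYPES")

    haplotypes: list[Haplotype] = []
    assignment: list[tuple[int, int]] = []
    corrections: list[Correction] = []
    line = next(it, None)
    while line is not None and line != "ASSIGNMENT":
        if line.strip():
            if set(line.strip()) - HAPLOTYPE_SYMBOLS:
                raise SolutionFormatError(f"non-binary haplotype line {line!r}")
            haplotypes.append(tuple(int(ch) for ch in line.strip()))
        line = next(it, None)
    if line != "ASSIGNMENT":
        raise SolutionFormatError("missing ASSIGNMENT section")
    line = next(it, None)
    while line is not None and line != "CORRECTIONS":
        if line.strip():
            _, a, b = (int(tok) for tok in line.split())
            for idx in (a, b):
                if not 1 <= idx <= len(haplotypes):
                    raise SolutionFormatError(
                        f"assignment references haplotype {idx} of {len(haplotypes)}"
                    )
            assignment.append((a - 1, b - 1))
        line = next(it, None)
    if line != "CORRECTIONS":
        raise SolutionFormatError("missing CORRECTIONS section")
    line = next(it, None)
    while line is not None and line != "END":
        if line.strip():
            p, j, orig, new = (int(tok) for tok in line.split())
            corrections.append(
                Correction(genotype_index=p, snp_index=j, delta=new - orig, corrected_value=new)
            )
        line = next(it, None)
    if line != "END":
        raise SolutionFormatError("missing END marker")
    if len(assignment) != n:
        raise SolutionFormatError(f"assignment block has {len(assignment)} rows, header says n={n}")
    if len(corrections) != n_corr:
        raise SolutionFormatError(
            f"corrections block has {len(corrections)} rows, header says {n_corr}"
        )
    for h in haplotypes:
        if len(h) != m:
            raise SolutionFormatError(f"haplotype length {len(h)} != m={m}")
    return PhasingSolution(
        haplotypes=haplotypes, assignment=assignment, corrections=corrections, objective=objective
    )


def read_genotypes(source) -> GenotypeMatrix:
    """Read and validate a genotype file."""
    from .datamodel import validate_genotype_matrix

    return validate_genotype_matrix(read_matrix(source, GENOTYPE_SYMBOLS))


def read_mask(source, genotypes: GenotypeMatrix) -> ErrorMask:
    """Read and validate a mask file against its genotype matrix."""
    from .datamodel import validate_error_mask

    return validate_error_mask(read_matrix(source, MASK_SYMBOLS), genotypes)
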