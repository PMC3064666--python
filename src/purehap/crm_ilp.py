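"""Class representative ILP for pure parsimony haplotyping, with and
without uncertain entries.

The model partitions work among at most ``2n`` *classes*, one per distinct
haplotype of the solution: class ``q < n`` is named by the smallest-index
genotype carrying its haplotype, and class ``n + q`` is the dummy
companion hosting genotype ``q``'s second haplotype when ``q`` is the
smallest carrier of both.  Binary variables:

* ``x_q``   — class q is used (the objective sums these);
* ``y_pq``  — genotype p carries class q's haplotype (representative
  memberships are identified with ``x``);
* ``z_qj``  — site j of class q's haplotype;
* ``e_pjd`` — masked entry (p, j) is corrected by delta d;
* ``w_pq``  — genotype p carries class q's haplotype *twice* (doubled
  resolution of a corrected row that became degenerate).

Each genotype takes exactly two memberships (``sum y + sum w = 2`` with
``w <= y``); at every site the two member classes' ``z`` values must sum
to the (corrected) genotype entry.  Homozygous certain entries fix member
sites directly; heterozygous and masked entries are linearized pairwise
over candidate class pairs.  The total correction count is bounded by
``L <= sum e <= U``.

The doubled-membership variables are this implementation's completion of
the class representative scheme for the corner where corrections make a
row degenerate: such a row is resolved by one haplotype taken twice, and
counting two identical classes would overstate the distinct-haplotype
objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .datamodel import (
    Correction,
    ErrorMask,
    GenotypeMatrix,
    Haplotype,
    PhasingSolution,
    allowed_corrections,
)
from .reduce import ReductionPlan, compute_reduction_plan

INTEGRALITY_TOL = 1e-6


class BackendUnavailableError(RuntimeError):
    """Raised for an unknown or unusable MILP backend identifier."""


class ModelError(ValueError):
    """Raised for inconsistent model parameters (e.g. L > U)."""


def candidate_classes(p: int, n: int) -> list[int]:
    """Classes genotype p may belong to: primaries 0..p and dummies n..n+p
    (a class is named by its smallest member, so representatives <= p)."""
    return list(range(p + 1)) + list(range(n, n + p + 1))


@dataclass
class CrmModel:
    """Assembled MILP plus bookkeeping from columns back to domain objects."""

    n: int
    m: int
    G: np.ndarray
    M: np.ndarray
    L: int
    U: int
    plan: ReductionPlan | None
    num_vars: int
    objective: np.ndarray
    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    x_cols: list[int]
    y_cols: dict[tuple[int, int], int]
    z_cols: dict[tuple[int, int], int]
    z_fixed: dict[tuple[int, int], int]
    e_cols: dict[tuple[int, int, int], int]
    w_cols: dict[tuple[int, int], int]
    memberships: dict[int, list[int]]

    @property
    def num_correction_vars(self) -> int:
        return len(self.e_cols)


@dataclass
class SolveResult:
    """Outcome of one MILP solve.

    ``objective`` is the distinct-haplotype count of the extracted
    solution (equal to the class-count optimum at optimality);
    ``root_lp`` is the LP-relaxation value and ``gap`` the relative
    difference (optimum - root_lp) / optimum.
    """

    status: str
    objective: int | None = None
    class_count: float | None = None
    best_bound: float | None = None
    root_lp: float | None = None
    gap: float | None = None
    node_count: int | None = None
    solution: PhasingSolution | None = None


class _RowBuilder:
    def __init__(self) -> None:
        self.rows_i: list[int] = []
        self.cols_j: list[int] = []
        self.data: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []

    def add(self, coeffs: dict[int, float], lo: float, hi: float) -> None:
        i = len(self.lb)
        for col, coef in coeffs.items():
            if coef:
                self.rows_i.append(i)
                self.cols_j.append(col)
                self.data.append(coef)
        self.lb.append(lo)
        self.ub.append(hi)

    def matrix(self, num_vars: int) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        A = sparse.csr_matrix(
            (self.data, (self.rows_i, self.cols_j)), shape=(len(self.lb), num_vars)
        )
        return A, np.asarray(self.lb, dtype=float), np.asarray(self.ub, dtype=float)


def build_crm(
    G: GenotypeMatrix,
    M: ErrorMask | None = None,
    L: int = 0,
    U: int | None = None,
    plan: ReductionPlan | None = None,
) -> CrmModel:
    """Assemble the class representative MILP.

    ``plan=None`` builds the fully unreduced model (every genotype may join
    every class, no identifications, no site fixing) for A/B comparison;
    passing a :class:`~purehap.reduce.ReductionPlan` applies structural
    index ordering, conflict removals, pair cuts and site fixing.
    """
    g = np.asarray(G.entries)
    n, m = g.shape
    mask = np.zeros((n, m), dtype=np.int8) if M is None else np.asarray(M.entries)
    if mask.shape != g.shape:
        raise ModelError(f"mask shape {mask.shape} != genotype shape {g.shape}")
    num_masked = int(mask.sum())
    if U is None:
        U = num_masked
    if not 0 <= L <= U:
        raise ModelError(f"correction bounds must satisfy 0 <= L <= U, got L={L}, U={U}")

    n_classes = 2 * n
    cols = 0

    def new_var() -> int:
        nonlocal cols
        cols += 1
        return cols - 1

    x_cols = [new_var() for _ in range(n_classes)]

    # Membership variables; under a plan, representative memberships are
    # identified with x and removed pairs are never instantiated.
    y_cols: dict[tuple[int, int], int] = {}
    memberships: dict[int, list[int]] = {}
    for p in range(n):
        if plan is not None:
            alive = [q for q in candidate_classes(p, n) if not plan.is_removed(p, q)]
        else:
            alive = list(range(n_classes))
        memberships[p] = alive
        for q in alive:
            if plan is not None and q in (p, n + p):
                continue  # aliased to x_q
            y_cols[(p, q)] = new_var()

    def yref(p: int, q: int) -> int:
        if plan is not None and q in (p, n + p):
            return x_cols[q]
        return y_cols[(p, q)]

    # Haplotype site variables, except those fixed by the plan.
    z_fixed: dict[tuple[int, int], int] = dict(plan.fixed_sites) if plan is not None else {}
    z_cols: dict[tuple[int, int], int] = {}
    for q in range(n_classes):
        for j in range(m):
            if (q, j) not in z_fixed:
                z_cols[(q, j)] = new_var()

    # Correction variables: one binary per masked cell and allowed delta.
    e_cols: dict[tuple[int, int, int], int] = {}
    for p in range(n):
        for j in range(m):
            if mask[p, j]:
                for d in sorted(allowed_corrections(int(g[p, j]))):
                    e_cols[(p, j, d)] = new_var()

    # Doubled memberships, only for genotypes whose every heterozygous
    # entry is masked (otherwise the corrected row can never be degenerate).
    w_cols: dict[tuple[int, int], int] = {}
    for p in range(n):
        if all(mask[p, j] for j in range(m) if g[p, j] == 1):
            for q in memberships[p]:
                w_cols[(p, q)] = new_var()

    rb = _RowBuilder()

    # Dummy gating: the companion class exists only if its primary is used.
    for q in range(n):
        rb.add({x_cols[n + q]: 1.0, x_cols[q]: -1.0}, -np.inf, 0.0)

    # Exactly two memberships per genotype (doubled ones count twice via
    # the pairing: y counts one, w upgrades it to two).
    for p in range(n):
        coeffs: dict[int, float] = {}
        for q in memberships[p]:
            coeffs[yref(p, q)] = coeffs.get(yref(p, q), 0.0) + 1.0
        for (pp, q), col in w_cols.items():
            if pp == p:
                coeffs[col] = coeffs.get(col, 0.0) + 1.0
        rb.add(coeffs, 2.0, 2.0)

    # Linkage: a class must be used by any genotype assigned to it, and a
    # doubled membership presumes the plain one.
    for (p, q), col in y_cols.items():
        rb.add({col: 1.0, x_cols[q]: -1.0}, -np.inf, 0.0)
    for (p, q), col in w_cols.items():
        ref = yref(p, q)
        rb.add({col: 1.0, ref: -1.0}, -np.inf, 0.0)

    # Joint-membership cuts from the triplet reduction.
    if plan is not None:
        for p, qa, qb in sorted(plan.pair_cuts):
            if qa in memberships[p] and qb in memberships[p]:
                rb.add({yref(p, qa): 1.0, yref(p, qb): 1.0}, -np.inf, 1.0)

    def zterm(q: int, j: int) -> tuple[int | None, float]:
        """(column, constant) for site j of class q."""
        if (q, j) in z_fixed:
            return None, float(z_fixed[(q, j)])
        return z_cols[(q, j)], 0.0

    # Site resolution constraints.
    for p in range(n):
        alive = memberships[p]
        for j in range(m):
            entry = int(g[p, j])
            if not mask[p, j]:
                if entry == 0:
                    # member-class sites forced to 0
                    for q in alive:
                        col, const = zterm(q, j)
                        if col is None:
                            if const == 1.0:
                                rb.add({yref(p, q): 1.0}, -np.inf, 0.0)
                        else:
                            rb.add({col: 1.0, yref(p, q): 1.0}, -np.inf, 1.0)
                elif entry == 2:
                    # member-class sites forced to 1
                    for q in alive:
                        col, const = zterm(q, j)
                        if col is None:
                            if const == 0.0:
                                rb.add({yref(p, q): 1.0}, -np.inf, 0.0)
                        else:
                            rb.add({yref(p, q): 1.0, col: -1.0}, -np.inf, 0.0)
                else:
                    # heterozygous: the two member sites sum to 1,
                    # linearized over candidate class pairs
                    for qa, qb in combinations(alive, 2):
                        ca, consta = zterm(qa, j)
                        cb, constb = zterm(qb, j)
                        zconst = consta + constb
                        upper: dict[int, float] = {yref(p, qa): 1.0, yref(p, qb): 1.0}
                        lower: dict[int, float] = {yref(p, qa): 1.0, yref(p, qb): 1.0}
                        for col in (ca, cb):
                            if col is not None:
                                upper[col] = upper.get(col, 0.0) + 1.0
                                lower[col] = lower.get(col, 0.0) - 1.0
                        if ca is None and cb is None:
                            if zconst != 1.0:
                                rb.add({yref(p, qa): 1.0, yref(p, qb): 1.0}, -np.inf, 1.0)
                            continue
                        # z_a + z_b <= 3 - y_a - y_b  and  z_a + z_b >= y_a + y_b - 1
                        rb.add(upper, -np.inf, 3.0 - zconst)
                        rb.add(lower, -np.inf, 1.0 + zconst)
            else:
                deltas = sorted(allowed_corrections(entry))
                ecols = {d: e_cols[(p, j, d)] for d in deltas}
                # pairwise: z_a + z_b - sum(d*e) = entry when both members
                for qa, qb in combinations(alive, 2):
                    ca, consta = zterm(qa, j)
                    cb, constb = zterm(qb, j)
                    zconst = consta + constb
                    upper: dict[int, float] = {}
                    lower: dict[int, float] = {}
                    for col in (ca, cb):
                        if col is not None:
                            upper[col] = upper.get(col, 0.0) + 1.0
                            lower[col] = lower.get(col, 0.0) + 1.0
                    for d, col in ecols.items():
                        upper[col] = upper.get(col, 0.0) - float(d)
                        lower[col] = lower.get(col, 0.0) - float(d)
                    ya, yb = yref(p, qa), yref(p, qb)
                    upper[ya] = upper.get(ya, 0.0) + 2.0
                    upper[yb] = upper.get(yb, 0.0) + 2.0
                    lower[ya] = lower.get(ya, 0.0) - 2.0
                    lower[yb] = lower.get(yb, 0.0) - 2.0
                    rb.add(upper, -np.inf, entry + 4.0 - zconst)
                    rb.add(lower, entry - 4.0 - zconst, np.inf)
                # doubled: 2 z_q - sum(d*e) = entry when w_pq
                for q in alive:
                    if (p, q) not in w_cols:
                        continue
                    cq, constq = zterm(q, j)
                    upper = {}
                    lower = {}
                    if cq is not None:
                        upper[cq] = 2.0
                        lower[cq] = 2.0
                    for d, col in ecols.items():
                        upper[col] = upper.get(col, 0.0) - float(d)
                        lower[col] = lower.get(col, 0.0) - float(d)
                    wcol = w_cols[(p, q)]
                    upper[wcol] = upper.get(wcol, 0.0) + 2.0
                    lower[wcol] = lower.get(wcol, 0.0) - 2.0
                    rb.add(upper, -np.inf, entry + 2.0 - 2.0 * constq)
                    rb.add(lower, entry - 2.0 - 2.0 * constq, np.inf)

    # At most one correction per masked cell.
    for p in range(n):
        for j in range(m):
            if mask[p, j]:
                coeffs = {e_cols[(p, j, d)]: 1.0 for d in allowed_corrections(int(g[p, j]))}
                rb.add(coeffs, -np.inf, 1.0)

    # Global correction budget L <= sum(e) <= U.
    if e_cols:
        rb.add({col: 1.0 for col in e_cols.values()}, float(L), float(U))
    elif L > 0:
        raise ModelError(f"L={L} corrections required but the mask is empty")

    objective = np.zeros(cols)
    for col in x_cols:
        objective[col] = 1.0
    A, row_lb, row_ub = rb.matrix(cols)
    return CrmModel(
        n=n, m=m, G=g, M=mask, L=L, U=U, plan=plan, num_vars=cols,
        objective=objective, A=A, row_lb=row_lb, row_ub=row_ub,
        x_cols=x_cols, y_cols=y_cols, z_cols=z_cols, z_fixed=z_fixed,
        e_cols=e_cols, w_cols=w_cols, memberships=memberships,
    )


def _solve_highs(model: CrmModel, time_limit: float | None, seed: int | None,
                 relax: bool = False):
    options: dict = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    integrality = np.zeros(model.num_vars) if relax else np.ones(model.num_vars)
    return milp(
        c=model.objective,
        constraints=LinearConstraint(model.A, model.row_lb, model.row_ub),
        integrality=integrality,
        bounds=Bounds(0.0, 1.0),
        options=options,
    )


#: Registry of MILP backends; each maps (model, time_limit, seed, relax) to
#: a scipy-style OptimizeResult.
BACKENDS: dict[str, Callable] = {"highs": _solve_highs}

_STATUS = {0: "optimal", 1: "time-limit", 2: "infeasible", 3: "unbounded"}


def solve_crm(
    model: CrmModel,
    backend: str = "highs",
    time_limit: float | None = None,
    seed: int | None = None,
    compute_root_lp: bool = True,
) -> SolveResult:
    """Solve an assembled model.

    The objective value at optimality is the minimum number of distinct
    haplotypes resolving the instance under the correction bounds; it is
    deterministic per backend, though the optimal haplotype set itself may
    vary between alternate optima.
    """
    if backend not in BACKENDS:
        raise BackendUnavailableError(
            f"unknown backend {backend!r}; available: {sorted(BACKENDS)}"
        )
    solver = BACKENDS[backend]
    res = solver(model, time_limit, seed)
    status = _STATUS.get(int(res.status), "error")
    if res.x is None:
        return SolveResult(status=status)

    solution = extract_solution(model, res.x)
    class_count = float(np.round(model.objective @ res.x))
    result = SolveResult(
        status=status,
        objective=solution.objective,
        class_count=class_count,
        best_bound=getattr(res, "mip_dual_bound", None),
        node_count=int(getattr(res, "mip_node_count", 0)) or None,
        solution=solution,
    )
    if compute_root_lp and status == "optimal":
        lp = solver(model, time_limit, seed, relax=True)
        if lp.x is not None:
            result.root_lp = float(lp.fun)
            if class_count > 0:
                result.gap = (class_count - result.root_lp) / class_count
    return result


def extract_solution(model: CrmModel, values: np.ndarray) -> PhasingSolution:
    """Decode an incumbent into haplotypes, assignments and corrections."""
    frac = np.abs(values - np.round(values))
    if float(frac.max(initial=0.0)) > 1e-4:
        raise ModelError("incumbent violates integrality tolerance")
    val = np.round(values).astype(int)

    def site(q: int, j: int) -> int:
        if (q, j) in model.z_fixed:
            return int(model.z_fixed[(q, j)])
        return int(val[model.z_cols[(q, j)]])

    def yval(p: int, q: int) -> int:
        if model.plan is not None and q in (p, model.n + p):
            return int(val[model.x_cols[q]])
        return int(val[model.y_cols[(p, q)]])

    class_hap: dict[int, Haplotype] = {}
    haplotypes: list[Haplotype] = []
    hap_index: dict[Haplotype, int] = {}

    def hap_of(q: int) -> int:
        if q not in class_hap:
            h = tuple(site(q, j) for j in range(model.m))
            class_hap[q] = h
        h = class_hap[q]
        if h not in hap_index:
            hap_index[h] = len(haplotypes)
            haplotypes.append(h)
        return hap_index[h]

    assignment: list[tuple[int, int]] = []
    for p in range(model.n):
        members = [q for q in model.memberships[p] if yval(p, q) == 1]
        doubled = [
            q for q in members
            if (p, q) in model.w_cols and val[model.w_cols[(p, q)]] == 1
        ]
        if doubled:
            q = doubled[0]
            assignment.append((hap_of(q), hap_of(q)))
        elif len(members) == 2:
            assignment.append(tuple(sorted((hap_of(members[0]), hap_of(members[1])))))  # type: ignore[arg-type]
        else:
            raise ModelError(
                f"genotype {p + 1} has {len(members)} memberships in the incumbent"
            )

    corrections: list[Correction] = []
    for (p, j, d), col in sorted(model.e_cols.items()):
        if val[col] == 1:
            corrections.append(
                Correction(
                    genotype_index=p + 1,
                    snp_index=j + 1,
                    delta=d,
                    corrected_value=int(model.G[p, j]) + d,
                )
            )

    return PhasingSolution(
        haplotypes=haplotypes,
        assignment=assignment,
        corrections=corrections,
        objective=len(haplotypes),
    )


def solve_pph(
    G: GenotypeMatrix,
    M: ErrorMask | None = None,
    L: int = 0,
    U: int | None = None,
    *,
    reduce: bool = True,
    backend: str = "highs",
    time_limit: float | None = None,
    seed: int | None = None,
    compute_root_lp: bool = False,
) -> SolveResult:
    """Convenience wrapper: reduction plan (optional) + build + solve."""
    plan = compute_reduction_plan(G, M) if reduce else None
    model = build_crm(G, M, L=L, U=U, plan=plan)
    return solve_crm(
        model, backend=backend, time_limit=time_limit, seed=seed,
        compute_root_lp=compute_root_lp,
    )
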