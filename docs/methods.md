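# Methods

## Problem and notation

Input: a genotype matrix `G ∈ {0,1,2}^{n×m}` (rows = individuals,
columns = SNPs; 0/2 homozygous wild/mutant, 1 heterozygous), optionally a
binary error mask `M` of the same shape and correction-count bounds
`0 ≤ L ≤ U`.  A pair of binary haplotypes `(h¹, h²)` resolves row `g`
when `h¹ⱼ + h²ⱼ` equals the *corrected* entry at every site, where a
masked entry `gⱼ` may first be shifted by one admissible delta
(`0 → +1/+2`, `2 → −1/−2`, `1 → ±1`; unmasked entries are never touched)
and at most `U` (at least `L`) entries are shifted in total.  Objective:
the minimum number of **distinct** haplotypes resolving all rows.

Validation removes duplicate rows (with a warning) — the class
representative argument presumes distinct genotypes — and rejects
degenerate rows (no `1` entry), which carry no phasing ambiguity and are
excluded from the problem input.  Corrected rows *may* become degenerate;
see "Doubled memberships" below.

## The class representative ILP

Any feasible phasing induces subsets of genotypes, one per distinct
haplotype, such that each genotype lies in exactly two subsets and two
subsets share at most one genotype.  Each subset is named by its
smallest-index member `q`; when a genotype is the smallest member of both
its subsets, the second one is hosted by the dummy index `n + q`.  Hence
genotype `p` can only belong to classes `{1..p} ∪ {n+1..n+p}`, and the
dummy `n+q` is usable only if class `q` is (`x_{n+q} ≤ x_q`).

Binary variables: `x_q` (class used, `q ∈ 1..2n`), `y_pq` (membership;
representative memberships `y_pp`, `y_{p,n+p}` are identified with `x_p`,
`x_{n+p}`), `z_qj` (haplotype site), `e_pjd` (masked cell `(p,j)`
corrected by delta `d`), `w_pq` (doubled membership, below).  The model:

* objective `min Σ_q x_q`;
* `Σ_q y_pq + Σ_q w_pq = 2` per genotype, `y_pq ≤ x_q`, `w_pq ≤ y_pq`;
* unmasked entries: `g_pj = 0` forces `z_qj ≤ 1 − y_pq`; `g_pj = 2`
  forces `z_qj ≥ y_pq`; `g_pj = 1` is linearized pairwise over candidate
  class pairs `(q, q′)`:
  `z_qj + z_q′j ≥ y_pq + y_pq′ − 1` and `z_qj + z_q′j ≤ 3 − y_pq − y_pq′`,
  enforcing the site sum of exactly 1 when both memberships hold;
* masked entries: with `s = Σ_d d·e_pjd` the corrected value is
  `g_pj + s`, and the pairwise equality is enforced big-M style with
  `M = 2` (the expression `z_qj + z_q′j − s − g_pj` is bounded by ±2 for
  every admissible delta set):
  `z_qj + z_q′j − s ≤ g_pj + 2(2 − y_pq − y_pq′)` and symmetrically below;
* at most one correction per masked cell (`Σ_d e_pjd ≤ 1`) and
  `L ≤ Σ e ≤ U` globally;
* all variables binary.

### Doubled memberships

A corrected row with all heterozygous entries masked can become
degenerate, in which case its only resolution is a doubled haplotype
`h + h`.  Two classes carrying identical site vectors would satisfy the
plain model but overstate the distinct-haplotype count by one.  The
variable `w_pq` therefore upgrades a single membership to multiplicity
two and forces `2·z_qj − s = g_pj` (same ±2 big-M); `w_pq` is only
instantiated for genotypes whose every heterozygous entry is masked,
since no other row can be corrected to degeneracy.  With this extension
the class-count optimum equals the distinct-haplotype optimum on all
inputs (two identical used classes are never optimal: their members can
be merged, using `w` where a genotype sat in both), which the oracle
equivalence suite confirms.

## Model-size reduction

Computed in polynomial time before the build (`purehap.reduce`):

* **index ordering** — memberships only for classes whose representative
  index is ≤ the genotype's, with representative memberships identified
  with `x` (part of the class-naming convention above);
* **certain conflicts** — `(p, q)` memberships (primary and dummy) are
  dropped when at some SNP one of `p`, `rep(q)` is a certain 0 and the
  other a certain 2: no shared haplotype can exist, and no correction is
  available at an unmasked cell.  A mask on either cell voids the
  removal;
* **pair cuts** — if `p` is certainly heterozygous at `j` while two of
  its candidate classes' representatives certainly force site `j` to the
  same value, `y_pq + y_pq′ ≤ 1`;
* **site fixing** — `z_qj` is fixed to 0/1 when the representative's
  entry at `j` is a certain 0/2 (the representative belongs to every
  class it names).

All four only exclude assignments violating the haplotype sum, so the
optimum is preserved; this is tested against the oracle rather than
argued per instance.  `build_crm(plan=None)` deliberately builds a fully
*unreduced* model (full membership grid, no identification, no fixing)
so A/B comparisons measure the reduction's effect.

## Solving

The assembled model is a pure 0/1 MILP handed to a pluggable backend
registry; the shipped backend is HiGHS through `scipy.optimize.milp`.
Reported per solve: status, objective (distinct haplotypes of the
extracted solution), class-count, dual bound, node count, and optionally
the LP-relaxation value with the relative gap
`(optimum − LP) / optimum`.  Incumbents are rounded at an integrality
tolerance of 1e−4 (HiGHS default feasibility is far tighter); fractional
incumbents are rejected.  Only the objective is guaranteed deterministic
across backends — alternate optimal haplotype sets exist, so experiments
fix the backend and never assert specific optimal sets unless unique.

## Exhaustive oracle

`purehap.oracle` enumerates every correction profile (per masked cell:
no correction or one admissible delta, total count in `[L, U]`) and, per
corrected matrix, searches the product of each row's resolving pairs
(`2^(k−1)` per row; degenerate corrected rows contribute the single
doubled option).  Rows are visited fewest-options-first; an admissible
bound (committed distinct count ≥ best found) prunes by default and never
changes the optimum, `prune=False` forces the plain walk.  The
enumeration works directly on resolving pairs — independent of the class
encoding it certifies — and is guarded to `n ≤ 6`, `m ≤ 8` so exhaustive
runs stay interactive.

## Synthetic data

The generator emulates the standard phasing benchmark construction:

* **pool** — `pool_size` distinct haplotypes drawn uniformly (for
  `m ≤ 24` by drawing integer codes without replacement, which is the
  same distribution as Bernoulli(0.5) rows with duplicate rejection but
  always terminates; the rejection loop is used for larger `m`).  The
  pool replaces an external coalescent simulation; it reproduces the
  low-diversity premise (few distinct haplotypes explain many genotypes)
  but not linkage structure, mutation-rate realism or recombination, so
  recovery results here speak to solver behaviour, not population
  genetics;
* **pairing** — each genotype is the componentwise sum of two pool
  draws; `uniform` mode draws parents equiprobably, `nonuniform` mode
  from a frequency vector drawn once per run from a symmetric
  Dirichlet(`concentration`, default 0.3; smaller = more skew).
  Degenerate and duplicate rows are rejected and resampled within a
  bounded budget (error if the pool cannot support `n` distinct rows);
* **masks** — exactly `round(r·n·m)` ones (round half up), uniform
  without replacement, so a stated error ratio `r ∈ {1,5,10,15}%` is
  reproduced exactly rather than in expectation;
* **error injection** (`inject_errors`) — optional corruption of masked
  entries to a uniformly chosen different value, for recovery-from-error
  experiments; the accuracy experiment below masks *clean* data, i.e.
  uncertainty without actual corruption, matching its reference
  construction.

Defaults (50 genotypes × 10 SNPs, pool of 10, uniform) mirror the
smallest benchmark condition; pool sizes are the package's choice as the
benchmark's source pools are external.

## Recovery accuracy

For a replicate: phase the clean instance (empty mask) — its haplotype
set is the *reference*; re-phase under a mask of ratio `r`; score
`|reference ∩ estimated| / |reference|` (exact vector matches, no
partial credit).  Ratio 1 means the uncertain-data solve recovered the
full clean-data set.  Under alternate optima the reference is whatever
optimal set the fixed backend returns, so accuracies are reported, not
asserted, per instance.  The shipped experiment uses 20 replicates of
10-genotype × 8-SNP uniform instances from a pool of 6 — sizes chosen so
a full sweep over the four standard error ratios completes in well under
a minute on one CPU while leaving the qualitative trend (higher error
ratio, harder recovery) measurable.

## Numerical and design notes

* Indices in reports and `Correction` records are 1-based; all internal
  arrays are 0-based.
* `L`/`U` bound the *count* of corrected cells (each 0 or 1), not the
  summed delta magnitude; defaults `L = 0`, `U` = number of masked cells.
* Infeasibility (e.g. `L` larger than the number of masked cells can
  support) is reported as a status, not raised.
* The pair-counting bounds `⌈(1+√(1+8n))/2⌉ ≤ optimum ≤ 2n` hold when
  (corrected) rows are pairwise distinct and non-degenerate; corrections
  can merge rows or degenerate them, in which case only the upper bound
  survives (the test suite conditions the lower-bound check accordingly).

## Limitations

Exact exponential-worst-case optimization: practical for benchmark-scale
instances (tens of genotypes, ≤ 100 SNPs), not cohort-scale phasing.  No
VCF/PLINK import, multi-allelic sites, or statistical phasing metrics
(switch error); accuracy is the set-recovery ratio only.
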