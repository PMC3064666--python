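# purehap

Exact haplotype phasing from SNP genotypes under the **pure parsimony
criterion**, with support for **uncertain data** (missing or possibly
erroneous entries), via an integer linear program.

## The problem

Sequencing an individual yields, per SNP, only the *genotype* — the
conflation of the two chromosome copies.  Encoding the common allele as 0
and the rare allele as 1, a genotype is a string over `{0, 1, 2}`: `0`/`2`
mark sites homozygous wild-type/mutant, `1` marks heterozygous sites.  A
*haplotype* is a binary string; an unordered pair of haplotypes *resolves*
a genotype `g` when `h¹ⱼ + h²ⱼ = gⱼ` at every site.  A genotype with `k`
heterozygous sites has `2^(k−1)` resolving pairs, so phasing needs a
selection criterion.  The pure parsimony criterion asks for the **minimum
set of distinct haplotypes** resolving every genotype — an NP-hard
combinatorial problem that reflects the low haplotype diversity of
low-recombination regions.

Real genotype matrices also contain unreliable entries.  Given a binary
*error mask* `M` flagging uncertain cells, the uncertain-data variant lets
the solver *correct* a masked entry by an integer delta before resolving
(`0 → +1/+2`, `2 → −1/−2`, `1 → ±1`), with the total number of corrections
bounded by `L ≤ Σe ≤ U`.

## The model

`purehap` implements a class representative formulation: every feasible
phasing partitions the genotypes into subsets ("classes"), one per
distinct haplotype, each genotype belonging to exactly two.  Classes are
named by their smallest-index member; a dummy companion index hosts a
genotype's second class when it is the smallest carrier of both
haplotypes.  With binaries `x_q` (class used), `y_pq` (genotype `p` in
class `q`), `z_qj` (site `j` of class `q`'s haplotype) and `e_pjd`
(correction of masked cell `(p,j)` by delta `d`), the model minimises
`Σ_q x_q` subject to membership, linkage, haplotype-sum and
correction-budget constraints (see `docs/methods.md` for the full
algebra, including the doubled-membership extension for corrected rows
that become degenerate).  A polynomial-time reduction removes provably
redundant variables before solving; the MILP is solved through a
pluggable backend (HiGHS via SciPy by default).  A brute-force exhaustive
oracle provides independent ground truth on small instances, and a
benchmark-style simulator (haplotype pool + random pairing, exact-count
masks at 1/5/10/15% error ratios) drives the recovery experiments.

## Worked example

Phasing five genotypes of four SNPs:

```sh
$ printf '2112\n1011\n1022\n2011\n2101\n' > example.gen
$ purehap solve --genotypes example.gen --oracle-check
PUREHAP SOLUTION 1
n 5 m 4
objective 4
corrections 0
status optimal
HAPLOTYPES
1101
1011
0011
1000
ASSIGNMENT
1 1 2
2 3 4
3 2 3
4 2 4
5 1 4
CORRECTIONS
END
```

Four distinct haplotypes suffice (and `--oracle-check` confirms no three
do): genotype 1 = `1101` + `1011`, genotype 2 = `0011` + `1000`, and so
on — each pair sums componentwise to its genotype row.

Uncertain data can shrink the optimum.  The genotypes `12` and `10`
conflict at SNP 2 (a certain `2` forces both haplotype sites to 1, a
certain `0` forces both to 0), so clean phasing needs 4 haplotypes; if
cell (2,2) is flagged uncertain, one correction `0 → 2` lets a single
haplotype pair cover both:

```sh
$ printf '12\n10\n' > pair.gen ; printf '00\n01\n' > pair.mask
$ purehap solve --genotypes pair.gen --mask pair.mask
PUREHAP SOLUTION 1
n 2 m 2
objective 2
corrections 1
status optimal
HAPLOTYPES
11
01
ASSIGNMENT
1 1 2
2 1 2
CORRECTIONS
2 2 0 2
END
```

The `CORRECTIONS` line reads: genotype 2, SNP 2, original value 0,
corrected value 2.

Other subcommands: `purehap simulate` (synthetic genotype/mask files),
`purehap eval` (haplotype-set recovery accuracy between two solution
files), `purehap experiment` (replicated recovery experiment, TSV
output).  The same functionality is available as a library
(`purehap.solve_pph`, `purehap.oracle_solve`,
`purehap.accuracy_experiment`, ...).

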