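# mcap — transcriptomic structural variants in heterogeneous samples

`mcap` detects transcriptomic structural variants (TSVs) — novel
adjacencies in transcript sequence caused by genomic structural variation
— from a **genome segment graph** (GSG), while modeling sample
heterogeneity: tumors and diploid genomes carry multiple alleles, and
read evidence that looks self-contradictory under a single-genome model
is often two alleles' worth of consistent rearrangements.

It is aimed at developers and users of RNA-seq SV callers who already
have a segment graph (segments of the reference plus weighted
endpoint-to-endpoint adjacencies from discordant read alignments) and
want allele-aware calling, exact or approximate, with a quantitative
measure of how heterogeneous the sample is.

## The model

A GSG is a weighted undirected graph `G = (V, E, w)`: each genome segment
`s` contributes two vertices, its head `s_h` (5'-proximal) and tail
`s_t`; each edge joins endpoints of two segments and is weighted by the
number of supporting read pairs. An **arrangement** `(π, f)` is a
permutation of all segments plus a per-segment orientation bit — one
allele's rearranged genome. An edge `e = (u_a, v_b)` with `π(u) < π(v)`
is **concordant** with the arrangement iff

```
f(u) = 1[a = t]   and   f(v) = 1[b = h]
```

i.e. the adjacency runs tail-then-head along the rearranged genome. The
**multiple compatible arrangements problem (MCAP)** asks, for a given
allele count `k`, for arrangements `A = {(π_i, f_i)}` maximizing

```
max_A  Σ_{e∈E} w(e) · 1[e concordant with at least one (π_i, f_i) ∈ A]
```

`k = 1` (the single compatible arrangement problem, SCAP) is the
classical homogeneous model. The problem is NP-complete, so the package
provides:

* an exhaustive oracle for toy instances (`mcap.brute`),
* greedy solvers with proven floors — end-placement greedy (≥ w(E)/4,
  hence a 1/4-approximation of SCAP), insertion greedy (same floor,
  better in practice), and an iterative scheme that re-solves on residual
  graphs (3/4-approximation of the `k = 2` optimum with an exact oracle,
  3/16 with the greedy oracle) (`mcap.greedy`),
* an exact binary integer program for general `k`, solved per connected
  component with per-component time limits (`mcap.ilp`),
* a conflict-structure detector that labels each reference-discordant
  edge by whether it sits in a cycle that no single arrangement can
  satisfy — the fraction of such edges measures heterogeneity
  (`mcap.conflicts`),
* a synthetic-instance generator with planted alleles and known TSVs
  (`mcap.simulate`).

Edges concordant in at least one solution arrangement are reported as
TSV calls in BEDPE: `REARRANGED` if discordant with the reference, or
`DISTANT` if reference-concordant but joining different chromosomes or
segments further apart than a configurable distance (default 200 kb) —
adjacencies alternative splicing cannot explain.

## Worked example

`example.gsg` holds the smallest instance where heterogeneity matters: two
segments joined by a tail-tail edge (weight 3) and a head-head edge
(weight 2). No single arrangement satisfies both.

```
S	u	chr1	0	100
S	v	chr1	100	200
E	u	T	v	T	3
E	u	H	v	H	2
```

```console
$ mcap solve --gsg example.gsg --method ilp --k 2 --out-prefix example
objective	5
total_weight	5
n_tsv_calls	2
```

Under the diploid model the full edge weight (5) is explained and both
adjacencies are called, one per allele:

```console
$ cat example.bedpe
# mcap 0.1.0 solve method=ilp k=2 gsg=example.gsg
chr1	0	1	chr1	100	101	u:H|v:H	2	HH	REARRANGED	1
chr1	100	101	chr1	200	201	u:T|v:T	3	TT	REARRANGED	0
```

With `--k 1` the solver keeps only the heavier edge (`objective 3`,
one call) — the homogeneous model discards a true variant. The conflict
census quantifies this directly:

```console
$ mcap conflicts --gsg example.gsg
IN_CONFLICT	2
NOT_IN_CONFLICT	0
UNDECIDED	0
heterogeneity_fraction	1
```

Both discordant edges sit in a conflict structure: the sample cannot be
homogeneous unless the reads are errors.

The library mirrors the CLI: `parse_gsg`, `solve_per_component`,
`call_tsvs`, `heterogeneity_fraction`, `simulate_instance` etc. — see the
module docstrings and `docs/methods.md`.

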