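# Methods

## Problem and data model

The package operates on a genome segment graph (GSG): a segmentation of
the reference genome into disjoint intervals (0-based half-open
coordinates, BED-compatible), one vertex per segment endpoint (head =
5'-proximal, tail = 3'-proximal), and weighted undirected edges between
endpoints of distinct segments. Edge weight is read support, accepted as
any nonnegative real (integers typical; upstream filtering may produce
fractional support). Duplicate edge records for the same unordered
endpoint pair are merged by summing weights, so the graph carries at most
one edge per endpoint pair; within-segment edges are rejected at parse
time, since edge concordance is defined between two distinct segments.
Graph construction from read alignments is deliberately out of scope —
the expected input is the documented plain text format (`S` and `E`
records).

An arrangement is a permutation of all segments plus one orientation bit
per segment; `k` arrangements model `k` alleles. Edge concordance
follows the tail-then-head rule: with `(u, a)` the endpoint whose
segment ranks earlier, the edge is concordant iff `orient(u) = 1[a=t]`
and `orient(v) = 1[b=h]`. The rule is symmetric in the edge's endpoint
order and invariant under reversing an arrangement (reversing ranks and
flipping every orientation), which the test suite checks exhaustively;
the solver objective is the total weight of edges concordant in at least
one arrangement, each edge counted once.

## TSV calling

Edges concordant in at least one solution arrangement are TSV
candidates in two categories. Reference-discordant edges become
`REARRANGED` calls. Reference-concordant edges become `DISTANT` calls
when they join different chromosomes or same-chromosome segments whose
interval gap (start of the later segment minus end of the earlier)
exceeds `max_distance`; everything nearer is attributed to alternative
splicing and not reported. Choices made where the convention was open:

* **Distance definition.** The inter-segment gap is used rather than a
  breakpoint-to-breakpoint distance; the two differ by at most the two
  segment lengths and the gap is independent of which ends the edge
  uses. Default `max_distance` = 200,000 bp, configurable — a scale at
  which same-gene splicing is implausible for typical mammalian genes.
* **Breakpoint coordinates.** A head endpoint maps to the segment start,
  a tail endpoint to the segment end, making BEDPE output deterministic.
* **Cross-chromosome reference concordance.** The reference arrangement
  concatenates chromosomes in file order, so a tail-head edge across
  chromosomes can test as "concordant" with the concatenation; such
  edges are reported as `DISTANT` (the inter-chromosomal clause) rather
  than suppressed, so the arbitrary concatenation order never hides a
  translocation.
* **Phasing.** Every arrangement index satisfying an edge is reported in
  the call's allele list; no canonical phasing is chosen because many
  phasings are typically equivalent.

## Solvers

**Exhaustive oracle.** All `n!·2^n` arrangements are enumerated (cap:
8 segments for `k = 1`, 5 for multi-arrangement problems). For the
multi-arrangement optimum, arrangements are collapsed to their
concordant-edge bitmasks, masks contained in other masks are dropped
(dominated for a union objective), and the best union over `k` remaining
masks is taken — far below `(n!·2^n)^k`. Ties break by enumeration
order, so results are deterministic. This oracle defines ground truth
for every ratio and exactness test.

**Greedy solvers.** Segments are processed in a caller-supplied order
(default: genomic). The end-placement variant evaluates four options per
segment — prepend/append × both orientations — and keeps the best; the
four candidate gains partition the weight of all edges to already-placed
segments (each such edge is concordant under exactly one option), which
yields the `w(E)/4` floor. The insertion variant widens the candidate
set to every insertion position; inserting never changes relative order
or orientation of placed segments, so satisfied edges stay satisfied and
the same floor applies. Gains are computed by direct evaluation of the
concordance rule on the tentative arrangement (correct for arbitrary
prior orientations); the partition identity is asserted in tests rather
than assumed. Tie-breaking is fixed (append before prepend, original
orientation before inverted; lowest insertion index first) for
reproducibility. The iterative multi-arrangement scheme solves the
single-arrangement problem `k` times, zeroing the weights of already
satisfied edges between rounds (topology is kept so later rounds see the
same graph). Each connected component is solved independently and the
results composed in genomic order.

**Integer program.** Binary variables per arrangement `i`: `y[u,i]`
(orientation), `z[{u,v},i]` (precedence; one variable per unordered
pair, the reverse direction substituted as `1 − z`, so antisymmetry
holds structurally and the variable count halves), and `x[e,i]` (edge
satisfied); one `q[e]` per edge with `q ≤ Σ_i x[e,i]`, objective
`max Σ w(e)·q[e]`. Each connection type contributes four cap
constraints tying `x = 1` to its order/orientation pattern (tail-head:
`z = y_u = y_v`; tail-tail: `z = y_u = 1−y_v`; head-tail:
`z = 1−y_u = 1−y_v`; head-head: `z = 1−y_u = y_v`, with `u` the
genomically earlier segment). Caps are one-sided; maximization supplies
the reverse implication, and `x` may remain 0 on an edge the decoded
arrangement in fact satisfies — decoding therefore never loses objective
value, which is tested. A transitivity band `0 ≤ z_uv + z_vw − z_uw ≤ 1`
per segment triple (triples over segments, not endpoint vertices) makes
each `z` layer a total order; ranks are decoded by counting
predecessors. Constraint count: `4k|E|` caps + `|E|` q-links +
`k·C(n,3)` transitivity bands for `n` segments. The backend is
`scipy.optimize.milp` (HiGHS), which honors wall-clock time limits and
returns incumbents; a solve that hits the limit is reported as
`FEASIBLE_TIME_LIMIT`, and a component with no incumbent falls back to
its reference arrangement with a warning. HiGHS exposes no seed through
scipy; solves are deterministic in practice. The default pipeline runs
the ILP with `k = 2` (diploid assumption) on every connected component
with a per-component time limit (default 3600 s) and composes global
arrangements in genomic order.

## Conflict structures and heterogeneity

For conflict analysis the graph gains one auxiliary segment edge per
segment joining its own head and tail. Any edge set that is acyclic
together with the segment edges is satisfiable by a single arrangement
(a leaf segment can always be placed at one of the four end options);
conflicts therefore require cycles. A simple cycle is tested by the
junction criterion: it is satisfiable by one arrangement iff exactly two
of its vertices carry two of the cycle's adjacency edges ("junctions")
and those two vertices lie on different segments.

**Scope of the junction criterion.** The criterion is exact on cycles
with at most two junction vertices — the class the classifier's
agreement tests draw from — and this covers the alternating cycles that
segment-edge traversals produce. With three or more junctions it can
misjudge in one direction only: a vertex may carry two concordant
adjacency edges at once (the splicing allowance), so a satisfiable cycle
can be flagged as a conflict; the converse error cannot occur. A unit
test pins a four-junction counterexample. Consequently the per-edge
classifier is conservative: `IN_CONFLICT` labels on edges whose only
witness cycles have ≥ 3 junctions may overcall heterogeneity, and the
heterogeneity fraction is an upper-bound-leaning estimate.

A reference-discordant edge is classified by enumerating simple paths
between its endpoints (the edge itself omitted, segment edges included),
closing each path into a cycle with the edge and applying the junction
criterion; the first failing cycle is returned as a witness
(`IN_CONFLICT`), exhaustive enumeration without one yields
`NOT_IN_CONFLICT` (no completeness claim is attached — an incompatible
subgraph that is not a simple cycle would be missed, matching the
procedure's stated sufficiency-only guarantee). Each enumeration attempt
has a wall-clock timeout (default 0.5 s); on timeout the neighbor order
is reshuffled with a seeded RNG and the search rerun, up to
`max_reruns` (default 1000) extra attempts, after which the edge is
`UNDECIDED`. With a zero timeout every attempt expires immediately, so a
zero rerun budget yields `UNDECIDED` — a deliberate contract for
budget-free smoke runs. The heterogeneity fraction is the share of
reference-discordant edges labeled `IN_CONFLICT` (0 when there are
none).

## Synthetic instances

The generator emulates the graph a heterogeneous sample induces:
contiguous segments (lengths uniform in 500–5000 bp) on `n_chroms`
chromosomes; each of `k` alleles derived from the reference by
`ops_per_allele` random operations (run inversion, run move, disjoint
run swap); per allele, `edges_per_allele` edges drawn between ordered
segment pairs of that allele — biased 60% toward adjacent pairs, the
rest uniform over ordered pairs, mirroring that concordant edges need
not be adjacencies (splicing) — with weights `1 + Poisson(mean − 1)`
(default mean 10); plus `n_noise_edges` uniformly random endpoint pairs
with small integer weights (default ≤ 3) that never collide with planted
pairs, so planted signal dominates by default (overridable). Every
planted edge is asserted concordant in its source allele at generation
time, and the reference-discordant planted edges form the ground-truth
TSV set. The `allele_scope` switch confines each allele's operations and
edges to its own chromosome (`disjoint`) or lets all alleles share the
genome (`shared`); since an incompatible cycle needs edges from at least
two sources, the disjoint setting suppresses conflicts and the shared
setting produces them — the dose-response test asserts exactly this
trend. Instances are fully reproducible from the config seed.

What the generator does **not** model: read-level noise (FASTQ/alignment
artifacts), expression variation across alleles, tumor purity mixtures,
segment boundary uncertainty, or weight inflation from multi-mapping.
Passing recovery tests therefore show correctness of the optimization
and calling machinery on clean allele-structured evidence, not
robustness to alignment artifacts.

## Problem sizes and numerics

Oracle-backed sweeps use instances of 3–5 segments (8 for the greedy
floor sweep), 3–12 edges and integer weights 1–10, sizes at which the
exhaustive optimum is instant and the full acceptance battery (500-
instance ratio sweep, 300 ILP exactness solves, 450 structure checks,
50 recovery solves, 1000-instance floor sweep) completes in seconds.
Floating-point comparisons use absolute tolerances of 1e-6–1e-9 against
integer-valued optima. Ties everywhere break deterministically
(enumeration order; fixed greedy option priority; first-found incumbent).

## Known limitations

* The junction criterion's conservativeness beyond two junctions (above)
  biases heterogeneity fractions upward on dense graphs.
* `NOT_IN_CONFLICT` is exact only relative to simple-cycle witnesses.
* The ILP's transitivity constraints are materialized for all triples
  (`O(k·n³)` rows); very large components should use the greedy solvers
  or per-component decomposition with time limits.
* Arrangement optima are generally non-unique; reported arrangements and
  phasings are one representative of an equivalence class.
* The allele count `k` is an input, not estimated.
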