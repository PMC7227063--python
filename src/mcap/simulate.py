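"""Synthetic segment-graph instances with planted alleles and known TSVs.

The generator emulates what a heterogeneous RNA-seq sample induces on a
segment graph: a reference segmentation, k alleles derived from the
reference by random rearrangement operations (inversion of a segment run,
move of a run, swap of two runs), per-allele adjacency edges drawn between
ordered segment pairs of that allele (hence concordant in it by
construction), and uniform random noise edges with small weights.  The
planted arrangements and the reference-discordant planted edges are
returned as ground truth, so solvers and the conflict detector can be
scored without external data.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .arrangement import (
    Arrangement,
    ArrangementSet,
    TSVCall,
    is_concordant,
    reference_arrangement,
)
from .gsg import GSG, Edge, EndpointRef, HEAD, TAIL, Segment

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GroundTruth",
    "simulate_instance",
    "evaluate_calls",
    "random_gsg",
    "random_simple_cycle",
]


class SimConfigError(ValueError):
    """The requested instance cannot be generated (counts impossible)."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``allele_scope`` controls where each allele's rearrangements and edges
    land: ``shared`` lets all alleles hit the same regions (conflicts
    likely), ``disjoint`` confines allele i to chromosome ``i mod
    n_chroms`` (conflicts require noise).
    """

    seed: int
    n_chroms: int = 2
    segments_per_chrom: int = 4
    k_alleles: int = 2
    ops_per_allele: int = 2
    edges_per_allele: int = 6
    mean_weight: float = 10.0
    n_noise_edges: int = 2
    noise_weight_max: int = 3
    min_segment_len: int = 500
    max_segment_len: int = 5000
    allele_scope: Literal["shared", "disjoint"] = "shared"

    def __post_init__(self) -> None:
        if self.k_alleles < 1:
            raise SimConfigError("k_alleles must be >= 1")
        for name in ("n_chroms", "segments_per_chrom"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        for name in ("ops_per_allele", "edges_per_allele", "n_noise_edges",
                     "noise_weight_max"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        n = self.n_chroms * self.segments_per_chrom
        if n < 2 and (self.edges_per_allele or self.n_noise_edges):
            raise SimConfigError("edges need at least 2 segments")
        if self.allele_scope == "disjoint" and self.segments_per_chrom < 2 \
                and (self.edges_per_allele or self.ops_per_allele):
            raise SimConfigError("disjoint scope needs >= 2 segments per chromosome")


@dataclass
class GroundTruth:
    """Planted alleles and the planted reference-discordant (TSV) edges."""

    arrangements: ArrangementSet
    tsv_edges: list[Edge]
    source_alleles: dict[tuple[EndpointRef, EndpointRef], tuple[int, ...]]


def _apply_op(rng: np.random.Generator, allele: list[tuple[str, int]],
              lo: int, hi: int) -> None:
    """Apply one random rearrangement operation to allele[lo:hi] in place."""
    span = hi - lo
    if span < 2:
        return
    kind = rng.choice(["invert", "move", "swap"])
    if kind == "invert":
        i = int(rng.integers(lo, hi - 1))
        j = int(rng.integers(i + 1, hi))
        allele[i:j + 1] = [(sid, 1 - o) for sid, o in reversed(allele[i:j + 1])]
    elif kind == "move":
        i = int(rng.integers(lo, hi))
        j = int(rng.integers(i, hi))
        run = allele[i:j + 1]
        del allele[i:j + 1]
        dest = int(rng.integers(lo, hi - len(run) + 1))
        allele[dest:dest] = run
    else:  # swap two disjoint runs
        if span < 2:
            return
        cuts = sorted(rng.choice(np.arange(lo, hi + 1), size=4, replace=True))
        a, b, c, d = (int(x) for x in cuts)
        if b == c:  # ensure disjoint, possibly empty-adjacent runs are fine
            allele[a:d] = allele[b:d] + allele[a:b]
        else:
            allele[a:d] = allele[c:d] + allele[b:c] + allele[a:b]


def _concordant_edge_for(allele: list[tuple[str, int]], p: int, q: int) -> tuple[EndpointRef, EndpointRef]:
    """Endpoint pair concordant in the allele for ordered positions p < q."""
    u, ou = allele[p]
    v, ov = allele[q]
    a = TAIL if ou else HEAD
    b = HEAD if ov else TAIL
    return EndpointRef(u, a), EndpointRef(v, b)


def simulate_instance(config: SimConfig) -> tuple[GSG, GroundTruth]:
    """Generate one instance; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    segments: list[Segment] = []
    for c in range(config.n_chroms):
        pos = 0
        for j in range(config.segments_per_chrom):
            length = int(rng.integers(config.min_segment_len,
                                      config.max_segment_len + 1))
            segments.append(Segment(f"s{c}_{j}", f"chr{c + 1}", pos, pos + length))
            pos += length
    skeleton = GSG(segments)
    ref_order = skeleton.genomic_order()
    n = len(ref_order)
    chrom_slices = [
        (c * config.segments_per_chrom, (c + 1) * config.segments_per_chrom)
        for c in range(config.n_chroms)
    ]

    alleles: list[list[tuple[str, int]]] = []
    for i in range(config.k_alleles):
        allele = [(sid, 1) for sid in ref_order]
        if config.allele_scope == "disjoint":
            lo, hi = chrom_slices[i % config.n_chroms]
        else:
            lo, hi = 0, n
        for _ in range(config.ops_per_allele):
            _apply_op(rng, allele, lo, hi)
        alleles.append(allele)

    planted: dict[tuple[EndpointRef, EndpointRef], float] = {}
    sources: dict[tuple[EndpointRef, EndpointRef], set[int]] = {}
    for i, allele in enumerate(alleles):
        if config.allele_scope == "disjoint":
            lo, hi = chrom_slices[i % config.n_chroms]
        else:
            lo, hi = 0, n
        if hi - lo < 2:
            continue
        for _ in range(config.edges_per_allele):
            p = int(rng.integers(lo, hi - 1))
            if rng.random() < 0.6 or p == hi - 2:
                q = p + 1
            else:
                q = int(rng.integers(p + 1, hi))
            a, b = _concordant_edge_for(allele, p, q)
            key = Edge(a, b, 0.0).key
            weight = 1.0 + float(rng.poisson(max(config.mean_weight - 1.0, 0.0)))
            planted[key] = planted.get(key, 0.0) + weight
            sources.setdefault(key, set()).add(i)

    # noise: uniform random endpoint pairs not colliding with planted edges
    noise: dict[tuple[EndpointRef, EndpointRef], float] = {}
    all_pairs = [
        Edge(EndpointRef(u, eu), EndpointRef(v, ev), 0.0).key
        for u, v in itertools.combinations(ref_order, 2)
        for eu in (HEAD, TAIL)
        for ev in (HEAD, TAIL)
    ]
    free = [p for p in all_pairs if p not in planted]
    if config.n_noise_edges > len(free):
        raise SimConfigError(
            f"cannot place {config.n_noise_edges} noise edges; "
            f"only {len(free)} endpoint pairs are free"
        )
    if config.n_noise_edges:
        picks = rng.choice(len(free), size=config.n_noise_edges, replace=False)
        for idx in picks:
            key = free[int(idx)]
            noise[key] = float(rng.integers(1, config.noise_weight_max + 1))

    edges = [Edge(a, b, w) for (a, b), w in planted.items()]
    edges += [Edge(a, b, w) for (a, b), w in noise.items()]
    gsg = GSG(segments, edges)

    arrangement_set = ArrangementSet(
        [
            Arrangement(tuple(s for s, _ in allele), {s: o for s, o in allele})
            for allele in alleles
        ]
    )
    # construction soundness: every planted edge is concordant in a source allele
    for key, alleles_of in sources.items():
        e = gsg.edge_by_key(*key)
        for i in alleles_of:
            assert is_concordant(e, arrangement_set[i]), (
                f"planted edge {e} not concordant in allele {i}"
            )

    ref = reference_arrangement(gsg)
    tsv_edges = [
        gsg.edge_by_key(*key)
        for key in planted
        if not is_concordant(gsg.edge_by_key(*key), ref)
    ]
    truth = GroundTruth(
        arrangements=arrangement_set,
        tsv_edges=tsv_edges,
        source_alleles={k: tuple(sorted(v)) for k, v in sources.items()},
    )
    return gsg, truth


def evaluate_calls(truth: GroundTruth, calls: Iterable[TSVCall]) -> tuple[float, float]:
    """Precision/recall of TSV calls against the planted TSV edges.

    Matching is exact on the unordered endpoint pair; allele assignment is
    ignored (phasings are generally non-unique).  With no calls, precision
    is reported as 1.0 by convention; with no planted TSVs, recall is 1.0.
    """
    truth_keys = {e.key for e in truth.tsv_edges}
    call_keys = {c.edge.key for c in calls}
    tp = len(truth_keys & call_keys)
    precision = tp / len(call_keys) if call_keys else 1.0
    recall = tp / len(truth_keys) if truth_keys else 1.0
    return precision, recall


def random_gsg(
    rng: random.Random | int,
    n_segments: int,
    n_edges: int,
    weight_range: tuple[int, int] = (1, 10),
    segment_length: int = 100,
) -> GSG:
    """Uniform random instance on one chromosome (for stress/oracle tests).

    Draws ``n_edges`` distinct endpoint pairs across distinct segments with
    integer weights in ``weight_range``.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    segments = [
        Segment(f"s{j}", "chr1", j * segment_length, (j + 1) * segment_length)
        for j in range(n_segments)
    ]
    pairs = [
        (EndpointRef(a.id, ea), EndpointRef(b.id, eb))
        for a, b in itertools.combinations(segments, 2)
        for ea in (HEAD, TAIL)
        for eb in (HEAD, TAIL)
    ]
    if n_edges > len(pairs):
        raise SimConfigError(f"at most {len(pairs)} distinct edges possible")
    chosen = rng.sample(pairs, n_edges)
    lo, hi = weight_range
    edges = [Edge(a, b, float(rng.randint(lo, hi))) for a, b in chosen]
    return GSG(segments, edges)


def random_simple_cycle(
    rng: random.Random | int,
    max_segments: int = 5,
    n_junctions: int | None = None,
):
    """Random simple cycle in a conflict graph, plus a GSG of its edges.

    Each segment either contributes both endpoints joined by its segment
    edge (a *traversal*) or a single *junction* vertex carrying two of the
    cycle's adjacency edges.  ``n_junctions`` fixes the junction count
    (default: random in {0, 1, 2}).  The cycle-compatibility criterion is
    provably exact on cycles with at most two junctions; with three or
    more junctions it can flag satisfiable cycles as conflicts (it stays
    conservative), so agreement tests draw from the <= 2-junction class.

    Returns ``(cycle, gsg)`` where ``gsg`` holds the cycle's adjacency
    edges with unit weights, so single-arrangement satisfiability of the
    cycle can be decided by exhaustive search on ``gsg``.
    """
    from .conflicts import ADJACENCY, SEGMENT, SimpleCycle
    from .gsg import Segment as _Segment

    if isinstance(rng, int):
        rng = random.Random(rng)
    while True:
        m = rng.randint(2, max_segments)
        nj = rng.choice([0, 1, 2]) if n_junctions is None else n_junctions
        segs = [f"s{i}" for i in range(m)]
        units: list[tuple[EndpointRef, ...]]
        if nj == 2 and rng.random() < 0.3:
            # both junctions on one segment (its endpoints, no segment edge)
            units = [(EndpointRef(segs[0], HEAD),), (EndpointRef(segs[0], TAIL),)]
            traversed = segs[1:]
        else:
            j_segs = rng.sample(segs, min(nj, m))
            units = [(EndpointRef(s, rng.choice("HT")),) for s in j_segs]
            traversed = [s for s in segs if s not in j_segs]
        for s in traversed:
            enter = rng.choice("HT")
            exit_ = TAIL if enter == HEAD else HEAD
            units.append((EndpointRef(s, enter), EndpointRef(s, exit_)))
        if len(units) < 2:
            continue
        for _ in range(20):  # adjacency edges must join distinct segments
            rng.shuffle(units)
            if all(
                units[i][0].segment_id != units[(i + 1) % len(units)][0].segment_id
                for i in range(len(units))
            ):
                break
        else:
            continue
        verts: list[EndpointRef] = []
        kinds: list[str] = []
        for u in units:
            if len(u) == 2:
                verts += [u[0], u[1]]
                kinds += [SEGMENT, ADJACENCY]
            else:
                verts.append(u[0])
                kinds.append(ADJACENCY)
        cycle = SimpleCycle(tuple(verts), tuple(kinds))
        pairs = {
            Edge(verts[i], verts[(i + 1) % len(verts)], 0.0).key
            for i in range(len(verts))
            if kinds[i] == ADJACENCY
        }
        gsg = GSG(
            [_Segment(s, "chr1", 100 * i, 100 * (i + 1)) for i, s in enumerate(segs)],
            [Edge(a, b, 1.0) for a, b in pairs],
        )
        return cycle, gsg
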