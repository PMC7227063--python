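"""Arrangements (permutation + orientation), edge concordance, TSV calling.

An arrangement models one allele of a rearranged genome: a permutation of
all segments plus a per-segment orientation bit (1 = original orientation,
0 = inverted).  An edge joining segment *u* at end *a* to segment *v* at
end *b* is *concordant* with an arrangement when, taking *u* to be the
lower-ranked segment, ``orient(u) == 1[a == T]`` and
``orient(v) == 1[b == H]`` — i.e. the read-implied adjacency runs
tail-then-head along the rearranged genome.  Edges concordant in at least
one of *k* arrangements count toward the MCAP objective; those that are
discordant with the reference but concordant in some solution arrangement
(or reference-concordant but spanning chromosomes / a large gap) are the
predicted transcriptomic structural variants (TSVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .gsg import (
    GSG,
    HEAD,
    TAIL,
    Edge,
    GSGReferenceError,
    GSGValidationError,
)

__all__ = [
    "Arrangement",
    "ArrangementSet",
    "TSVCall",
    "REARRANGED",
    "DISTANT",
    "DEFAULT_MAX_DISTANCE",
    "reference_arrangement",
    "reverse_arrangement",
    "is_concordant",
    "is_reference_concordant",
    "objective_value",
    "call_tsvs",
    "write_arrangements",
    "write_bedpe",
]

REARRANGED = "REARRANGED"
DISTANT = "DISTANT"

#: Default gap (bp) beyond which a reference-concordant adjacency is no
#: longer attributable to splicing and is reported as a DISTANT TSV.
DEFAULT_MAX_DISTANCE = 200_000


@dataclass(frozen=True)
class Arrangement:
    """A permutation of segment ids plus per-segment orientation bits.

    ``order[i]`` is the segment with rank ``i``; ``orient[sid]`` is 1 when
    the segment keeps its original orientation and 0 when inverted.
    """

    order: tuple[str, ...]
    orient: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise GSGValidationError("arrangement order contains duplicates")
        if set(self.orient) != set(self.order):
            raise GSGValidationError(
                "orientation map must cover exactly the ordered segments"
            )
        if any(o not in (0, 1) for o in self.orient.values()):
            raise GSGValidationError("orientations must be 0 or 1")
        object.__setattr__(
            self, "_rank", {sid: i for i, sid in enumerate(self.order)}
        )

    @property
    def rank(self) -> dict[str, int]:
        return self._rank  # type: ignore[attr-defined]

    @property
    def n(self) -> int:
        return len(self.order)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self.rank

    def signed_ids(self) -> list[str]:
        """Segment ids in rank order, '-'-prefixed when inverted."""
        return [sid if self.orient[sid] else "-" + sid for sid in self.order]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Arrangement):
            return NotImplemented
        return self.order == other.order and self.orient == other.orient

    def __hash__(self) -> int:
        return hash((self.order, tuple(self.orient[s] for s in self.order)))


@dataclass
class ArrangementSet:
    """An ordered list of k arrangements over one common segment set."""

    arrangements: list[Arrangement]

    def __post_init__(self) -> None:
        if self.arrangements:
            base = set(self.arrangements[0].order)
            for arr in self.arrangements[1:]:
                if set(arr.order) != base:
                    raise GSGValidationError(
                        "all arrangements in a set must cover the same segments"
                    )

    @property
    def k(self) -> int:
        return len(self.arrangements)

    def __iter__(self):
        return iter(self.arrangements)

    def __getitem__(self, i: int) -> Arrangement:
        return self.arrangements[i]

    def __len__(self) -> int:
        return len(self.arrangements)


@dataclass(frozen=True)
class TSVCall:
    """A predicted transcriptomic structural variant (one qualifying edge).

    Breakpoints map an H endpoint to the segment start and a T endpoint to
    the segment end.  ``alleles`` lists the indices of all solution
    arrangements in which the edge is concordant (phasing is generally
    non-unique, so every supporting allele is reported).
    """

    bp1: tuple[str, int, str]  # (chrom, position, H|T)
    bp2: tuple[str, int, str]
    category: str  # REARRANGED | DISTANT
    weight: float
    alleles: tuple[int, ...]
    edge: Edge

    @property
    def name(self) -> str:
        return f"{self.edge.a}|{self.edge.b}"

    @property
    def end_types(self) -> str:
        return self.edge.a.end + self.edge.b.end


def reference_arrangement(gsg: GSG) -> Arrangement:
    """The identity arrangement: genomic order, all orientations 1."""
    order = tuple(gsg.genomic_order())
    return Arrangement(order, {sid: 1 for sid in order})


def reverse_arrangement(arr: Arrangement) -> Arrangement:
    """Reverse-complement an arrangement: reverse ranks, flip orientations.

    An involution; concordance of every edge is invariant under it.
    """
    return Arrangement(
        tuple(reversed(arr.order)),
        {sid: 1 - o for sid, o in arr.orient.items()},
    )


def is_concordant(edge: Edge, arr: Arrangement) -> bool:
    """Concordance of one edge under one arrangement.

    Symmetric in the edge's endpoint order and invariant under
    :func:`reverse_arrangement`.
    """
    u, v = edge.a, edge.b
    for ref in (u, v):
        if ref.segment_id not in arr:
            raise GSGReferenceError(
                f"segment {ref.segment_id!r} missing from arrangement"
            )
    if arr.rank[u.segment_id] > arr.rank[v.segment_id]:
        u, v = v, u
    return (
        arr.orient[u.segment_id] == int(u.end == TAIL)
        and arr.orient[v.segment_id] == int(v.end == HEAD)
    )


def is_reference_concordant(gsg: GSG, edge: Edge) -> bool:
    """Concordance with the reference (identity) arrangement of ``gsg``."""
    return is_concordant(edge, reference_arrangement(gsg))


def objective_value(gsg: GSG, A: ArrangementSet) -> tuple[float, set[Edge]]:
    """MCAP objective: total weight of edges concordant in >= 1 arrangement.

    Each edge counts once no matter how many arrangements satisfy it.
    Returns the value together with the satisfied edge set.
    """
    if A.k and set(A[0].order) != set(gsg.segments):
        raise GSGReferenceError("arrangement set does not cover the graph's segments")
    satisfied = {
        e for e in gsg.edges if any(is_concordant(e, arr) for arr in A)
    }
    return sum(e.weight for e in satisfied), satisfied


def _breakpoint(gsg: GSG, ref) -> tuple[str, int, str]:
    seg = gsg.segment(ref.segment_id)
    pos = seg.start if ref.end == HEAD else seg.end
    return (seg.chrom, pos, ref.end)


def _gap(gsg: GSG, edge: Edge) -> int:
    """Gap between the two segment intervals (same chromosome only)."""
    s1 = gsg.segment(edge.a.segment_id)
    s2 = gsg.segment(edge.b.segment_id)
    if s1.start > s2.start:
        s1, s2 = s2, s1
    return max(0, s2.start - s1.end)


def call_tsvs(
    gsg: GSG,
    A: ArrangementSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[TSVCall]:
    """Call TSVs from a solved arrangement set.

    Two categories of edges concordant in at least one solution arrangement
    qualify: REARRANGED edges are discordant with the reference arrangement
    (a genuine rearrangement is needed to explain them); DISTANT edges are
    reference-concordant but join different chromosomes or segments more
    than ``max_distance`` bp apart, which alternative splicing cannot
    explain.  Everything else is splicing or noise and is not reported.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    ref = reference_arrangement(gsg)
    calls: list[TSVCall] = []
    for e in gsg.edges:
        alleles = tuple(i for i, arr in enumerate(A) if is_concordant(e, arr))
        if not alleles:
            continue
        if not is_concordant(e, ref):
            category = REARRANGED
        else:
            same_chrom = (
                gsg.segment(e.a.segment_id).chrom
                == gsg.segment(e.b.segment_id).chrom
            )
            if not same_chrom:
                category = DISTANT
            elif _gap(gsg, e) > max_distance:
                category = DISTANT
            else:
                continue  # explainable by alternative splicing
        calls.append(
            TSVCall(
                bp1=_breakpoint(gsg, e.a),
                bp2=_breakpoint(gsg, e.b),
                category=category,
                weight=e.weight,
                alleles=alleles,
                edge=e,
            )
        )
    calls.sort(key=lambda c: (c.bp1, c.bp2))
    return calls


# -- writers ---------------------------------------------------------------


def write_arrangements(A: ArrangementSet, stream: TextIO, header: str | None = None) -> None:
    """One line per allele: index then signed segment ids in rank order."""
    if header:
        stream.write(f"# {header}\n")
    for i, arr in enumerate(A):
        stream.write(f"{i}\t" + "\t".join(arr.signed_ids()) + "\n")


def write_bedpe(calls: Iterable[TSVCall], stream: TextIO, header: str | None = None) -> None:
    """BEDPE-style TSV call output.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand-free
    end-type pair, category, comma-joined allele indices.  Breakpoints are
    single positions, written as half-open 1 bp intervals.
    """
    if header:
        stream.write(f"# {header}\n")
    for c in calls:
        (c1, p1, _), (c2, p2, _) = c.bp1, c.bp2
        stream.write(
            "\t".join(
                [
                    c1, str(p1), str(p1 + 1),
                    c2, str(p2), str(p2 + 1),
                    c.name,
                    f"{c.weight:g}",
                    c.end_types,
                    c.category,
                    ",".join(map(str, c.alleles)),
                ]
            )
            + "\n"
        )
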