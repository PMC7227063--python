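"""Genome segment graph (GSG) data model and plain-text I/O.

A GSG is a weighted undirected graph whose vertices are the two endpoints
(head ``H``, nearer the 5' end; tail ``T``, nearer the 3' end) of genome
segments, and whose edges record read-supported adjacencies between segment
endpoints.  Segments partition each chromosome into disjoint intervals;
edge weights count the sequencing reads supporting the adjacency.

Text format (tab- or whitespace-separated, ``#`` starts a comment)::

    S  <id>  <chrom>  <start>  <end>
    E  <id1>  <H|T>  <id2>  <H|T>  <weight>

Coordinates are 0-based half-open.  Duplicate edge lines for the same
unordered endpoint pair are merged by summing their weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, TextIO

HEAD = "H"
TAIL = "T"

__all__ = [
    "HEAD",
    "TAIL",
    "Segment",
    "EndpointRef",
    "Edge",
    "GSG",
    "GSGError",
    "GSGParseError",
    "GSGValidationError",
    "GSGReferenceError",
    "parse_gsg",
    "parse_gsg_text",
    "write_gsg",
    "total_weight",
    "connected_components",
]


class GSGError(ValueError):
    """Base class for genome-segment-graph errors."""


class GSGParseError(GSGError):
    """Malformed text input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GSGValidationError(GSGError):
    """Structurally invalid graph (overlaps, bad weights, self edges)."""


class GSGReferenceError(GSGError):
    """An endpoint or edge refers to something not in the graph."""


@dataclass(frozen=True)
class Segment:
    """A genomic interval that moves as a unit under rearrangement."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.id:
            raise GSGValidationError("segment id must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise GSGValidationError(
                f"segment {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class EndpointRef(NamedTuple):
    """One end of a segment: ``H`` (5'-proximal) or ``T`` (3'-proximal)."""

    segment_id: str
    end: str

    def __str__(self) -> str:  # e.g. "u:T"
        return f"{self.segment_id}:{self.end}"


def _check_end(end: str) -> str:
    if end not in (HEAD, TAIL):
        raise GSGValidationError(f"endpoint end must be 'H' or 'T', got {end!r}")
    return end


@dataclass(frozen=True)
class Edge:
    """Unordered weighted edge between endpoints of two distinct segments.

    Endpoints are stored in a canonical (sorted) order so equal edges
    compare and hash equal regardless of input orientation.
    """

    a: EndpointRef
    b: EndpointRef
    weight: float

    def __post_init__(self) -> None:
        _check_end(self.a.end)
        _check_end(self.b.end)
        if self.a.segment_id == self.b.segment_id:
            raise GSGValidationError(
                f"within-segment edge on {self.a.segment_id!r} is not allowed"
            )
        if self.weight < 0:
            raise GSGValidationError(f"negative edge weight {self.weight}")
        if (self.b.segment_id, self.b.end) < (self.a.segment_id, self.a.end):
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def key(self) -> tuple[EndpointRef, EndpointRef]:
        """Canonical unordered-pair key (weight excluded)."""
        return (self.a, self.b)

    def endpoint_of(self, segment_id: str) -> EndpointRef:
        if self.a.segment_id == segment_id:
            return self.a
        if self.b.segment_id == segment_id:
            return self.b
        raise GSGReferenceError(f"edge {self} has no endpoint on {segment_id!r}")

    def __str__(self) -> str:
        return f"({self.a}--{self.b}, w={self.weight:g})"


@dataclass
class GSG:
    """A genome segment graph: segments plus weighted endpoint edges.

    ``chrom_order`` fixes the concatenation order of chromosomes used by
    the reference arrangement; by default it is first-appearance order.
    """

    segments: dict[str, Segment]
    edges: list[Edge]
    chrom_order: list[str] = field(default_factory=list)

    def __init__(
        self,
        segments: Iterable[Segment],
        edges: Iterable[Edge] = (),
        chrom_order: Sequence[str] | None = None,
    ):
        self.segments = {}
        for seg in segments:
            if seg.id in self.segments:
                raise GSGValidationError(f"duplicate segment id {seg.id!r}")
            self.segments[seg.id] = seg
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(s.chrom for s in self.segments.values()))
        else:
            chrom_order = list(chrom_order)
            missing = {s.chrom for s in self.segments.values()} - set(chrom_order)
            if missing:
                raise GSGValidationError(f"chrom_order missing {sorted(missing)}")
        self.chrom_order = chrom_order
        self._check_overlaps()
        # Merge duplicate edges (same unordered endpoint pair) by weight sum.
        merged: dict[tuple[EndpointRef, EndpointRef], float] = {}
        for e in edges:
            for ref in (e.a, e.b):
                if ref.segment_id not in self.segments:
                    raise GSGReferenceError(
                        f"edge endpoint {ref} references unknown segment"
                    )
            merged[e.key] = merged.get(e.key, 0.0) + e.weight
        self.edges = [Edge(a, b, w) for (a, b), w in merged.items()]

    def _check_overlaps(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments.values():
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: (s.start, s.end))
            for prev, cur in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise GSGValidationError(
                        f"segments {prev.id!r} and {cur.id!r} overlap on {chrom}"
                    )

    # -- convenience -----------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def segment(self, segment_id: str) -> Segment:
        try:
            return self.segments[segment_id]
        except KeyError:
            raise GSGReferenceError(f"unknown segment {segment_id!r}") from None

    def genomic_order(self) -> list[str]:
        """Segment ids sorted by (chromosome order, start coordinate)."""
        chrom_rank = {c: i for i, c in enumerate(self.chrom_order)}
        return sorted(
            self.segments,
            key=lambda sid: (chrom_rank[self.segments[sid].chrom],
                             self.segments[sid].start),
        )

    def edge_by_key(self, a: EndpointRef, b: EndpointRef) -> Edge:
        key = Edge(a, b, 0.0).key
        for e in self.edges:
            if e.key == key:
                return e
        raise GSGReferenceError(f"no edge between {a} and {b}")

    def with_weights(self, weights: dict[tuple[EndpointRef, EndpointRef], float]) -> "GSG":
        """Copy of this graph with some edge weights replaced (same topology)."""
        new_edges = [
            Edge(e.a, e.b, weights.get(e.key, e.weight)) for e in self.edges
        ]
        return GSG(self.segments.values(), new_edges, self.chrom_order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GSG):
            return NotImplemented
        return (
            self.segments == other.segments
            and {e.key: e.weight for e in self.edges}
            == {e.key: e.weight for e in other.edges}
            and self.chrom_order == other.chrom_order
        )


# -- I/O ------------------------------------------------------------------


def parse_gsg(stream: TextIO) -> GSG:
    """Parse a GSG from its plain-text representation.

    Raises :class:`GSGParseError` with the line number on malformed input,
    :class:`GSGReferenceError` for edges naming unknown segments, and
    :class:`GSGValidationError` for structural problems.
    """
    segments: list[Segment] = []
    raw_edges: list[tuple[int, str, str, str, str, float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        tag = fields[0]
        if tag == "S":
            if len(fields) != 5:
                raise GSGParseError(
                    f"segment record needs 4 fields, got {len(fields) - 1}", lineno
                )
            sid, chrom, start_s, end_s = fields[1:]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GSGParseError(
                    f"non-integer coordinate in {start_s!r}/{end_s!r}", lineno
                ) from None
            try:
                segments.append(Segment(sid, chrom, start, end))
            except GSGError as exc:
                raise GSGParseError(str(exc), lineno) from None
        elif tag == "E":
            if len(fields) != 6:
                raise GSGParseError(
                    f"edge record needs 5 fields, got {len(fields) - 1}", lineno
                )
            id1, end1, id2, end2, w_s = fields[1:]
            if end1 not in (HEAD, TAIL) or end2 not in (HEAD, TAIL):
                raise GSGParseError(f"endpoint end must be H or T", lineno)
            try:
                w = float(w_s)
            except ValueError:
                raise GSGParseError(f"non-numeric weight {w_s!r}", lineno) from None
            raw_edges.append((lineno, id1, end1, id2, end2, w))
        else:
            raise GSGParseError(f"unknown record type {tag!r}", lineno)
    seg_ids = {s.id for s in segments}
    edges = []
    for lineno, id1, end1, id2, end2, w in raw_edges:
        for sid in (id1, id2):
            if sid not in seg_ids:
                raise GSGReferenceError(
                    f"line {lineno}: edge references unknown segment {sid!r}"
                )
        try:
            edges.append(Edge(EndpointRef(id1, end1), EndpointRef(id2, end2), w))
        except GSGError as exc:
            raise GSGValidationError(f"line {lineno}: {exc}") from None
    return GSG(segments, edges)


def parse_gsg_text(text: str) -> GSG:
    import io

    return parse_gsg(io.StringIO(text))


def write_gsg(gsg: GSG, stream: TextIO) -> None:
    """Write a GSG in canonical order (segments genomic, edges lexicographic)."""
    for sid in gsg.genomic_order():
        seg = gsg.segments[sid]
        stream.write(f"S\t{seg.id}\t{seg.chrom}\t{seg.start}\t{seg.end}\n")
    for e in sorted(gsg.edges, key=lambda e: e.key):
        stream.write(
            f"E\t{e.a.segment_id}\t{e.a.end}\t{e.b.segment_id}\t{e.b.end}\t{e.weight:g}\n"
        )


# -- graph operations ------------------------------------------------------


def total_weight(gsg: GSG, subset: Iterable[Edge] | None = None) -> float:
    """Sum of edge weights, over the whole graph or an edge subset of it."""
    if subset is None:
        return sum(e.weight for e in gsg.edges)
    own = {e.key: e.weight for e in gsg.edges}
    tot = 0.0
    for e in subset:
        if e.key not in own:
            raise GSGReferenceError(f"edge {e} is not in the graph")
        tot += e.weight
    return tot


def connected_components(gsg: GSG) -> list[GSG]:
    """Split a GSG into connected components (segment connectivity via edges).

    Segments with no incident edge form singleton components.  Components
    are returned in genomic order of their first segment; their union
    reconstructs the input graph.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(gsg.segments)
    for e in gsg.edges:
        g.add_edge(e.a.segment_id, e.b.segment_id)
    order = {sid: i for i, sid in enumerate(gsg.genomic_order())}
    comps = sorted(nx.connected_components(g), key=lambda c: min(order[s] for s in c))
    out = []
    for comp in comps:
        segs = [gsg.segments[sid] for sid in sorted(comp, key=order.get)]
        edges = [e for e in gsg.edges if e.a.segment_id in comp]
        chroms = [c for c in gsg.chrom_order if any(s.chrom == c for s in segs)]
        out.append(GSG(segs, edges, chroms))
    return out
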