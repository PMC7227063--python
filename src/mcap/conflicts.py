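"""Conflict-structure detection and heterogeneity quantification.

For this analysis the segment graph is augmented with one *segment edge*
per segment joining its own head and tail, giving a perfect matching over
endpoint vertices.  Any acyclic subgraph can be satisfied by a single
arrangement, so conflicts — edge sets that no single arrangement can make
concordant, the signature of a sample with more than one allele — always
involve cycles.  A simple cycle is satisfiable by one arrangement exactly
when it has precisely two vertices of adjacency-edge degree 2 within the
cycle and those two vertices lie on different segments; a simple cycle
failing that test witnesses a conflict.

A discordant edge is classified by enumerating simple paths between its
endpoints (omitting the edge itself), closing each path into a simple
cycle with the edge, and testing each cycle.  Enumeration is depth-first
with a per-attempt wall-clock timeout; on timeout the neighbor order is
reshuffled (seeded) and the search rerun, and an edge whose enumeration
never completes within the rerun budget is labeled undecided.  Defaults:
0.5 s per attempt, 1000 reruns.

The fraction of discordant edges involved in conflicts measures how
heterogeneous the sample is.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field
from typing import Iterator

from .arrangement import is_concordant, reference_arrangement
from .gsg import GSG, Edge, EndpointRef, GSGReferenceError, HEAD, TAIL

__all__ = [
    "ADJACENCY",
    "SEGMENT",
    "IN_CONFLICT",
    "NOT_IN_CONFLICT",
    "UNDECIDED",
    "ConflictGraph",
    "SimpleCycle",
    "EdgeConflictLabel",
    "conflict_graph",
    "is_cycle_compatible",
    "classify_discordant_edge",
    "heterogeneity_fraction",
]

ADJACENCY = "adj"  # an edge of the segment graph proper (read support)
SEGMENT = "seg"  # an auxiliary head-tail edge within one segment

IN_CONFLICT = "IN_CONFLICT"
NOT_IN_CONFLICT = "NOT_IN_CONFLICT"
UNDECIDED = "UNDECIDED"

DEFAULT_TIMEOUT = 0.5
DEFAULT_MAX_RERUNS = 1000


@dataclass
class ConflictGraph:
    """A GSG plus its segment edges, as an endpoint-vertex adjacency map."""

    gsg: GSG
    adjacency: dict[EndpointRef, list[tuple[EndpointRef, str, object]]]

    @property
    def n_segment_edges(self) -> int:
        return self.gsg.n_segments

    def discordant_edges(self) -> list[Edge]:
        """Edges discordant with the reference arrangement."""
        if self.gsg.n_segments == 0:
            return []
        ref = reference_arrangement(self.gsg)
        return [e for e in self.gsg.edges if not is_concordant(e, ref)]


def conflict_graph(gsg: GSG) -> ConflictGraph:
    adj: dict[EndpointRef, list[tuple[EndpointRef, str, object]]] = {}
    for sid in gsg.segments:
        h, t = EndpointRef(sid, HEAD), EndpointRef(sid, TAIL)
        adj[h] = [(t, SEGMENT, None)]
        adj[t] = [(h, SEGMENT, None)]
    for e in gsg.edges:
        adj[e.a].append((e.b, ADJACENCY, e.key))
        adj[e.b].append((e.a, ADJACENCY, e.key))
    return ConflictGraph(gsg, adj)


@dataclass(frozen=True)
class SimpleCycle:
    """A closed walk with pairwise-distinct vertices.

    ``kinds[i]`` labels the edge joining ``vertices[i]`` and
    ``vertices[(i+1) % n]`` as an adjacency edge or a segment edge.
    """

    vertices: tuple[EndpointRef, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) != len(self.kinds) or len(self.vertices) < 2:
            raise ValueError("cycle needs one edge kind per vertex (>= 2)")
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("cycle vertices must be pairwise distinct")

    def adjacency_degrees(self) -> dict[EndpointRef, int]:
        """Per-vertex count of incident cycle edges that are adjacency edges."""
        n = len(self.vertices)
        return {
            v: int(self.kinds[i - 1] == ADJACENCY) + int(self.kinds[i] == ADJACENCY)
            for i, v in enumerate(self.vertices)
        }


def is_cycle_compatible(cycle: SimpleCycle) -> bool:
    """Single-arrangement satisfiability test for a simple cycle.

    True iff exactly two cycle vertices have adjacency-edge degree 2 within
    the cycle and those two vertices belong to different segments (they
    become the 5'-most tail and 3'-most head of the satisfying arrangement).
    """
    deg2 = [v for v, d in cycle.adjacency_degrees().items() if d == 2]
    return len(deg2) == 2 and deg2[0].segment_id != deg2[1].segment_id


@dataclass(frozen=True)
class EdgeConflictLabel:
    edge: Edge
    label: str  # IN_CONFLICT | NOT_IN_CONFLICT | UNDECIDED
    witness: SimpleCycle | None = None
    attempts: int = 1

    def __post_init__(self) -> None:
        if self.label == IN_CONFLICT and self.witness is None:
            raise ValueError("IN_CONFLICT requires a witness cycle")


class _Timeout(Exception):
    pass


def _simple_paths(
    cg: ConflictGraph,
    start: EndpointRef,
    goal: EndpointRef,
    skip_key,
    deadline: float,
    rng: random.Random | None,
) -> Iterator[tuple[list[EndpointRef], list[str]]]:
    """DFS enumeration of simple paths start -> goal avoiding edge skip_key.

    Raises :class:`_Timeout` when the wall clock passes ``deadline``.
    Neighbor order is sorted by default or shuffled when ``rng`` is given.
    """

    def ordered(v: EndpointRef):
        nbrs = list(cg.adjacency.get(v, ()))
        nbrs.sort(key=lambda item: (item[0], item[1]))
        if rng is not None:
            rng.shuffle(nbrs)
        return iter(nbrs)

    path = [start]
    kinds: list[str] = []
    visited = {start}
    stack = [ordered(start)]
    while stack:
        if time.monotonic() >= deadline:
            raise _Timeout
        item = next(stack[-1], None)
        if item is None:
            stack.pop()
            visited.discard(path.pop())
            if kinds:
                kinds.pop()
            continue
        nb, kind, ekey = item
        if kind == ADJACENCY and ekey == skip_key:
            continue
        if nb == goal:
            yield path + [nb], kinds + [kind]
            continue
        if nb in visited:
            continue
        path.append(nb)
        kinds.append(kind)
        visited.add(nb)
        stack.append(ordered(nb))


def classify_discordant_edge(
    cg: ConflictGraph,
    e: Edge,
    timeout: float = DEFAULT_TIMEOUT,
    max_reruns: int = DEFAULT_MAX_RERUNS,
    seed: int = 0,
) -> EdgeConflictLabel:
    """Label one reference-discordant edge by cycle enumeration.

    Every simple path between the edge's endpoints (edge omitted) closes
    into a simple cycle through the edge; the first cycle failing the
    compatibility test yields IN_CONFLICT with that witness.  Exhaustive
    enumeration without such a cycle yields NOT_IN_CONFLICT.  An attempt
    that outlives ``timeout`` seconds is retried with reshuffled neighbor
    order until ``max_reruns`` extra attempts are spent, then UNDECIDED.
    """
    own = {edge.key for edge in cg.gsg.edges}
    if e.key not in own:
        raise GSGReferenceError(f"edge {e} is not in the graph")
    ref = reference_arrangement(cg.gsg)
    if is_concordant(e, ref):
        raise ValueError(f"edge {e} is concordant with the reference")
    attempt = 0
    while attempt <= max_reruns:
        rng = random.Random((seed * 1_000_003 + attempt) & 0x7FFFFFFF) if attempt else None
        deadline = time.monotonic() + timeout
        try:
            for path, kinds in _simple_paths(cg, e.a, e.b, e.key, deadline, rng):
                cycle = SimpleCycle(tuple(path), tuple(kinds) + (ADJACENCY,))
                if not is_cycle_compatible(cycle):
                    return EdgeConflictLabel(e, IN_CONFLICT, cycle, attempt + 1)
            return EdgeConflictLabel(e, NOT_IN_CONFLICT, None, attempt + 1)
        except _Timeout:
            attempt += 1
    return EdgeConflictLabel(e, UNDECIDED, None, attempt)


def heterogeneity_fraction(
    cg: ConflictGraph,
    timeout: float = DEFAULT_TIMEOUT,
    max_reruns: int = DEFAULT_MAX_RERUNS,
    seed: int = 0,
) -> tuple[float, dict[str, int], list[EdgeConflictLabel]]:
    """Classify every reference-discordant edge; return the fraction that
    sit in conflict structures, the per-label tally and all labels.

    The fraction is 0.0 when the graph has no discordant edges.
    """
    counts = {IN_CONFLICT: 0, NOT_IN_CONFLICT: 0, UNDECIDED: 0}
    labels: list[EdgeConflictLabel] = []
    discordant = cg.discordant_edges()
    for i, e in enumerate(discordant):
        lab = classify_discordant_edge(
            cg, e, timeout=timeout, max_reruns=max_reruns, seed=seed + i
        )
        counts[lab.label] += 1
        labels.append(lab)
    frac = counts[IN_CONFLICT] / len(discordant) if discordant else 0.0
    return frac, counts, labels
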