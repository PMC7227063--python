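"""Greedy approximation solvers for single- and multi-arrangement problems.

The end-placement greedy places segments one at a time at either end of
the current order, in either orientation (4 options); picking the best of
the four keeps at least a quarter of the weight of the edges joining the
new segment to the already-placed ones, which yields the w(E)/4 floor and
hence a 1/4-approximation of the single-arrangement optimum.  The
insertion greedy widens the candidate set to every insertion position
(it subsumes the four end options, so the same floor applies).  The
iterative solver obtains k arrangements by repeatedly solving the
single-arrangement problem on a residual graph in which already-satisfied
edges have weight zero; with an exact single-arrangement oracle and k=2
this is a 3/4-approximation of the two-arrangement optimum, and with the
end-placement greedy as the oracle a 3/16-approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, TextIO

from .arrangement import Arrangement, ArrangementSet, is_concordant
from .gsg import GSG, Edge, connected_components

__all__ = [
    "GreedyStep",
    "GreedyTrace",
    "scap_greedy_ends",
    "scap_greedy_insert",
    "mcap_iterative",
]

# option labels for the end-placement greedy, in tie-break priority order
_END_OPTIONS = ("append/1", "append/0", "prepend/1", "prepend/0")


@dataclass(frozen=True)
class GreedyStep:
    """One iteration: the placed segment, all candidate gains, the choice."""

    segment_id: str
    labels: tuple[str, ...]
    gains: tuple[float, ...]
    chosen: str

    @property
    def incident_weight(self) -> float:
        """For the end-placement greedy the 4 gains partition the weight of
        all edges joining this segment to previously placed ones."""
        return sum(self.gains)


@dataclass
class GreedyTrace:
    steps: list[GreedyStep] = field(default_factory=list)

    def to_tsv(self, stream: TextIO) -> None:
        stream.write("segment\tchosen\t" "options\n")
        for s in self.steps:
            opts = ";".join(f"{l}={g:g}" for l, g in zip(s.labels, s.gains))
            stream.write(f"{s.segment_id}\t{s.chosen}\t{opts}\n")


def _check_order(gsg: GSG, order: Sequence[str] | None) -> list[str]:
    if order is None:
        return gsg.genomic_order()
    order = list(order)
    if sorted(order) != sorted(gsg.segments):
        raise ValueError("order must be a permutation of the graph's segments")
    return order


def _incident(edges: list[Edge]) -> dict[str, list[Edge]]:
    inc: dict[str, list[Edge]] = {}
    for e in edges:
        inc.setdefault(e.a.segment_id, []).append(e)
        inc.setdefault(e.b.segment_id, []).append(e)
    return inc


def _gain(
    edges: list[Edge],
    placed_order: list[str],
    orient: dict[str, int],
    new_sid: str,
    placed_set: set[str],
) -> float:
    """Weight of the new segment's edges to placed segments made concordant
    by the tentative arrangement ``placed_order``/``orient``."""
    arr = Arrangement(tuple(placed_order), dict(orient))
    total = 0.0
    for e in edges:
        other = e.b.segment_id if e.a.segment_id == new_sid else e.a.segment_id
        if other in placed_set and is_concordant(e, arr):
            total += e.weight
    return total


def _greedy_component(
    edges: list[Edge], order: list[str], insert: bool
) -> tuple[list[str], dict[str, int], list[GreedyStep]]:
    inc = _incident(edges)
    placed: list[str] = []
    orient: dict[str, int] = {}
    placed_set: set[str] = set()
    steps: list[GreedyStep] = []
    for sid in order:
        if not placed:
            placed.append(sid)
            orient[sid] = 1
            placed_set.add(sid)
            steps.append(GreedyStep(sid, (), (), "first"))
            continue
        my_edges = inc.get(sid, [])
        if insert:
            labels = []
            candidates = []
            for pos in range(len(placed) + 1):
                for o in (1, 0):
                    labels.append(f"ins{pos}/{o}")
                    candidates.append((pos, o))
        else:
            labels = list(_END_OPTIONS)
            candidates = [(len(placed), 1), (len(placed), 0), (0, 1), (0, 0)]
        gains = []
        for pos, o in candidates:
            tentative = placed[:pos] + [sid] + placed[pos:]
            orient[sid] = o
            gains.append(_gain(my_edges, tentative, orient, sid, placed_set))
        best = max(range(len(gains)), key=lambda i: (gains[i], -i))
        pos, o = candidates[best]
        placed.insert(pos, sid)
        orient[sid] = o
        placed_set.add(sid)
        steps.append(GreedyStep(sid, tuple(labels), tuple(gains), labels[best]))
    return placed, orient, steps


def _greedy(
    gsg: GSG, order: Sequence[str] | None, insert: bool
) -> tuple[Arrangement, GreedyTrace]:
    order = _check_order(gsg, order)
    order_pos = {sid: i for i, sid in enumerate(order)}
    full_order: list[str] = []
    full_orient: dict[str, int] = {}
    trace = GreedyTrace()
    # each connected component is an independent subproblem; results are
    # composed in genomic order (no edges cross components)
    for comp in connected_components(gsg):
        comp_order = sorted(comp.segments, key=order_pos.get)
        placed, orient, steps = _greedy_component(comp.edges, comp_order, insert)
        full_order.extend(placed)
        full_orient.update(orient)
        trace.steps.extend(steps)
    return Arrangement(tuple(full_order), full_orient), trace


def scap_greedy_ends(
    gsg: GSG, order: Sequence[str] | None = None
) -> tuple[Arrangement, GreedyTrace]:
    """End-placement greedy (4 options per segment); >= w(E)/4 guaranteed.

    ``order`` is the segment processing order (default: genomic order).
    Ties prefer append over prepend and original orientation over inverted.
    """
    return _greedy(gsg, order, insert=False)


def scap_greedy_insert(
    gsg: GSG, order: Sequence[str] | None = None
) -> tuple[Arrangement, GreedyTrace]:
    """Insertion greedy: every insertion position x both orientations.

    The candidate set contains the four end-placement options, so the
    w(E)/4 floor carries over; in practice it often does better.  Ties
    prefer the lowest insertion index, original orientation first.
    """
    return _greedy(gsg, order, insert=True)


Oracle = Callable[[GSG], "Arrangement | tuple"]


def _call_oracle(oracle: Oracle, gsg: GSG) -> Arrangement:
    out = oracle(gsg)
    if isinstance(out, Arrangement):
        return out
    return out[0]


def mcap_iterative(gsg: GSG, k: int, oracle: Oracle | None = None) -> ArrangementSet:
    """k arrangements by iterated single-arrangement solving on residuals.

    Round i solves the single-arrangement problem on a copy of the graph
    in which every edge already concordant in an earlier round has weight
    zero (topology is kept so the oracle sees the same graph structure).
    With an exact oracle and k=2 the objective is >= 3/4 of the
    two-arrangement optimum; with :func:`scap_greedy_ends` as the oracle,
    >= 3/16.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if oracle is None:
        oracle = scap_greedy_ends
    residual = gsg
    arrangements = []
    satisfied: set = set()
    for _ in range(k):
        arr = _call_oracle(oracle, residual)
        arrangements.append(arr)
        for e in gsg.edges:
            if e.key not in satisfied and is_concordant(e, arr):
                satisfied.add(e.key)
        residual = gsg.with_weights({key: 0.0 for key in satisfied})
    return ArrangementSet(arrangements)
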