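"""Exhaustive exact solvers for small instances.

These enumerate all ``n! * 2**n`` arrangements of an n-segment graph and
serve as the ground-truth oracle for the approximation-ratio, ILP-exactness
and conflict-structure tests.  The k-arrangement optimum is computed as a
maximum-weight union over k concordant-edge masks (arrangements with equal
masks are interchangeable for the objective, and masks dominated by a
superset can never help), which keeps the search far below
``(n! * 2**n) ** k``.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from .arrangement import Arrangement, ArrangementSet
from .gsg import GSG, HEAD, TAIL

__all__ = ["SizeCapError", "scap_exact", "mcap_exact", "enumerate_masks"]

DEFAULT_SCAP_CAP = 8
DEFAULT_MCAP_CAP = 5


class SizeCapError(ValueError):
    """Instance exceeds the configured exhaustive-search size cap."""


def _setup(gsg: GSG):
    sids = gsg.genomic_order()
    idx = {s: i for i, s in enumerate(sids)}
    n = len(sids)
    # orientation matrix: row m, column j = orientation bit of segment j
    O = ((np.arange(1 << n)[:, None] >> np.arange(n)) & 1).astype(bool)
    edges = [
        (idx[e.a.segment_id], e.a.end == TAIL, idx[e.b.segment_id], e.b.end == TAIL)
        for e in gsg.edges
    ]
    w = np.array([e.weight for e in gsg.edges], dtype=float)
    return sids, n, O, edges, w


def _perm_concordance(perm: tuple[int, ...], O: np.ndarray, edges) -> np.ndarray:
    """(2**n, |E|) concordance table for one permutation over all orientations."""
    pos = [0] * len(perm)
    for rank, j in enumerate(perm):
        pos[j] = rank
    cols = []
    for u, a_tail, v, b_tail in edges:
        if pos[u] < pos[v]:
            cu, cv = a_tail, not b_tail  # orient(u)=1[a=T], orient(v)=1[b=H]
        else:
            cu, cv = not a_tail, b_tail
        cols.append((O[:, u] == cu) & (O[:, v] == cv))
    return np.column_stack(cols)


def enumerate_masks(gsg: GSG) -> Iterator[tuple[tuple[int, ...], int, int]]:
    """Yield (permutation, orientation-int, concordant-edge bitmask) for every
    arrangement, in lexicographic enumeration order."""
    sids, n, O, edges, _ = _setup(gsg)
    if not edges:
        for perm in itertools.permutations(range(n)):
            for m in range(1 << n):
                yield perm, m, 0
        return
    bits = 1 << np.arange(len(edges), dtype=np.int64)
    for perm in itertools.permutations(range(n)):
        conc = _perm_concordance(perm, O, edges)
        masks = conc @ bits
        for m, mask in enumerate(masks):
            yield perm, m, int(mask)


def _build_arrangement(gsg: GSG, sids, perm: tuple[int, ...], m: int) -> Arrangement:
    order = tuple(sids[j] for j in perm)
    orient = {sids[j]: (m >> j) & 1 for j in range(len(sids))}
    return Arrangement(order, orient)


def _check_cap(gsg: GSG, cap: int) -> None:
    if gsg.n_segments > cap:
        raise SizeCapError(
            f"{gsg.n_segments} segments exceeds the exhaustive-search cap of {cap}"
        )


def scap_exact(gsg: GSG, max_segments: int = DEFAULT_SCAP_CAP) -> tuple[Arrangement, float]:
    """Optimal single arrangement (k=1) by full enumeration.

    Ties are broken by enumeration order, so the result is deterministic.
    """
    _check_cap(gsg, max_segments)
    sids, n, O, edges, w = _setup(gsg)
    if n == 0:
        return Arrangement((), {}), 0.0
    if not edges:
        return _build_arrangement(gsg, sids, tuple(range(n)), (1 << n) - 1), 0.0
    best = (-1.0, None, None)
    for perm in itertools.permutations(range(n)):
        scores = _perm_concordance(perm, O, edges) @ w
        m = int(np.argmax(scores))
        if scores[m] > best[0] + 1e-12:
            best = (float(scores[m]), perm, m)
    return _build_arrangement(gsg, sids, best[1], best[2]), best[0]


def _mask_weight(mask: int, w: np.ndarray) -> float:
    tot = 0.0
    i = 0
    while mask:
        if mask & 1:
            tot += w[i]
        mask >>= 1
        i += 1
    return tot


def mcap_exact(
    gsg: GSG, k: int, max_segments: int = DEFAULT_MCAP_CAP
) -> tuple[ArrangementSet, float]:
    """Optimal set of k arrangements by mask enumeration + k-subset search.

    Deduplicates concordant-edge masks, drops masks contained in another
    mask (dominated for a union objective), then takes the best union over
    k of the remaining masks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_cap(gsg, max_segments)
    sids, n, O, edges, w = _setup(gsg)
    if n == 0:
        return ArrangementSet([Arrangement((), {})] * k), 0.0
    if not edges:
        ref = _build_arrangement(gsg, sids, tuple(range(n)), (1 << n) - 1)
        return ArrangementSet([ref] * k), 0.0
    bits = 1 << np.arange(len(edges), dtype=np.int64)
    reps: dict[int, tuple[tuple[int, ...], int]] = {}
    for perm in itertools.permutations(range(n)):
        conc = _perm_concordance(perm, O, edges)
        masks = conc @ bits
        for m, mask in enumerate(masks):
            mask = int(mask)
            if mask not in reps:
                reps[mask] = (perm, m)
    # prune dominated masks (subset of another distinct mask)
    keys = list(reps)
    maximal = [
        a for a in keys if not any(a != b and (a & b) == a for b in keys)
    ]
    take = min(k, len(maximal))
    best = (-1.0, None)
    for combo in itertools.combinations(maximal, take):
        union = 0
        for mask in combo:
            union |= mask
        val = _mask_weight(union, w)
        if val > best[0] + 1e-12:
            best = (val, combo)
    arrs = [_build_arrangement(gsg, sids, *reps[mask]) for mask in best[1]]
    while len(arrs) < k:
        arrs.append(arrs[0])  # padding: extra alleles add nothing
    return ArrangementSet(arrs), best[0]
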