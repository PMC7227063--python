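"""Shared fixtures: the two-segment conflicting-edge example and helpers.

The ``conflict_pair`` graph is the canonical worked example: segments u, v on one
chromosome joined by a tail-tail edge (weight 3) and a head-head edge
(weight 2).  Neither edge is concordant with the reference, no single
arrangement satisfies both, and two arrangements satisfy both — the
smallest instance where modeling two alleles pays off.
"""

from __future__ import annotations

import random

import pytest

from mcap.gsg import GSG, Edge, EndpointRef, Segment, parse_gsg_text

CONFLICT_PAIR_TEXT = """\
# two segments, two mutually conflicting edges
S\tu\tchr1\t0\t100
S\tv\tchr1\t100\t200
E\tu\tT\tv\tT\t3
E\tu\tH\tv\tH\t2
"""


@pytest.fixture
def conflict_pair() -> GSG:
    return parse_gsg_text(CONFLICT_PAIR_TEXT)


@pytest.fixture
def conflict_pair_text() -> str:
    return CONFLICT_PAIR_TEXT


def make_gsg(seg_ids, edge_specs, chrom="chr1"):
    """Compact constructor: edge_specs = [(id1, end1, id2, end2, w), ...]."""
    segs = [
        Segment(sid, chrom, 100 * i, 100 * (i + 1)) for i, sid in enumerate(seg_ids)
    ]
    edges = [
        Edge(EndpointRef(a, ea), EndpointRef(b, eb), w)
        for a, ea, b, eb, w in edge_specs
    ]
    return GSG(segs, edges)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)
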