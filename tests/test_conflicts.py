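"""Conflict structures: cycle compatibility vs. exhaustive search, the
acyclic-subgraph property, and the timeout/rerun labeling procedure."""

import random

import pytest

from mcap.brute import scap_exact
from mcap.conflicts import (
    ADJACENCY,
    IN_CONFLICT,
    NOT_IN_CONFLICT,
    SEGMENT,
    UNDECIDED,
    SimpleCycle,
    classify_discordant_edge,
    conflict_graph,
    heterogeneity_fraction,
    is_cycle_compatible,
)
from mcap.gsg import Edge, EndpointRef, GSGReferenceError, Segment, GSG, \
    parse_gsg_text, total_weight
from mcap.simulate import random_simple_cycle

from .conftest import CONFLICT_PAIR_TEXT, make_gsg


def cycle_is_satisfiable(gsg):
    """Oracle: one arrangement makes every adjacency edge concordant."""
    return abs(scap_exact(gsg)[1] - total_weight(gsg)) < 1e-9


class TestCycleCompatibility:
    def test_conflict_pair_cycle_is_a_conflict(self):
        cyc = SimpleCycle(
            (
                EndpointRef("u", "H"),
                EndpointRef("v", "H"),
                EndpointRef("v", "T"),
                EndpointRef("u", "T"),
            ),
            (ADJACENCY, SEGMENT, ADJACENCY, SEGMENT),
        )
        assert not is_cycle_compatible(cyc)

    def test_parallel_edge_two_cycle_is_compatible(self):
        # two parallel tail-head edges, as they exist before weight merging
        cyc = SimpleCycle(
            (EndpointRef("u", "T"), EndpointRef("v", "H")),
            (ADJACENCY, ADJACENCY),
        )
        assert is_cycle_compatible(cyc)

    def test_two_junctions_same_segment_is_a_conflict(self, rng):
        cyc, gsg = random_simple_cycle(random.Random(42), n_junctions=2)
        # whatever the draw, the criterion verdict must match the oracle
        assert is_cycle_compatible(cyc) == cycle_is_satisfiable(gsg)

    @pytest.mark.parametrize("n_junctions", [0, 1, 2])
    def test_agreement_with_exhaustive_search(self, n_junctions):
        """On cycles with at most two junction vertices (vertices carrying
        two of the cycle's adjacency edges) the two-junction criterion
        matches single-arrangement satisfiability exactly."""
        rng = random.Random(1000 + n_junctions)
        for _ in range(80):
            cyc, gsg = random_simple_cycle(rng, n_junctions=n_junctions)
            assert is_cycle_compatible(cyc) == cycle_is_satisfiable(gsg)

    def test_criterion_is_conservative_beyond_two_junctions(self):
        """Known limitation: with three or more junction vertices the
        criterion can flag a satisfiable cycle as a conflict, because a
        junction may carry two concordant edges at once (the splicing
        allowance).  Pin one such cycle: four all-junction vertices whose
        edges are satisfied by inverting one segment."""
        verts = (
            EndpointRef("s0", "T"),
            EndpointRef("s1", "H"),
            EndpointRef("s2", "H"),
            EndpointRef("s3", "H"),
        )
        cyc = SimpleCycle(verts, (ADJACENCY,) * 4)
        g = make_gsg(
            ["s0", "s1", "s2", "s3"],
            [
                ("s0", "T", "s1", "H", 1),
                ("s1", "H", "s2", "H", 1),
                ("s2", "H", "s3", "H", 1),
                ("s0", "T", "s3", "H", 1),
            ],
        )
        assert cycle_is_satisfiable(g)  # order s2(inv), s0, s1, s3 works
        assert not is_cycle_compatible(cyc)  # ... yet the criterion says no

    def test_non_simple_cycle_rejected(self):
        with pytest.raises(ValueError):
            SimpleCycle(
                (EndpointRef("u", "T"), EndpointRef("u", "T")),
                (ADJACENCY, ADJACENCY),
            )


class TestAcyclicSubgraphs:
    def test_random_forests_are_always_satisfiable(self):
        """Any edge set that is acyclic together with the segment edges is
        satisfiable by a single arrangement (leaf segments can always be
        placed at one of the four end options)."""
        rng = random.Random(77)
        for _ in range(100):
            n = rng.randint(2, 3)  # up to 6 endpoint vertices
            segs = [Segment(f"s{i}", "chr1", 100 * i, 100 * (i + 1))
                    for i in range(n)]
            order = list(range(n))
            rng.shuffle(order)
            edges = []
            for i in range(1, n):
                if rng.random() < 0.85:  # forest over segments
                    j = rng.choice(order[:i])
                    edges.append(
                        Edge(
                            EndpointRef(f"s{order[i]}", rng.choice("HT")),
                            EndpointRef(f"s{j}", rng.choice("HT")),
                            rng.randint(1, 5),
                        )
                    )
            g = GSG(segs, edges)
            assert abs(scap_exact(g)[1] - total_weight(g)) < 1e-9


class TestClassification:
    def test_conflict_pair_both_edges_in_conflict_with_witness(self, conflict_pair):
        cg = conflict_graph(conflict_pair)
        for e in cg.discordant_edges():
            lab = classify_discordant_edge(cg, e)
            assert lab.label == IN_CONFLICT
            assert len(lab.witness.vertices) == 4
            assert not is_cycle_compatible(lab.witness)

    def test_lone_discordant_edge_not_in_conflict(self):
        g = parse_gsg_text("S u chr1 0 100\nS v chr1 100 200\nE u T v T 3\n")
        cg = conflict_graph(g)
        lab = classify_discordant_edge(cg, g.edges[0])
        assert lab.label == NOT_IN_CONFLICT and lab.witness is None

    def test_zero_timeout_exhausts_rerun_budget(self, conflict_pair):
        cg = conflict_graph(conflict_pair)
        lab = classify_discordant_edge(cg, conflict_pair.edges[0], timeout=0.0, max_reruns=1)
        assert lab.label == UNDECIDED
        assert lab.attempts == 2  # the initial attempt plus one rerun

    def test_concordant_edge_rejected(self):
        g = make_gsg("ab", [("a", "T", "b", "H", 1)])
        cg = conflict_graph(g)
        with pytest.raises(ValueError, match="concordant"):
            classify_discordant_edge(cg, g.edges[0])

    def test_foreign_edge_rejected(self, conflict_pair):
        cg = conflict_graph(conflict_pair)
        alien = Edge(EndpointRef("u", "T"), EndpointRef("v", "H"), 1)
        with pytest.raises(GSGReferenceError):
            classify_discordant_edge(cg, alien)

    def test_deterministic_with_fixed_seed(self, conflict_pair):
        cg = conflict_graph(conflict_pair)
        runs = [heterogeneity_fraction(cg, seed=5) for _ in range(2)]
        assert runs[0][0] == runs[1][0]
        assert [l.label for l in runs[0][2]] == [l.label for l in runs[1][2]]


class TestHeterogeneityFraction:
    def test_conflict_pair_fully_conflicted(self, conflict_pair):
        frac, counts, labels = heterogeneity_fraction(conflict_graph(conflict_pair))
        assert frac == 1.0
        assert counts == {IN_CONFLICT: 2, NOT_IN_CONFLICT: 0, UNDECIDED: 0}

    def test_concordant_graph_scores_zero(self):
        g = make_gsg("abc", [("a", "T", "b", "H", 1), ("b", "T", "c", "H", 1)])
        frac, counts, _ = heterogeneity_fraction(conflict_graph(g))
        assert frac == 0.0 and sum(counts.values()) == 0

    def test_isolated_discordant_pair_dilutes_fraction(self, conflict_pair_text):
        text = conflict_pair_text + (
            "S p chr1 300 400\nS q chr1 400 500\nE p T q T 2\n"
        )
        g = parse_gsg_text(text)
        frac, counts, _ = heterogeneity_fraction(conflict_graph(g))
        assert frac == pytest.approx(2 / 3)
        assert counts[NOT_IN_CONFLICT] == 1

    def test_labels_partition_discordant_edges(self, conflict_pair_text):
        g = parse_gsg_text(conflict_pair_text + "S z chr1 300 350\nE u H z T 1\n")
        cg = conflict_graph(g)
        frac, counts, labels = heterogeneity_fraction(cg)
        assert sum(counts.values()) == len(cg.discordant_edges()) == len(labels)
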