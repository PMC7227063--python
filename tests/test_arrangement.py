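"""Arrangement semantics: concordance, objective, reversal, TSV calling."""

import itertools

import pytest

from mcap.arrangement import (
    Arrangement,
    ArrangementSet,
    DISTANT,
    REARRANGED,
    call_tsvs,
    is_concordant,
    objective_value,
    reference_arrangement,
    reverse_arrangement,
)
from mcap.gsg import Edge, EndpointRef, GSGReferenceError, parse_gsg_text, total_weight

from .conftest import make_gsg


def arr(order, orients):
    return Arrangement(tuple(order), dict(zip(order, orients)))


def all_arrangements(seg_ids):
    for perm in itertools.permutations(seg_ids):
        for bits in itertools.product((0, 1), repeat=len(seg_ids)):
            yield arr(perm, bits)


class TestReferenceArrangement:
    def test_conflict_pair_parse(self, conflict_pair):
        ref = reference_arrangement(conflict_pair)
        assert ref.rank == {"u": 0, "v": 1}
        assert ref.orient == {"u": 1, "v": 1}

    def test_two_chromosomes_concatenate_in_order(self):
        g = parse_gsg_text(
            "S a chrA 0 10\nS b chrB 0 10\nS c chrA 50 60\n"
        )
        assert reference_arrangement(g).order == ("a", "c", "b")

    def test_empty_graph(self):
        g = parse_gsg_text("")
        assert reference_arrangement(g).order == ()


class TestConcordance:
    @pytest.mark.parametrize(
        "ends, orients, expected",
        [
            (("T", "T"), (1, 0), True),   # flip the later segment: TT satisfied
            (("H", "H"), (0, 1), True),   # flip the earlier segment: HH satisfied
            (("T", "H"), (1, 1), True),   # tail-head is the reference pattern
            (("T", "T"), (1, 1), False),  # TT discordant without a flip
            (("H", "T"), (1, 1), False),  # head-tail needs both inverted
            (("H", "T"), (0, 0), True),
        ],
    )
    def test_two_segment_cases(self, ends, orients, expected):
        e = Edge(EndpointRef("u", ends[0]), EndpointRef("v", ends[1]), 1)
        assert is_concordant(e, arr(["u", "v"], orients)) is expected

    def test_tt_discordant_in_reference(self, conflict_pair):
        ref = reference_arrangement(conflict_pair)
        tt = conflict_pair.edge_by_key(EndpointRef("u", "T"), EndpointRef("v", "T"))
        hh = conflict_pair.edge_by_key(EndpointRef("u", "H"), EndpointRef("v", "H"))
        assert not is_concordant(tt, ref)
        assert not is_concordant(hh, ref)

    def test_missing_segment_raises(self, conflict_pair):
        e = conflict_pair.edges[0]
        with pytest.raises(GSGReferenceError):
            is_concordant(e, arr(["u"], [1]))

    def test_reversal_symmetry_exhaustive(self):
        """Concordance is invariant under reversing the whole arrangement.

        Checked exhaustively: all 4 end-type pairs x all arrangements of
        4 segments (384 arrangements)."""
        seg_ids = ["a", "b", "c", "d"]
        edges = [
            Edge(EndpointRef("a", ea), EndpointRef("c", eb), 1)
            for ea in "HT"
            for eb in "HT"
        ]
        for a in all_arrangements(seg_ids):
            r = reverse_arrangement(a)
            for e in edges:
                assert is_concordant(e, a) == is_concordant(e, r)

    def test_reverse_is_involution(self):
        a = arr(["a", "b", "c"], [1, 0, 1])
        assert reverse_arrangement(reverse_arrangement(a)) == a
        single = arr(["a"], [1])
        assert reverse_arrangement(single).orient == {"a": 0}

    def test_exactly_one_of_four_placements_satisfies_an_edge(self):
        """For a fixed placed segment (either orientation) and any end-type
        pair, exactly one of {prepend, append} x {orient 1, orient 0}
        makes the connecting edge concordant."""
        for prior_orient in (0, 1):
            for ea, eb in itertools.product("HT", repeat=2):
                e = Edge(EndpointRef("new", ea), EndpointRef("old", eb), 1)
                hits = 0
                for position in ("prepend", "append"):
                    for o in (0, 1):
                        order = (
                            ["new", "old"] if position == "prepend" else ["old", "new"]
                        )
                        a = Arrangement(
                            tuple(order), {"old": prior_orient, "new": o}
                        )
                        hits += is_concordant(e, a)
                assert hits == 1


class TestObjective:
    def test_conflict_pair_reference_scores_zero(self, conflict_pair):
        val, sat = objective_value(conflict_pair, ArrangementSet([reference_arrangement(conflict_pair)]))
        assert val == 0 and sat == set()

    def test_conflict_pair_single_flip_scores_tt(self, conflict_pair):
        a = arr(["u", "v"], [1, 0])  # later segment inverted
        val, sat = objective_value(conflict_pair, ArrangementSet([a]))
        assert val == 3
        assert {e.a.end + e.b.end for e in sat} == {"TT"}

    def test_conflict_pair_two_arrangements_score_everything(self, conflict_pair):
        A = ArrangementSet([arr(["u", "v"], [1, 0]), arr(["u", "v"], [0, 1])])
        val, sat = objective_value(conflict_pair, A)
        assert val == total_weight(conflict_pair) == 5
        assert len(sat) == 2

    def test_concordant_discordant_partition(self, conflict_pair, rng):
        from mcap.simulate import random_gsg

        for _ in range(10):
            g = random_gsg(rng, 4, 6)
            for a in [reference_arrangement(g), arr(g.genomic_order(), [0, 1, 0, 1])]:
                sat = [e for e in g.edges if is_concordant(e, a)]
                unsat = [e for e in g.edges if not is_concordant(e, a)]
                assert total_weight(g, sat) + total_weight(g, unsat) == pytest.approx(
                    total_weight(g)
                )

    def test_monotone_in_appended_arrangements(self, conflict_pair):
        a1 = ArrangementSet([arr(["u", "v"], [1, 0])])
        a2 = ArrangementSet([arr(["u", "v"], [1, 0]), arr(["u", "v"], [0, 1])])
        assert objective_value(conflict_pair, a2)[0] >= objective_value(conflict_pair, a1)[0]

    def test_segment_mismatch_raises(self, conflict_pair):
        with pytest.raises(GSGReferenceError):
            objective_value(conflict_pair, ArrangementSet([arr(["u"], [1])]))


class TestTSVCalling:
    def test_conflict_pair_two_rearranged_calls(self, conflict_pair):
        A = ArrangementSet([arr(["u", "v"], [1, 0]), arr(["u", "v"], [0, 1])])
        calls = call_tsvs(conflict_pair, A)
        assert len(calls) == 2
        assert {c.category for c in calls} == {REARRANGED}
        assert sorted(c.alleles for c in calls) == [(0,), (1,)]
        by_type = {c.end_types: c for c in calls}
        # H breakpoints at segment starts, T breakpoints at segment ends
        assert by_type["TT"].bp1 == ("chr1", 100, "T")
        assert by_type["TT"].bp2 == ("chr1", 200, "T")
        assert by_type["HH"].bp1 == ("chr1", 0, "H")

    def test_cross_chromosome_concordant_edge_is_distant(self):
        g = parse_gsg_text(
            "S a chr1 0 100\nS b chr2 0 100\nE a T b H 4\n"
        )
        ref = reference_arrangement(g)
        calls = call_tsvs(g, ArrangementSet([ref]))
        assert [c.category for c in calls] == [DISTANT]

    def test_nearby_concordant_edge_is_not_called(self):
        g = parse_gsg_text(
            "S a chr1 0 100\nS b chr1 1100 1200\nE a T b H 4\n"
        )
        calls = call_tsvs(g, ArrangementSet([reference_arrangement(g)]),
                          max_distance=200_000)
        assert calls == []

    def test_far_concordant_edge_is_distant(self):
        g = parse_gsg_text(
            "S a chr1 0 100\nS b chr1 500000 500100\nE a T b H 4\n"
        )
        calls = call_tsvs(g, ArrangementSet([reference_arrangement(g)]),
                          max_distance=200_000)
        assert [c.category for c in calls] == [DISTANT]

    def test_unsatisfied_edges_never_called(self, conflict_pair):
        calls = call_tsvs(conflict_pair, ArrangementSet([reference_arrangement(conflict_pair)]))
        assert calls == []

    def test_max_distance_must_be_positive(self, conflict_pair):
        with pytest.raises(ValueError):
            call_tsvs(conflict_pair, ArrangementSet([reference_arrangement(conflict_pair)]),
                      max_distance=0)
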