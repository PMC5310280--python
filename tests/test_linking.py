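"""Paired-end link counting, edge confidence and chain resolution."""

import pytest

from gaap.config import GaapConfig
from gaap.formats import MateAlignment, ReadPairAlignment, read_pe_alignments, write_pe_alignments
from gaap.indexing import ContigIndex, Placement, ScaffoldString
from gaap.linking import (
    CONFLICTING,
    CONSISTENT,
    UNINFORMATIVE,
    LinkEdge,
    classify_adjacency,
    classify_and_score,
    count_pe_links,
    edge_confidence,
    estimate_insert_size,
    filter_links,
    resolve_chains,
    string_internal_adjacencies,
)

from oracles import brute_force_link_counts


def pair(pid, c1, p1, s1, c2, p2, s2, rl=100):
    return ReadPairAlignment(
        pid,
        MateAlignment(c1, p1, s1, c1 is not None, rl),
        MateAlignment(c2, p2, s2, c2 is not None, rl),
    )


LENGTHS = {"sc1": 2000, "sc2": 1500, "sc3": 1000}


def random_pairs(rng, n=200, contigs=6, rl=50):
    lengths = {f"c{i}": int(rng.integers(300, 2000)) for i in range(contigs)}
    pairs = []
    for i in range(n):
        mates = []
        for _ in range(2):
            cid = f"c{int(rng.integers(0, contigs))}"
            mates.append(
                MateAlignment(
                    cid,
                    int(rng.integers(0, lengths[cid] - rl)),
                    "+" if rng.random() < 0.5 else "-",
                    rng.random() > 0.05,
                    rl,
                )
            )
        pairs.append(ReadPairAlignment(f"p{i}", mates[0], mates[1]))
    return pairs, lengths


class TestCountPeLinks:
    def test_forward_near_tail_reverse_near_head_is_tail_to_head(self):
        # forward mate 50 bp from sc1's tail, reverse mate 40 bp from sc2's head
        pairs = [pair("p1", "sc1", 2000 - 50 - 100, "+", "sc2", 40, "-")] * 6
        counts, _ = count_pe_links(pairs, LENGTHS, window=500)
        ((ends, n),) = counts.items()
        assert set(ends) == {("sc1", "T"), ("sc2", "H")}
        assert n == 6
        (edge,) = filter_links(counts, cutoff=5)
        assert edge.connection_type == "tail-to-head"

    def test_both_mates_on_one_contig_never_link(self):
        pairs = [pair("p1", "sc1", 1900, "+", "sc1", 10, "-")]
        counts, _ = count_pe_links(pairs, LENGTHS, window=500)
        assert counts == {}

    def test_interior_mate_outside_window_discarded(self):
        pairs = [pair("p1", "sc1", 1000, "+", "sc2", 10, "-")]
        counts, discarded = count_pe_links(pairs, LENGTHS, window=500)
        assert counts == {} and discarded == 1

    def test_all_eight_strand_end_mate_order_cases(self):
        # exhaustive: each mate near head (reverse) or tail (forward), both orders
        cases = []
        for s1, e1 in (("+", "T"), ("-", "H")):
            for s2, e2 in (("+", "T"), ("-", "H")):
                for order in (0, 1):
                    p1 = 1990 - 100 if s1 == "+" else 5
                    p2 = 1490 - 100 if s2 == "+" else 5
                    m = [("sc1", p1, s1), ("sc2", p2, s2)]
                    if order:
                        m.reverse()
                    cases.append((pair("p", *m[0], *m[1]), frozenset({("sc1", e1), ("sc2", e2)})))
        for p, expected in cases:
            counts, _ = count_pe_links([p], LENGTHS, window=500)
            ((ends, n),) = counts.items()
            assert frozenset(ends) == expected and n == 1

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            pairs, lengths = random_pairs(rng)
            window = int(rng.integers(50, 600))
            counts, _ = count_pe_links(pairs, lengths, window)
            assert counts == brute_force_link_counts(pairs, lengths, window)

    def test_oracle_agreement_survives_sam_roundtrip(self, rng, tmp_path):
        pairs, lengths = random_pairs(rng, n=120)
        path = tmp_path / "pe.sam"
        write_pe_alignments(pairs, lengths, path)
        back = list(read_pe_alignments(path))
        counts, _ = count_pe_links(back, lengths, 300)
        assert counts == brute_force_link_counts(pairs, lengths, 300)


class TestFilterLinks:
    def test_strictly_greater_than_cutoff(self):
        counts = {((u"a", "T"), ("b", "H")): 5, (("a", "H"), ("c", "T")): 6}
        kept = filter_links(counts, cutoff=5)
        assert [(e.ends, e.count) for e in kept] == [((("a", "H"), ("c", "T")), 6)]

    def test_zero_cutoff_keeps_every_nonzero_link(self):
        counts = {(("a", "T"), ("b", "H")): 1}
        assert len(filter_links(counts, cutoff=0)) == 1


def two_contig_string():
    return ScaffoldString("str1", [Placement("A", 1, 100), Placement("B", 1, None)])


class TestClassifyAndConfidence:
    def setup_method(self):
        self.strings = [
            ScaffoldString("str1", [Placement("A", 1, 0), Placement("B", 1, 0), Placement("C", 1, None)]),
            ScaffoldString("str2", [Placement("D", 1, 0), Placement("E", 1, None)]),
        ]
        self.internal = string_internal_adjacencies(self.strings)
        self.statuses = {c: "indexed" for c in "ABCDE"} | {"R": "unindexed", "X": "ambiguous"}

    def test_facing_ends_of_string_neighbors_consistent(self):
        edge = LinkEdge(("A", "T"), ("B", "H"), 10)
        assert classify_adjacency(edge, self.internal, self.statuses) == CONSISTENT

    def test_interior_ends_conflict(self):
        edge = LinkEdge(("B", "T"), ("D", "T"), 10)  # B.T is interior (joined to C.H)
        assert classify_adjacency(edge, self.internal, self.statuses) == CONFLICTING

    def test_terminus_to_unindexed_is_uninformative(self):
        edge = LinkEdge(("C", "T"), ("R", "H"), 10)
        assert classify_adjacency(edge, self.internal, self.statuses) == UNINFORMATIVE

    def test_ambiguous_contig_conflicts(self):
        edge = LinkEdge(("C", "T"), ("X", "H"), 10)
        assert classify_adjacency(edge, self.internal, self.statuses) == CONFLICTING

    def test_confidence_law(self):
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        consistent = LinkEdge(("A", "T"), ("B", "H"), 1, CONSISTENT)
        conflicting = LinkEdge(("B", "T"), ("D", "T"), 1000, CONFLICTING)
        uninformative = LinkEdge(("C", "T"), ("R", "H"), 6, UNINFORMATIVE)
        assert edge_confidence(consistent, cfg) == 1.0
        assert edge_confidence(conflicting, cfg) == 0.0
        assert edge_confidence(uninformative, cfg) == pytest.approx(0.3)


class TestResolveChains:
    def _indices(self, statuses):
        return [ContigIndex(c, 1000, status=s) for c, s in statuses.items()]

    def test_higher_confidence_edge_wins_competition(self):
        strings = [
            ScaffoldString("str1", [Placement("A", 1, None)]),
            ScaffoldString("str2", [Placement("B", 1, None)]),
            ScaffoldString("str3", [Placement("C", 1, None)]),
        ]
        indices = self._indices({"A": "indexed", "B": "indexed", "C": "indexed"})
        cfg = GaapConfig(alpha=0.0, l_sat=10)
        edges = [
            LinkEdge(("A", "T"), ("B", "H"), 9, UNINFORMATIVE, 0.9),
            LinkEdge(("A", "T"), ("C", "H"), 4, UNINFORMATIVE, 0.4),
        ]
        extended, attached = resolve_chains(edges, strings, indices, {}, cfg)
        assert [e.confidence for e in attached] == [0.9]
        walks = [[p.contig_id for p in s.placements] for s in extended]
        assert ["A", "B"] in walks

    def test_zero_confidence_edges_never_attach(self):
        strings = [two_contig_string(), ScaffoldString("str2", [Placement("D", 1, None)])]
        indices = self._indices({"A": "indexed", "B": "indexed", "D": "indexed"})
        edges = [LinkEdge(("A", "H"), ("D", "H"), 50, CONFLICTING, 0.0)]
        extended, attached = resolve_chains(edges, strings, indices, {}, GaapConfig())
        assert attached == []
        assert [[p.contig_id for p in s.placements] for s in extended] == [["A", "B"], ["D"]]

    def test_unindexed_repeat_recovered_between_strings(self):
        strings = [
            ScaffoldString("str1", [Placement("A", 1, None)]),
            ScaffoldString("str2", [Placement("B", 1, None)]),
        ]
        indices = self._indices({"A": "indexed", "B": "indexed", "R": "unindexed"})
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        edges = classify_and_score(
            [LinkEdge(("A", "T"), ("R", "H"), 20), LinkEdge(("R", "T"), ("B", "H"), 18)],
            strings, indices, cfg,
        )
        depths = {"A": 10.0, "B": 10.0, "R": 10.0}
        extended, _ = resolve_chains(edges, strings, indices, depths, cfg)
        (s,) = extended
        assert [p.contig_id for p in s.placements] == ["A", "R", "B"]

    def test_high_depth_repeat_reused_at_two_junctions(self):
        strings = [
            ScaffoldString(f"str{i}", [Placement(c, 1, None)])
            for i, c in enumerate("ABCD", start=1)
        ]
        indices = self._indices({c: "indexed" for c in "ABCD"} | {"R": "unindexed"})
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        edges = classify_and_score(
            [
                LinkEdge(("A", "T"), ("R", "H"), 20), LinkEdge(("R", "T"), ("B", "H"), 20),
                LinkEdge(("C", "T"), ("R", "H"), 19), LinkEdge(("R", "T"), ("D", "H"), 19),
            ],
            strings, indices, cfg,
        )
        depths = {"A": 10.0, "B": 10.0, "C": 10.0, "D": 10.0, "R": 25.0}
        extended, _ = resolve_chains(edges, strings, indices, depths, cfg)
        walks = sorted([p.contig_id for p in s.placements] for s in extended)
        assert walks == [["A", "R", "B"], ["C", "R", "D"]]

    def test_normal_depth_contig_used_once_only(self):
        strings = [
            ScaffoldString(f"str{i}", [Placement(c, 1, None)])
            for i, c in enumerate("ABCD", start=1)
        ]
        indices = self._indices({c: "indexed" for c in "ABCD"} | {"R": "unindexed"})
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        edges = classify_and_score(
            [
                LinkEdge(("A", "T"), ("R", "H"), 20), LinkEdge(("R", "T"), ("B", "H"), 20),
                LinkEdge(("C", "T"), ("R", "H"), 19), LinkEdge(("R", "T"), ("D", "H"), 19),
            ],
            strings, indices, cfg,
        )
        depths = {c: 10.0 for c in "ABCD"} | {"R": 10.0}
        extended, _ = resolve_chains(edges, strings, indices, depths, cfg)
        used = [p.contig_id for s in extended for p in s.placements]
        assert used.count("R") == 1

    def test_matching_validity_no_end_used_twice(self, rng):
        # random uninformative edges among singleton strings: after resolution
        # every non-repeat contig end participates in at most one join
        contigs = [f"c{i}" for i in range(8)]
        strings = [ScaffoldString(f"str{i}", [Placement(c, 1, None)]) for i, c in enumerate(contigs)]
        indices = self._indices({c: "indexed" for c in contigs})
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        for _ in range(20):
            raw = []
            for _ in range(12):
                a, b = rng.choice(8, 2, replace=False)
                raw.append(
                    LinkEdge(
                        (contigs[int(a)], "T" if rng.random() < 0.5 else "H"),
                        (contigs[int(b)], "T" if rng.random() < 0.5 else "H"),
                        int(rng.integers(6, 30)),
                    )
                )
            edges = classify_and_score(raw, strings, indices, cfg)
            extended, _ = resolve_chains(edges, strings, indices, {}, cfg)
            placed = [p.contig_id for s in extended for p in s.placements]
            assert sorted(placed) == sorted(contigs)

    def test_raising_cutoff_never_increases_joins(self, rng):
        pairs, lengths = random_pairs(rng, n=400, contigs=5)
        contigs = sorted(lengths)
        strings = [ScaffoldString(f"str{i}", [Placement(c, 1, None)]) for i, c in enumerate(contigs)]
        indices = [ContigIndex(c, lengths[c], status="indexed") for c in contigs]
        cfg = GaapConfig(alpha=0.5, l_sat=10)
        counts, _ = count_pe_links(pairs, lengths, 400)
        joins = []
        for cutoff in (0, 2, 5, 10, 20):
            edges = classify_and_score(filter_links(counts, cutoff), strings, indices, cfg)
            _, attached = resolve_chains(edges, strings, indices, {}, cfg)
            joins.append(len(attached))
        assert joins == sorted(joins, reverse=True)


def test_insert_size_estimated_from_intra_contig_innies():
    pairs = [pair(f"p{i}", "sc1", 100, "+", "sc1", 100 + 300 - 100, "-") for i in range(10)]
    assert estimate_insert_size(pairs) == 300
    assert estimate_insert_size([]) == 500  # fallback
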