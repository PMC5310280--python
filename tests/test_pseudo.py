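"""Permutation voting, guide selection and pseudo-genome construction."""

import pytest

from gaap.cgof import CgofSegment, SegmentPermutation
from gaap.config import GaapConfig
from gaap.formats import revcomp
from gaap.indexing import (
    ContigIndex,
    Placement,
    ReferenceGapEstimator,
    ScaffoldString,
    SegmentInterval,
    GeneHit,
)
from gaap.linking import canonical_junction
from gaap.pseudo import (
    GuideEmbeddingError,
    PermutationVote,
    build_pseudo_genome,
    canonicalize_permutation,
    count_patterns,
    filter_conflicting,
    induced_permutation,
    pattern_adjacencies,
    select_guide,
)

from conftest import make_cluster_table
from oracles import brute_force_compatible


class TestCanonicalize:
    def test_rotation_collapses(self):
        assert canonicalize_permutation((("S2", 1), ("S1", 1))) == (("S1", 1), ("S2", 1))

    def test_reflection_with_sign_flip_collapses(self):
        assert canonicalize_permutation((("S2", -1), ("S1", -1))) == (("S1", 1), ("S2", 1))

    def test_single_segment(self):
        assert canonicalize_permutation((("S1", -1),)) == (("S1", 1),)

    def test_invariant_under_random_rotations_and_reflection(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            perm = [(f"S{i + 1}", int(s)) for i, s in zip(rng.permutation(n), rng.integers(0, 2, n) * 2 - 1)]
            canon = canonicalize_permutation(perm)
            r = int(rng.integers(0, n))
            rotated = perm[r:] + perm[:r]
            reflected = [(sid, -s) for sid, s in reversed(rotated)]
            assert canonicalize_permutation(rotated) == canon
            assert canonicalize_permutation(reflected) == canon


class TestVotingAndSelection:
    def test_count_patterns_collapses_equivalent_arrangements(self):
        perms = [
            SegmentPermutation("a", "chr", (("S1", 1), ("S2", 1))),
            SegmentPermutation("b", "chr", (("S2", 1), ("S1", 1))),       # rotation
            SegmentPermutation("c", "chr", (("S2", -1), ("S1", -1))),     # reflection
            SegmentPermutation("d", "chr", (("S1", 1), ("S2", -1))),
        ]
        votes = count_patterns(perms)
        assert [(v.pattern, v.prevalence) for v in votes] == [
            ((("S1", 1), ("S2", 1)), 3),
            ((("S1", 1), ("S2", -1)), 1),
        ]

    def test_filter_removes_pattern_lacking_witnessed_junction(self):
        votes = [
            PermutationVote((("S1", 1), ("S2", 1), ("S3", 1)), ["a"]),
            PermutationVote((("S1", 1), ("S2", -1), ("S3", 1)), ["b"]),
        ]
        junction = {canonical_junction(("S1", 1), ("S2", 1))}
        kept = filter_conflicting(votes, junction)
        assert [v.pattern for v in kept] == [(("S1", 1), ("S2", 1), ("S3", 1))]
        assert votes[1].compatible is False

    def test_no_witnessed_junction_keeps_everything(self):
        votes = [PermutationVote((("S1", 1), ("S2", 1)), ["a"]),
                 PermutationVote((("S1", 1), ("S2", -1)), ["b"])]
        assert len(filter_conflicting(votes, set())) == 2

    def test_select_guide_prefers_prevalence_then_first_genome(self):
        p1 = PermutationVote((("S1", 1), ("S2", 1)), ["b", "c", "d"])
        p2 = PermutationVote((("S1", 1), ("S2", -1)), ["a", "e", "f"])
        assert select_guide([p1, p2]) is p2  # tie broken by genome 'a'
        p1.genomes.append("g")
        assert select_guide([p1, p2]) is p1
        assert select_guide([]) is None

    def test_selection_agrees_with_exhaustive_compatibility(self, rng):
        """filter_conflicting + select_guide vs brute-force over toy patterns."""
        for _ in range(100):
            n_seg = int(rng.integers(2, 6))
            n_ref = int(rng.integers(2, 7))
            seg_names = [f"S{i + 1}" for i in range(n_seg)]
            perms = []
            for g in range(n_ref):
                order = rng.permutation(n_seg)
                signs = rng.integers(0, 2, n_seg) * 2 - 1
                perms.append(SegmentPermutation(
                    f"g{g:02d}", "chr",
                    tuple((seg_names[int(i)], int(s)) for i, s in zip(order, signs)),
                ))
            votes = count_patterns(perms)
            # witnessed junctions: a random subset of one random pattern's adjacencies
            source = votes[int(rng.integers(0, len(votes)))].pattern
            adjacencies = sorted(pattern_adjacencies(source))
            k = int(rng.integers(0, len(adjacencies) + 1))
            picks = rng.choice(len(adjacencies), k, replace=False) if k else []
            junctions = {adjacencies[int(i)] for i in picks}

            kept = filter_conflicting(votes, junctions)
            expected_kept = {
                v.pattern for v in votes if brute_force_compatible(v.pattern, junctions)
            }
            assert {v.pattern for v in kept} == expected_kept
            guide = select_guide(kept)
            if expected_kept:
                best = max(v.prevalence for v in votes if v.pattern in expected_kept)
                assert guide.prevalence == best
            else:
                assert guide is None


# ---------------------------------------------------------------------------
# pseudo-genome assembly
# ---------------------------------------------------------------------------


def _toy_setup(rng):
    """Two segments of three 100 bp genes; contigs A (S1) and B (S2)."""
    genes = {f"g{i}": "".join(rng.choice(list("ACGT"), 100)) for i in range(6)}
    segments = [
        CgofSegment("S1", (("g0", 1), ("g1", 1), ("g2", 1))),
        CgofSegment("S2", (("g3", 1), ("g4", 1), ("g5", 1))),
    ]
    spacer = lambda: "".join(rng.choice(list("ACGT"), 50))
    seq_a = genes["g0"] + spacer() + genes["g1"] + spacer() + genes["g2"]
    seq_b = genes["g3"] + spacer() + genes["g4"] + spacer() + genes["g5"]
    contigs = {"A": seq_a, "B": seq_b}

    def interval(sid, lo, hi, cid, positions):
        hits = {
            p: GeneHit(f"g{p + (0 if sid == 'S1' else 3)}", cid, pos, pos + 100, 1)
            for p, pos in positions.items()
        }
        return SegmentInterval(sid, lo, hi, 1, hits)

    idx_a = ContigIndex("A", len(seq_a), status="indexed",
                        intervals=[interval("S1", 0, 2, "A", {0: 0, 1: 150, 2: 300})])
    idx_b = ContigIndex("B", len(seq_b), status="indexed",
                        intervals=[interval("S2", 0, 2, "B", {0: 0, 1: 150, 2: 300})])
    layout = [(f"g{i}", i * 150, i * 150 + 100, "+") for i in range(6)]
    table = make_cluster_table({"R1": layout, "R2": layout})
    return segments, contigs, [idx_a, idx_b], table


class TestBuildPseudoGenome:
    def test_two_strings_on_guide_with_flagged_gaps(self, rng):
        segments, contigs, indices, table = _toy_setup(rng)
        strings = [
            ScaffoldString("str1", [Placement("A", 1, None)]),
            ScaffoldString("str2", [Placement("B", 1, None)]),
        ]
        guide = PermutationVote((("S1", 1), ("S2", 1)), ["R1", "R2"])
        cfg = GaapConfig()
        pseudo, leftovers = build_pseudo_genome(
            strings, guide, indices, segments, contigs, ReferenceGapEstimator(table), cfg
        )
        assert leftovers == []
        assert pseudo.topology == "circular"
        assert [p.contig_id for p in pseudo.placements] == ["A", "B"]
        # two inter-string junctions (including the wrap), both guide-only
        assert len(pseudo.unverified) == 2
        assert len(pseudo.gaps) == 2
        assert all(g >= cfg.min_gap for g in (b - a for a, b in pseudo.gaps))

    def test_sequence_conservation_and_induced_permutation(self, rng):
        segments, contigs, indices, table = _toy_setup(rng)
        strings = [
            ScaffoldString("str1", [Placement("A", 1, None)]),
            ScaffoldString("str2", [Placement("B", -1, None)]),  # B enters reversed
        ]
        guide = PermutationVote((("S1", 1), ("S2", 1)), ["R1"])
        pseudo, _ = build_pseudo_genome(
            strings, guide, indices, segments, contigs, ReferenceGapEstimator(table), GaapConfig()
        )
        non_n = len(pseudo.sequence) - pseudo.sequence.count("N")
        assert non_n == sum(len(s) for s in contigs.values())
        for placement in pseudo.placements:
            placed = pseudo.sequence[placement.start : placement.end]
            original = contigs[placement.contig_id]
            assert placed == (original if placement.orient == 1 else revcomp(original))
        assert induced_permutation(pseudo, indices) == canonicalize_permutation(guide.pattern)

    def test_single_spanning_string_circularizes_as_is(self, rng):
        segments, contigs, indices, table = _toy_setup(rng)
        string = ScaffoldString("str1", [Placement("A", 1, 125), Placement("B", 1, None)])
        guide = PermutationVote((("S1", 1), ("S2", 1)), ["R1"])
        pseudo, _ = build_pseudo_genome(
            [string], guide, indices, segments, contigs, ReferenceGapEstimator(table), GaapConfig()
        )
        assert pseudo.unverified == []
        assert pseudo.sequence.startswith(contigs["A"])

    def test_incompatible_string_raises(self, rng):
        segments, contigs, indices, table = _toy_setup(rng)
        # B's interval claims S2 reversed relative to the guide while A pins S1:
        # one string containing both cannot embed
        indices[1].intervals[0].orient = -1
        string = ScaffoldString(
            "str1", [Placement("A", 1, 100), Placement("B", 1, None)]
        )
        guide = PermutationVote((("S1", 1), ("S2", 1)), ["R1"])
        with pytest.raises(GuideEmbeddingError):
            build_pseudo_genome(
                [string], guide, indices, segments, contigs, ReferenceGapEstimator(table), GaapConfig()
            )

    def test_string_without_intervals_goes_to_leftovers(self, rng):
        segments, contigs, indices, table = _toy_setup(rng)
        contigs = dict(contigs, X="ACGT" * 100)
        indices = indices + [ContigIndex("X", 400, status="unindexed")]
        strings = [
            ScaffoldString("str1", [Placement("A", 1, 125), Placement("B", 1, None)]),
            ScaffoldString("str2", [Placement("X", 1, None)]),
        ]
        guide = PermutationVote((("S1", 1), ("S2", 1)), ["R1"])
        pseudo, leftovers = build_pseudo_genome(
            strings, guide, indices, segments, contigs, ReferenceGapEstimator(table), GaapConfig()
        )
        assert [s.string_id for s in leftovers] == ["str2"]
        assert {p.contig_id for p in pseudo.placements} == {"A", "B"}
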