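"""Pseudo-genome construction guided by reference segment permutations.

Each reference replicon contributes one circular signed order of cGOF
segments.  Patterns are canonicalized (rotation and reflection-with-sign-flip
collapse to one representative, since the deposited strand of a reference is
arbitrary), patterns conflicting with a segment junction directly witnessed
in the assembled strings are removed, and the most prevalent survivor guides
the circular arrangement of the scaffold strings.  If no reference pattern
survives, the target carries a novel arrangement and no pseudo-genome is
emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cgof import CgofSegment, SegmentPermutation
from .config import GaapConfig
from .indexing import ContigIndex, Placement, ReferenceGapEstimator, ScaffoldString
from .linking import canonical_junction

logger = logging.getLogger("gaap")

Pattern = tuple[tuple[str, int], ...]


class GuideEmbeddingError(RuntimeError):
    """A scaffold string cannot be embedded in the guide permutation."""


def canonicalize_permutation(segments: Sequence[tuple[str, int]]) -> Pattern:
    """Lexicographically smallest representative of a circular signed order,
    over all rotations and the reflection with all signs flipped."""
    seq = tuple(segments)
    if not seq:
        return ()

    def key(s: Pattern):
        return tuple((sid, 0 if sign > 0 else 1) for sid, sign in s)

    best: Pattern | None = None
    for variant in (seq, tuple((sid, -sign) for sid, sign in reversed(seq))):
        for r in range(len(variant)):
            cand = variant[r:] + variant[:r]
            if best is None or key(cand) < key(best):
                best = cand
    return best


@dataclass
class PermutationVote:
    pattern: Pattern
    genomes: list[str] = field(default_factory=list)
    compatible: bool = True

    @property
    def prevalence(self) -> int:
        return len(self.genomes)


def count_patterns(perms: Sequence[SegmentPermutation]) -> list[PermutationVote]:
    """Collapse reference permutations into canonical patterns with prevalence."""
    votes: dict[Pattern, PermutationVote] = {}
    for perm in perms:
        pattern = canonicalize_permutation(perm.segments)
        votes.setdefault(pattern, PermutationVote(pattern)).genomes.append(perm.genome_id)
    out = list(votes.values())
    for v in out:
        v.genomes.sort()
    out.sort(key=lambda v: (-v.prevalence, v.genomes))
    return out


def pattern_adjacencies(pattern: Pattern) -> set:
    """Circular signed segment adjacencies of a pattern (canonicalized)."""
    n = len(pattern)
    if n < 2:
        return set()
    return {canonical_junction(pattern[i], pattern[(i + 1) % n]) for i in range(n)}


def filter_conflicting(votes: Sequence[PermutationVote], junctions: set) -> list[PermutationVote]:
    """Mark patterns lacking any junction the strings directly witness.

    Returns only the compatible votes; every vote's ``compatible`` flag is
    updated in place so the full report can be written out.
    """
    compatible = []
    for vote in votes:
        vote.compatible = junctions <= pattern_adjacencies(vote.pattern)
        if vote.compatible:
            compatible.append(vote)
    return compatible


def select_guide(compatible: Sequence[PermutationVote]) -> PermutationVote | None:
    """Most prevalent compatible pattern; ties go to the pattern supported by
    the lexicographically first genome (deterministic and stable under adding
    unrelated references)."""
    if not compatible:
        return None
    best_prev = max(v.prevalence for v in compatible)
    tied = [v for v in compatible if v.prevalence == best_prev]
    return min(tied, key=lambda v: v.genomes[0])


# ---------------------------------------------------------------------------
# embedding strings on the guide
# ---------------------------------------------------------------------------


def _chain_intervals(string: ScaffoldString, by_id: Mapping[str, ContigIndex]):
    """The string's segment intervals in chain order with chain-frame signs."""
    out = []
    for p in string.placements:
        idx = by_id.get(p.contig_id)
        if idx is None or not idx.intervals:
            continue
        ivs = idx.intervals if p.orient == 1 else list(reversed(idx.intervals))
        for iv in ivs:
            out.append((iv.segment_id, iv.gene_lo, iv.gene_hi, iv.orient * p.orient))
    return out


def _guide_coordinates(guide: Pattern, segments: Sequence[CgofSegment]):
    seg_by_id = {s.segment_id: s for s in segments}
    base, coords = 0, {}
    for sid, sign in guide:
        length = len(seg_by_id[sid])
        coords[sid] = (base, sign, length)
        base += length
    return coords, base


def embed_string(
    string: ScaffoldString,
    guide: Pattern,
    by_id: Mapping[str, ContigIndex],
    coords,
    total: int,
) -> tuple[int, int, int]:
    """Place one string on the guide circle.

    Returns (start gene coordinate, covered gene count, flip) where flip is
    -1 when the string must be reverse-complemented to follow the guide
    direction.  Raises :class:`GuideEmbeddingError` when neither orientation
    fits — the string's segment content contradicts the guide.
    """
    ivs = _chain_intervals(string, by_id)
    if not ivs:
        raise GuideEmbeddingError(f"string {string.string_id} carries no segment interval")
    guide_sign = {sid: sign for sid, sign in guide}
    for flip in (1, -1):
        oriented = ivs if flip == 1 else [
            (sid, lo, hi, -o) for sid, lo, hi, o in reversed(ivs)
        ]
        if any(sid not in guide_sign or o != guide_sign[sid] for sid, lo, hi, o in oriented):
            continue
        spans = []
        for sid, lo, hi, _ in oriented:
            base, sign, length = coords[sid]
            if sign == 1:
                spans.append((base + lo, base + hi))
            else:
                spans.append((base + length - 1 - hi, base + length - 1 - lo))
        # spans must ascend circularly (at most one wrap past the origin)
        wraps = sum(1 for a, b in zip(spans, spans[1:]) if b[0] <= a[1])
        if wraps > 1:
            continue
        start = spans[0][0]
        covered = (spans[-1][1] - spans[0][0]) % total + 1
        return start, covered, flip
    raise GuideEmbeddingError(
        f"string {string.string_id} is incompatible with the guide permutation"
    )


# ---------------------------------------------------------------------------
# anchors and gaps at string ends
# ---------------------------------------------------------------------------


def _end_anchor(string: ScaffoldString, by_id, seg_by_id, side: str):
    """(anchor gene, overhang bp from that gene to the string's ``side`` end)."""
    placements = string.placements
    order = range(len(placements) - 1, -1, -1) if side == "end" else range(len(placements))
    extra = 0
    for i in order:
        p = placements[i]
        idx = by_id[p.contig_id]
        if not idx.intervals:
            extra += idx.length
            gap = placements[i - 1].gap_after if side == "end" and i > 0 else (
                p.gap_after if side == "start" else None
            )
            extra += gap or 0
            continue
        ivs = idx.intervals if p.orient == 1 else list(reversed(idx.intervals))
        iv = ivs[-1] if side == "end" else ivs[0]
        signed = iv.orient * p.orient
        at_far = (side == "end") == (signed == 1)
        pos = iv.gene_hi if at_far else iv.gene_lo
        hit = iv.hits[pos]
        toward_end = (side == "end") == (p.orient == 1)
        within = (idx.length - hit.t_hi) if toward_end else hit.t_lo
        gene = seg_by_id[iv.segment_id].genes[pos][0]
        return gene, within + extra
    return None


def _flipped(string: ScaffoldString) -> ScaffoldString:
    gaps = [p.gap_after for p in string.placements]
    rev = [Placement(p.contig_id, -p.orient, None) for p in reversed(string.placements)]
    rev_gaps = (gaps[-2::-1] if len(gaps) > 1 else []) + [None]
    for p, g in zip(rev, rev_gaps):
        p.gap_after = g
    return ScaffoldString(string.string_id, rev)


# ---------------------------------------------------------------------------
# the pseudo-genome
# ---------------------------------------------------------------------------


@dataclass
class ContigPlacement:
    contig_id: str
    orient: int
    start: int
    end: int


@dataclass
class PseudoGenome:
    name: str
    sequence: str
    placements: list[ContigPlacement]
    gaps: list[tuple[int, int]]
    guide: Pattern
    unverified: list[tuple[str, str]]  # (left string id, right string id) guide-only joins
    topology: str = "circular"


from .formats import revcomp  # noqa: E402  (re-exported for convenience)


def build_pseudo_genome(
    strings: Sequence[ScaffoldString],
    guide: PermutationVote,
    indices: Sequence[ContigIndex],
    segments: Sequence[CgofSegment],
    contig_seqs: Mapping[str, str],
    gap_estimator: ReferenceGapEstimator,
    cfg: GaapConfig,
    name: str = "pseudogenome",
) -> tuple[PseudoGenome, list[ScaffoldString]]:
    """Arrange the strings along the guide into one circular sequence.

    Strings without any segment interval cannot be anchored and are returned
    as leftovers.  Junctions created purely by the guide (every inter-string
    join) are reported as unverified: nothing but reference prevalence
    supports them.  A single string spanning the whole guide is circularized
    as-is, so re-scaffolding an emitted pseudo-genome reproduces it.
    """
    by_id = {idx.contig_id: idx for idx in indices}
    seg_by_id = {s.segment_id: s for s in segments}
    coords, total = _guide_coordinates(guide.pattern, segments)

    anchored, leftovers = [], []
    for s in strings:
        try:
            start, covered, flip = embed_string(s, guide.pattern, by_id, coords, total)
        except GuideEmbeddingError:
            if _chain_intervals(s, by_id):
                raise  # a segment-bearing string the filter should have caught
            leftovers.append(s)
            continue
        anchored.append((start, covered, flip, s))
    if not anchored:
        raise GuideEmbeddingError("no scaffold string could be anchored on the guide")
    anchored.sort(key=lambda item: (item[0], item[3].string_id))
    for (s1, c1, _, a), (s2, _, _, b) in zip(anchored, anchored[1:]):
        if s2 < s1 + c1:
            raise GuideEmbeddingError(
                f"strings {a.string_id} and {b.string_id} overlap on the guide"
            )

    oriented = [s if flip == 1 else _flipped(s) for _, _, flip, s in anchored]
    single = len(oriented) == 1

    parts: list[str] = []
    placements: list[ContigPlacement] = []
    gaps: list[tuple[int, int]] = []
    unverified: list[tuple[str, str]] = []
    pos = 0

    def put_gap(length: int):
        nonlocal pos
        if length > 0:
            parts.append("N" * length)
            gaps.append((pos, pos + length))
            pos += length

    for i, s in enumerate(oriented):
        for p in s.placements:
            seq = contig_seqs[p.contig_id]
            if p.orient == -1:
                seq = revcomp(seq)
            parts.append(seq)
            placements.append(ContigPlacement(p.contig_id, p.orient, pos, pos + len(seq)))
            pos += len(seq)
            if p.gap_after is not None:
                put_gap(p.gap_after)
        nxt = oriented[(i + 1) % len(oriented)]
        # the junction to the next string (or back to the start of this one)
        # exists only because the guide says so
        gap = _between_strings(s, nxt, by_id, seg_by_id, gap_estimator, cfg, wrap_ok=single)
        put_gap(gap)
        if not single:
            unverified.append((s.string_id, nxt.string_id))

    pseudo = PseudoGenome(
        name=name,
        sequence="".join(parts),
        placements=placements,
        gaps=gaps,
        guide=guide.pattern,
        unverified=unverified,
    )
    return pseudo, leftovers


def _between_strings(a, b, by_id, seg_by_id, estimator, cfg, wrap_ok: bool) -> int:
    anchor_a = _end_anchor(a, by_id, seg_by_id, "end")
    anchor_b = _end_anchor(b, by_id, seg_by_id, "start")
    floor = 0 if wrap_ok else cfg.min_gap
    if anchor_a is None or anchor_b is None:
        return cfg.min_gap
    gene_a, over_a = anchor_a
    gene_b, over_b = anchor_b
    est = estimator.estimate(gene_a, over_a, gene_b, over_b)
    return max(floor, min(cfg.max_gap, est))


def induced_permutation(
    pseudo: PseudoGenome, indices: Sequence[ContigIndex]
) -> Pattern:
    """The canonical signed segment order the pseudo-genome realizes."""
    by_id = {idx.contig_id: idx for idx in indices}
    signed: list[tuple[str, int]] = []
    for placement in pseudo.placements:
        idx = by_id.get(placement.contig_id)
        if idx is None or not idx.intervals:
            continue
        ivs = idx.intervals if placement.orient == 1 else list(reversed(idx.intervals))
        for iv in ivs:
            entry = (iv.segment_id, iv.orient * placement.orient)
            if not signed or signed[-1] != entry:
                signed.append(entry)
    dedup: list[tuple[str, int]] = []
    for entry in signed:
        if not dedup or dedup[-1] != entry:
            dedup.append(entry)
    if len(dedup) > 1 and dedup[0] == dedup[-1]:
        dedup.pop()
    return canonicalize_permutation(dedup)
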