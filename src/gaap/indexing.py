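"""Indexing draft contigs by cGOF genes and merging them into strings.

Each contig is searched for core-gene hits; the surviving hits map the contig
onto sub-ranges of cGOF segments with an orientation.  Contigs sharing a
segment are ordered by their gene sub-ranges, and a contig that spans the end
of one segment and the start of another (an "overbridge") fuses the two
segments' contig chains into a single scaffold string.  Contigs without any
core gene stay unindexed (they are candidates for recovery by read pairs
later); contigs with self-contradictory hits are set aside as ambiguous and
never joined.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats import AlignmentHit, ClusterTable
from .cgof import CgofSegment

logger = logging.getLogger("gaap")

HEAD, TAIL = "H", "T"


@dataclass(frozen=True)
class GeneHit:
    """The accepted placement of one core gene on one contig."""

    cluster_id: str
    contig_id: str
    t_lo: int
    t_hi: int
    strand: int  # +1 / -1


@dataclass
class SegmentInterval:
    """A maximal run of one segment's genes found on a contig.

    ``gene_lo``..``gene_hi`` are inclusive indexes into the segment's gene
    list; ``orient`` is +1 when walking the contig forward ascends the
    segment's gene index.
    """

    segment_id: str
    gene_lo: int
    gene_hi: int
    orient: int
    hits: dict[int, GeneHit] = field(default_factory=dict)  # seg index -> hit


@dataclass
class ContigIndex:
    contig_id: str
    length: int
    hits: list[GeneHit] = field(default_factory=list)
    intervals: list[SegmentInterval] = field(default_factory=list)
    status: str = "unindexed"  # indexed | unindexed | ambiguous

    @property
    def n_hits(self) -> int:
        return len(self.hits)


@dataclass
class Placement:
    contig_id: str
    orient: int           # +1 / -1 within the string
    gap_after: int | None  # estimated bp to the next placement; None at the end


@dataclass
class ScaffoldString:
    string_id: str
    placements: list[Placement]

    def contig_ids(self) -> list[str]:
        return [p.contig_id for p in self.placements]


# ---------------------------------------------------------------------------
# built-in exact matcher (for core-gene FASTA input; BLAT/BLAST replace it
# in production via read_gene_hits)
# ---------------------------------------------------------------------------


def exact_gene_hits(
    gene_seqs: Mapping[str, str], contigs: Mapping[str, str]
) -> list[AlignmentHit]:
    """Find full-length exact occurrences of each gene on the contigs.

    Emits identity 1.0 / coverage 1.0 hits for every occurrence on either
    strand.  Genes split across contig boundaries simply produce no hit.
    """
    from .formats import revcomp

    hits = []
    for gene, seq in sorted(gene_seqs.items()):
        for strand, probe in (("+", seq), ("-", revcomp(seq))):
            for cid, contig in contigs.items():
                start = contig.find(probe)
                while start != -1:
                    hits.append(
                        AlignmentHit(
                            query_id=gene,
                            target_id=cid,
                            query_span=(0, len(seq)),
                            target_span=(start, start + len(seq)),
                            strand=strand,
                            identity=1.0,
                            query_coverage=1.0,
                        )
                    )
                    start = contig.find(probe, start + 1)
    return hits


# ---------------------------------------------------------------------------
# hit assignment
# ---------------------------------------------------------------------------


def assign_gene_hits(
    hits: Sequence[AlignmentHit],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
    ambiguity_margin: float = 0.01,
) -> tuple[dict[str, list[GeneHit]], set[str]]:
    """Keep one best hit per gene; drop genes whose best hits effectively tie.

    Hits below the identity/coverage thresholds are discarded first.  The
    best hit is the one maximizing identity x coverage; if the runner-up is
    within ``ambiguity_margin`` (relative) of the best, the gene is not
    uniquely mapped and contributes nothing.  Returns hits grouped per contig
    (sorted by position) and the set of ambiguous genes.
    """
    by_gene: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        if hit.identity < min_identity or hit.query_coverage < min_coverage:
            continue
        by_gene.setdefault(hit.query_id, []).append(hit)
    per_contig: dict[str, list[GeneHit]] = {}
    ambiguous: set[str] = set()
    for gene, candidates in by_gene.items():
        candidates.sort(key=lambda h: (-h.score(), h.target_id, h.target_span))
        best = candidates[0]
        if len(candidates) > 1 and candidates[1].score() >= best.score() * (1 - ambiguity_margin):
            ambiguous.add(gene)
            continue
        per_contig.setdefault(best.target_id, []).append(
            GeneHit(
                cluster_id=gene,
                contig_id=best.target_id,
                t_lo=best.target_span[0],
                t_hi=best.target_span[1],
                strand=1 if best.strand == "+" else -1,
            )
        )
    for lst in per_contig.values():
        lst.sort(key=lambda h: (h.t_lo, h.t_hi))
    if ambiguous:
        logger.info("%d genes dropped as ambiguously mapped", len(ambiguous))
    return per_contig, ambiguous


# ---------------------------------------------------------------------------
# contig indexing
# ---------------------------------------------------------------------------


def index_contigs(
    per_contig_hits: Mapping[str, list[GeneHit]],
    segments: Sequence[CgofSegment],
    contig_lengths: Mapping[str, int],
) -> list[ContigIndex]:
    """Annotate each contig with the segment sub-ranges its genes realize.

    Hits from genes in no segment (runs below the segment length cutoff) are
    ignored.  A contig whose intervals contradict each other — the same
    segment seen in both orientations, overlapping sub-ranges, or sub-ranges
    out of order — is flagged ambiguous; a clean internal deletion (two
    non-overlapping, order-consistent sub-ranges of one segment) stays
    indexed.
    """
    seg_index: dict[str, tuple[str, int, int]] = {}
    for seg in segments:
        for pos, (gene, sign) in enumerate(seg.genes):
            seg_index[gene] = (seg.segment_id, pos, sign)
    out = []
    for contig_id in sorted(contig_lengths):
        idx = ContigIndex(contig_id, contig_lengths[contig_id])
        idx.hits = list(per_contig_hits.get(contig_id, []))
        mapped = [
            (hit, seg_index[hit.cluster_id])
            for hit in idx.hits
            if hit.cluster_id in seg_index
        ]
        for hit, (sid, pos, canon_sign) in mapped:
            rel = hit.strand * canon_sign
            last = idx.intervals[-1] if idx.intervals else None
            if (
                last is not None
                and last.segment_id == sid
                and last.orient == rel
                and pos == (last.gene_hi + 1 if rel == 1 else last.gene_lo - 1)
            ):
                last.gene_lo = min(last.gene_lo, pos)
                last.gene_hi = max(last.gene_hi, pos)
                last.hits[pos] = hit
            else:
                idx.intervals.append(SegmentInterval(sid, pos, pos, rel, {pos: hit}))
        if idx.intervals:
            idx.status = "ambiguous" if _contradictory(idx.intervals) else "indexed"
        out.append(idx)
    return out


def _contradictory(intervals: list[SegmentInterval]) -> bool:
    """Do a contig's segment intervals contradict each other?

    Legal layouts per segment: one orientation; pairwise non-overlapping gene
    sub-ranges; interval positions circularly contiguous within the contig's
    interval list; and sub-ranges that advance along the walk with at most one
    circular descent.  The circular allowances exist because a contig may span
    the origin of a circular target (e.g. when re-scaffolding an emitted
    pseudo-genome), which splits one segment into a tail part at the contig's
    start and a head part at its end.
    """
    n = len(intervals)
    by_seg: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by_seg.setdefault(iv.segment_id, []).append(i)
    for sid, positions in by_seg.items():
        ivs = [intervals[i] for i in positions]
        if len({iv.orient for iv in ivs}) > 1:
            return True
        orient = ivs[0].orient
        ranges = sorted((iv.gene_lo, iv.gene_hi) for iv in ivs)
        if any(b[0] <= a[1] for a, b in zip(ranges, ranges[1:])):
            return True  # overlapping claims on one segment
        # positions must be circularly contiguous in the interval list
        breaks = sum(
            1
            for a, b in zip(positions, positions[1:] + [positions[0] + n])
            if b - a > 1
        )
        if breaks > 1:
            return True
        # sub-ranges advance along the contig walk, with at most one wrap
        walk = [(iv.gene_lo, iv.gene_hi) for iv in ivs]
        if orient == -1:
            walk = walk[::-1]
        descents = sum(
            1
            for a, b in zip(walk, walk[1:] + walk[:1])
            if b[0] <= a[1]
        )
        if len(walk) > 1 and descents > 1:
            return True
    return False


def merged_interval(index: ContigIndex, segment_id: str) -> SegmentInterval | None:
    """The union of a contig's intervals on one segment (internal deletions collapse)."""
    ivs = [iv for iv in index.intervals if iv.segment_id == segment_id]
    if not ivs:
        return None
    hits: dict[int, GeneHit] = {}
    for iv in ivs:
        hits.update(iv.hits)
    return SegmentInterval(
        segment_id,
        min(iv.gene_lo for iv in ivs),
        max(iv.gene_hi for iv in ivs),
        ivs[0].orient,
        hits,
    )


# ---------------------------------------------------------------------------
# gap estimation from reference coordinates
# ---------------------------------------------------------------------------


class ReferenceGapEstimator:
    """Estimate target gaps from the genomic span between two core genes.

    For two anchor genes, each reference that carries both provides the
    distance between their intervals; the median across references is the
    expected span in the target, from which the anchored contig overhangs are
    subtracted.
    """

    def __init__(self, table: ClusterTable, default_gap: int = 100):
        self.default_gap = default_gap
        self._coords: dict[tuple[str, str], tuple[str, int, int]] = {}
        self._span: dict[tuple[str, str], int] = {}  # lower bound on replicon length
        for row in table.rows.itertuples(index=False):
            self._coords[(row.cluster_id, row.genome_id)] = (row.replicon_id, row.start, row.end)
            key = (row.genome_id, row.replicon_id)
            self._span[key] = max(self._span.get(key, 0), row.end)
        self._genomes = table.genomes()

    def gene_distance(self, gene_a: str, gene_b: str) -> int | None:
        """Median circular distance between the two gene intervals.

        Replicon length is approximated by the last gene's end coordinate, so
        wrap-around distances are slight underestimates (by the terminal
        intergenic stretch); downstream clamping absorbs that.
        """
        dists = []
        for genome in self._genomes:
            a = self._coords.get((gene_a, genome))
            b = self._coords.get((gene_b, genome))
            if a is None or b is None or a[0] != b[0]:
                continue
            linear = max(0, max(a[1], b[1]) - min(a[2], b[2]))
            length = self._span[(genome, a[0])]
            wrap = max(0, length - (max(a[2], b[2]) - min(a[1], b[1])))
            dists.append(min(linear, wrap))
        return int(statistics.median(dists)) if dists else None

    def estimate(
        self,
        gene_a: str,
        overhang_a: int,
        gene_b: str,
        overhang_b: int,
    ) -> int:
        dist = self.gene_distance(gene_a, gene_b)
        if dist is None:
            return self.default_gap
        return max(0, dist - overhang_a - overhang_b)


# ---------------------------------------------------------------------------
# merging contigs and segments into strings
# ---------------------------------------------------------------------------


def merge_strings(
    indices: Sequence[ContigIndex],
    segments: Sequence[CgofSegment],
    gap_estimator: ReferenceGapEstimator,
) -> tuple[list[ScaffoldString], list[ContigIndex]]:
    """Order indexed contigs along their segments and fuse chains at overbridges.

    Returns the scaffold strings plus the full (possibly demoted) index list.
    When two contigs claim overlapping gene sub-ranges of one segment, the one
    with more gene hits survives and the other is demoted to ambiguous.
    """
    indices = list(indices)
    by_id = {idx.contig_id: idx for idx in indices}
    seg_by_id = {s.segment_id: s for s in segments}

    # resolve overlapping claims per segment
    changed = True
    while changed:
        changed = False
        for seg in segments:
            entries = _segment_entries(indices, seg.segment_id)
            for (a, iv_a), (b, iv_b) in zip(entries, entries[1:]):
                if iv_b.gene_lo <= iv_a.gene_hi:
                    loser = min((a, b), key=lambda i: (i.n_hits, i.contig_id))
                    logger.warning(
                        "contigs %s and %s overlap on %s; demoting %s",
                        a.contig_id, b.contig_id, seg.segment_id, loser.contig_id,
                    )
                    loser.status = "ambiguous"
                    changed = True
                    break
            if changed:
                break

    # build end-to-end edges along each segment chain
    edges: dict[tuple[str, str], tuple[tuple[str, str], int]] = {}
    for seg in segments:
        entries = _segment_entries(indices, seg.segment_id)
        for (a, iv_a), (b, iv_b) in zip(entries, entries[1:]):
            exit_end = TAIL if iv_a.orient == 1 else HEAD
            enter_end = HEAD if iv_b.orient == 1 else TAIL
            end_a, end_b = (a.contig_id, exit_end), (b.contig_id, enter_end)
            if end_a in edges or end_b in edges:
                logger.warning(
                    "end conflict joining %s-%s on %s; junction skipped",
                    a.contig_id, b.contig_id, seg.segment_id,
                )
                continue
            gap = _chain_gap(seg, iv_a, a, iv_b, b, gap_estimator)
            edges[end_a] = (end_b, gap)
            edges[end_b] = (end_a, gap)

    strings = _walk_chains(edges, by_id)
    return strings, indices


def _segment_entries(indices, segment_id):
    entries = []
    for idx in indices:
        if idx.status != "indexed":
            continue
        iv = merged_interval(idx, segment_id)
        if iv is not None:
            entries.append((idx, iv))
    entries.sort(key=lambda e: (e[1].gene_lo, e[1].gene_hi, e[0].contig_id))
    return entries


def _chain_gap(seg, iv_a, a, iv_b, b, estimator: ReferenceGapEstimator) -> int:
    gene_a = seg.genes[iv_a.gene_hi][0]
    gene_b = seg.genes[iv_b.gene_lo][0]
    hit_a = iv_a.hits.get(iv_a.gene_hi)
    hit_b = iv_b.hits.get(iv_b.gene_lo)
    if hit_a is None or hit_b is None:  # pragma: no cover - defensive
        return estimator.default_gap
    overhang_a = a.length - hit_a.t_hi if iv_a.orient == 1 else hit_a.t_lo
    overhang_b = hit_b.t_lo if iv_b.orient == 1 else b.length - hit_b.t_hi
    return estimator.estimate(gene_a, overhang_a, gene_b, overhang_b)


def _walk_chains(edges, by_id) -> list[ScaffoldString]:
    """Turn the contig-end adjacency map into ordered, oriented strings.

    A fully tiled circular genome yields a closed chain; such cycles are
    opened at the widest gap (ties by endpoint ids) so strings stay linear.
    """
    edges = dict(edges)
    indexed = sorted(
        cid for cid, idx in by_id.items() if idx.status == "indexed"
    )
    ends = [(cid, e) for cid in indexed for e in (HEAD, TAIL)]
    seen: set[str] = set()
    strings: list[ScaffoldString] = []

    def walk(cid, end):
        placements: list[Placement] = []
        while True:
            seen.add(cid)
            orient = 1 if end == HEAD else -1
            placements.append(Placement(cid, orient, None))
            exit_end = TAIL if end == HEAD else HEAD
            nxt = edges.get((cid, exit_end))
            if nxt is None:
                break
            placements[-1].gap_after = nxt[1]
            (cid, end) = nxt[0]
        strings.append(ScaffoldString(f"str{len(strings) + 1}", placements))

    for start in sorted(e for e in ends if e not in edges):
        if start[0] not in seen:
            walk(*start)
    for cid in indexed:  # leftover components are cycles
        if cid in seen:
            continue
        cycle_edges, node, end = [], cid, TAIL
        while True:
            other, gap = edges[(node, end)]
            cycle_edges.append(((node, end), other, gap))
            node, end = other[0], (TAIL if other[1] == HEAD else HEAD)
            if node == cid:
                break
        (end_a, end_b, _) = max(cycle_edges, key=lambda e: (e[2], e[0], e[1]))
        del edges[end_a], edges[end_b]
        logger.info("opened circular chain at %s-%s", end_a, end_b)
        walk(end_b[0], end_b[1])
    # canonical direction: lexicographically smaller terminal contig first
    for s in strings:
        first, last = s.placements[0].contig_id, s.placements[-1].contig_id
        if last < first:
            _reverse_string(s)
    strings.sort(key=lambda s: s.placements[0].contig_id)
    for i, s in enumerate(strings, start=1):
        s.string_id = f"str{i}"
    return strings


def _reverse_string(s: ScaffoldString) -> None:
    gaps = [p.gap_after for p in s.placements]
    s.placements.reverse()
    for p in s.placements:
        p.orient = -p.orient
    rev_gaps = gaps[-2::-1] if len(gaps) > 1 else []
    for p, g in zip(s.placements, rev_gaps + [None]):
        p.gap_after = g
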