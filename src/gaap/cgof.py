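"""Identification of cGOF segments from reference genomes.

A species' single-copy core genes tend to keep their relative order (synteny)
across strains either genome-wide or within large blocks.  This module sorts
the core genes of every reference genome into a signed circular order, finds
the maximal runs of genes whose signed adjacency is conserved in *every*
reference (the cGOF segments), and records each reference's signed segment
permutation.  Those permutations later vote on how to arrange a target's
scaffold strings into a circular pseudo-genome.

"Conserved in consecutive order" is operationalized as: the signed adjacency
(a, b) holds in a genome iff that genome contains ..., a, b, ... or
..., -b, -a, ... consecutively (circularly, within one replicon).  Because
core genes are single-copy, a run whose every internal adjacency is conserved
is itself consecutive (forward or fully reversed) in every genome, so the
segments are exactly the maximal conserved runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .formats import ClusterTable

logger = logging.getLogger("gaap")

SignedGene = tuple[str, int]  # (cluster_id, +1/-1)


@dataclass(frozen=True)
class OrderBlock:
    """The signed core-gene order of one replicon."""

    replicon_id: str
    genes: tuple[SignedGene, ...]
    circular: bool = True


@dataclass(frozen=True)
class CoreGeneOrder:
    genome_id: str
    blocks: tuple[OrderBlock, ...]

    def all_genes(self) -> set[str]:
        return {g for b in self.blocks for g, _ in b.genes}


@dataclass(frozen=True)
class CgofSegment:
    """A maximal order-conserved run of core genes, in canonical orientation.

    Canonical orientation is the orientation the run has in the
    lexicographically first reference genome, which makes output
    deterministic regardless of input row order.
    """

    segment_id: str
    genes: tuple[SignedGene, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def reversed_genes(self) -> tuple[SignedGene, ...]:
        return tuple((g, -s) for g, s in reversed(self.genes))


@dataclass(frozen=True)
class SegmentPermutation:
    """The circular signed order of cGOF segments in one replicon."""

    genome_id: str
    replicon_id: str
    segments: tuple[tuple[str, int], ...]  # (segment_id, +1/-1)


def _flip(gene: SignedGene) -> SignedGene:
    return (gene[0], -gene[1])


def canonical_adjacency(a: SignedGene, b: SignedGene) -> tuple[SignedGene, SignedGene]:
    """Normalize (a, b) so it compares equal to its reverse (-b, -a)."""
    fwd = (a, b)
    rev = (_flip(b), _flip(a))
    return min(fwd, rev)


def _block_adjacencies(block: OrderBlock) -> set[tuple[SignedGene, SignedGene]]:
    genes = block.genes
    adj = set()
    n = len(genes)
    if n < 2:
        return adj
    last = n if block.circular else n - 1
    for i in range(last):
        adj.add(canonical_adjacency(genes[i], genes[(i + 1) % n]))
    return adj


def order_adjacencies(order: CoreGeneOrder) -> set[tuple[SignedGene, SignedGene]]:
    adj: set[tuple[SignedGene, SignedGene]] = set()
    for block in order.blocks:
        adj |= _block_adjacencies(block)
    return adj


def build_core_orders(
    table: ClusterTable,
    genomes: Sequence[str] | None = None,
    circular: bool = True,
) -> list[CoreGeneOrder]:
    """Sort the shared single-copy core genes of each genome by position.

    Clusters missing from any of the genomes (or multi-copy anywhere) are
    excluded: the core is defined as present single-copy everywhere.  Each
    replicon yields its own order block; adjacencies never span replicons.
    """
    genomes = sorted(genomes) if genomes is not None else table.genomes()
    if len(genomes) < 2:
        raise ValueError(f"need at least 2 reference genomes, got {len(genomes)}")
    core = set(table.core_clusters(genomes))
    multi = {c for c, g in table.multi_copy if g in genomes}
    core -= multi
    if not core:
        raise ValueError("no single-copy core clusters shared by all genomes")
    sub = table.rows[table.rows["genome_id"].isin(genomes) & table.rows["cluster_id"].isin(core)]
    orders = []
    for genome in genomes:
        g_rows = sub[sub["genome_id"] == genome]
        blocks = []
        for replicon in sorted(g_rows["replicon_id"].unique()):
            r_rows = g_rows[g_rows["replicon_id"] == replicon].sort_values("start")
            genes = tuple(
                (row.cluster_id, 1 if row.strand == "+" else -1)
                for row in r_rows.itertuples(index=False)
            )
            blocks.append(OrderBlock(replicon, genes, circular))
        orders.append(CoreGeneOrder(genome, tuple(blocks)))
    return orders


def identify_segments(orders: Sequence[CoreGeneOrder], min_seg_len: int = 2) -> list[CgofSegment]:
    """Find maximal runs of core genes conserved consecutively in all orders.

    Runs shorter than ``min_seg_len`` genes are discarded (a single gene
    carries no order information; the default keeps runs of two or more).
    Segments are reported in the orientation and numbering of the
    lexicographically first genome.
    """
    if not orders:
        return []
    if min_seg_len < 2:
        raise ValueError("min_seg_len must be >= 2")
    conserved = order_adjacencies(orders[0])
    for order in orders[1:]:
        conserved &= order_adjacencies(order)
    first = min(orders, key=lambda o: o.genome_id)
    segments: list[CgofSegment] = []
    for block in first.blocks:
        for run in _conserved_runs(block, conserved):
            if len(run) >= min_seg_len:
                segments.append(CgofSegment(f"S{len(segments) + 1}", tuple(run)))
    logger.info(
        "identified %d cGOF segments covering %d genes",
        len(segments),
        sum(len(s) for s in segments),
    )
    return segments


def _conserved_runs(
    block: OrderBlock, conserved: set[tuple[SignedGene, SignedGene]]
) -> list[list[SignedGene]]:
    genes = block.genes
    n = len(genes)
    if n == 0:
        return []
    if n == 1:
        return [list(genes)]
    ok = [
        canonical_adjacency(genes[i], genes[(i + 1) % n]) in conserved
        for i in range(n)
    ]  # ok[i]: adjacency after position i holds everywhere
    if not block.circular:
        ok[n - 1] = False
    if all(ok):
        return [list(genes)]  # fully conserved circle: one segment, fixed rotation
    # rotate so a break sits at the end, then split linearly
    breaks = [i for i, v in enumerate(ok) if not v]
    start = (breaks[-1] + 1) % n
    rotated = [genes[(start + i) % n] for i in range(n)]
    ok_rot = [ok[(start + i) % n] for i in range(n)]
    runs, current = [], [rotated[0]]
    for i in range(n - 1):
        if ok_rot[i]:
            current.append(rotated[i + 1])
        else:
            runs.append(current)
            current = [rotated[i + 1]]
    runs.append(current)
    # report runs in the order they appear along the original block
    pos = {g: i for i, (g, _) in enumerate(genes)}
    runs.sort(key=lambda r: pos[r[0][0]])
    return runs


def derive_permutations(
    segments: Sequence[CgofSegment], orders: Sequence[CoreGeneOrder]
) -> list[SegmentPermutation]:
    """Record each replicon's circular signed order of the cGOF segments.

    Sign is + when the replicon carries the segment in canonical orientation.
    Expanding a permutation regenerates the replicon's core order restricted
    to segment-member genes; a segment that cannot be located intact means
    the segments do not belong to these orders.
    """
    seg_index: dict[str, tuple[str, int, int]] = {}
    for seg in segments:
        for pos, (gene, sign) in enumerate(seg.genes):
            seg_index[gene] = (seg.segment_id, pos, sign)
    seg_by_id = {s.segment_id: s for s in segments}
    perms = []
    for order in orders:
        for block in order.blocks:
            placements = _locate_segments(block, seg_index, seg_by_id)
            if len(placements) != len(
                {sid for (g, _) in block.genes for sid in [seg_index.get(g, (None,))[0]] if sid}
            ):
                raise RuntimeError(
                    f"segments not intact in {order.genome_id}/{block.replicon_id}"
                )
            perms.append(
                SegmentPermutation(
                    order.genome_id,
                    block.replicon_id,
                    tuple((sid, rel) for _, sid, rel in sorted(placements)),
                )
            )
    return perms


def _locate_segments(
    block: OrderBlock,
    seg_index: dict[str, tuple[str, int, int]],
    seg_by_id: dict[str, CgofSegment],
) -> list[tuple[int, str, int]]:
    genes = block.genes
    n = len(genes)
    placements = []
    for i, (gene, sign) in enumerate(genes):
        info = seg_index.get(gene)
        if info is None:
            continue
        sid, pos, canon_sign = info
        rel = sign * canon_sign  # +1: segment forward here, -1: reversed
        seg = seg_by_id[sid]
        length = len(seg.genes)
        starts_here = (rel == 1 and pos == 0) or (rel == -1 and pos == length - 1)
        if not starts_here:
            continue
        expected = seg.genes if rel == 1 else seg.reversed_genes()
        for k in range(length):
            j = (i + k) % n if block.circular else i + k
            if (not block.circular and j >= n) or genes[j] != expected[k]:
                raise RuntimeError(
                    f"segment {sid} not intact in block {block.replicon_id}"
                )
        placements.append((i, sid, rel))
    return placements


def expand_permutation(
    perm: SegmentPermutation, segments: Sequence[CgofSegment]
) -> list[SignedGene]:
    """Regenerate the core-gene order (restricted to segment genes)."""
    seg_by_id = {s.segment_id: s for s in segments}
    out: list[SignedGene] = []
    for sid, rel in perm.segments:
        seg = seg_by_id[sid]
        out.extend(seg.genes if rel == 1 else seg.reversed_genes())
    return out
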