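"""Local scaffolding: confirm and extend contig adjacencies with read pairs.

Every contig contributes a head and a tail vertex.  A read pair whose mates
sit near the ends of two different contigs, each pointing off its end, votes
for one of four connection types (head-to-head, head-to-tail, tail-to-head,
tail-to-tail).  Links are screened by a count cutoff, classified against the
cGOF-derived scaffold strings, and given a confidence

    c(i,j) = a * permutation(i,j) + (1 - a) * link(i,j)

where connections consistent with the cGOF order (and the internal head-tail
edge of every contig) are pinned at 1, connections conflicting with it at 0,
and order-uninformative connections fall back on the read-link term
link(i,j) = min(1, n_ij / L_sat).  A greedy highest-confidence matching then
extends the strings and recovers unindexed contigs; contigs with repeat-like
depth may be reused at several junctions.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .config import GaapConfig
from .indexing import HEAD, TAIL, ContigIndex, Placement, ScaffoldString
from .formats import ReadPairAlignment

logger = logging.getLogger("gaap")

Endpoint = tuple[str, str]  # (contig_id, 'H' | 'T')

CONNECTION_TYPES = {
    (HEAD, HEAD): "head-to-head",
    (HEAD, TAIL): "head-to-tail",
    (TAIL, HEAD): "tail-to-head",
    (TAIL, TAIL): "tail-to-tail",
}

CONSISTENT, CONFLICTING, UNINFORMATIVE = "consistent", "conflicting", "uninformative"


@dataclass(frozen=True)
class LinkEdge:
    end_a: Endpoint
    end_b: Endpoint
    count: int
    category: str = UNINFORMATIVE
    confidence: float = 0.0

    @property
    def connection_type(self) -> str:
        return CONNECTION_TYPES[(self.end_a[1], self.end_b[1])]

    @property
    def ends(self) -> tuple[Endpoint, Endpoint]:
        return (self.end_a, self.end_b)


def mate_endpoint(mate, contig_length: int, window: int) -> Endpoint | None:
    """The contig end a mapped mate points off, or None if it sits interior.

    A forward-strand mate reads toward the tail and supports a tail link when
    it lies within ``window`` of it; a reverse-strand mate reads toward the
    head and supports a head link symmetrically.
    """
    if mate.strand == "+":
        if contig_length - mate.pos <= window:
            return (mate.contig_id, TAIL)
    else:
        if mate.pos + mate.read_len <= window:
            return (mate.contig_id, HEAD)
    return None


def estimate_insert_size(
    pairs: Iterable[ReadPairAlignment], fallback: int = 500
) -> int:
    """Mean insert from innies with both mates on one contig."""
    inserts = []
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if not (m1.mapped and m2.mapped) or m1.contig_id != m2.contig_id:
            continue
        if m1.strand == m2.strand:
            continue
        fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
        insert = rev.pos + rev.read_len - fwd.pos
        if insert > 0:
            inserts.append(insert)
    if not inserts:
        logger.warning("no intra-contig pairs; insert size falls back to %d", fallback)
        return fallback
    return int(round(statistics.fmean(inserts)))


def contig_depths(
    pairs: Iterable[ReadPairAlignment], contig_lengths: Mapping[str, int]
) -> dict[str, float]:
    bases: Counter[str] = Counter()
    for pair in pairs:
        for mate in (pair.mate1, pair.mate2):
            if mate.mapped:
                bases[mate.contig_id] += mate.read_len
    return {cid: bases.get(cid, 0) / ln for cid, ln in contig_lengths.items() if ln > 0}


def count_pe_links(
    pairs: Iterable[ReadPairAlignment],
    contig_lengths: Mapping[str, int],
    window: int,
) -> tuple[dict[tuple[Endpoint, Endpoint], int], int]:
    """Count qualifying read pairs per (contig end, contig end) connection.

    A pair qualifies when both mates are mapped, on different contigs, and
    each lies within ``window`` of the contig end it points off.  Returns the
    counts (endpoint pairs sorted for a canonical key) and the number of
    inter-contig pairs discarded by the window rule.
    """
    counts: Counter[tuple[Endpoint, Endpoint]] = Counter()
    discarded = 0
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if not (m1.mapped and m2.mapped) or m1.contig_id == m2.contig_id:
            continue
        e1 = mate_endpoint(m1, contig_lengths[m1.contig_id], window)
        e2 = mate_endpoint(m2, contig_lengths[m2.contig_id], window)
        if e1 is None or e2 is None:
            discarded += 1
            continue
        counts[tuple(sorted((e1, e2)))] += 1
    if discarded:
        logger.info("%d inter-contig pairs fell outside the end window", discarded)
    return dict(counts), discarded


def filter_links(
    counts: Mapping[tuple[Endpoint, Endpoint], int], cutoff: int
) -> list[LinkEdge]:
    """Keep connections with strictly more than ``cutoff`` supporting pairs."""
    return [
        LinkEdge(a, b, n)
        for (a, b), n in sorted(counts.items())
        if n > cutoff
    ]


# ---------------------------------------------------------------------------
# classification against the cGOF strings
# ---------------------------------------------------------------------------


def string_internal_adjacencies(
    strings: Sequence[ScaffoldString],
) -> set[frozenset[Endpoint]]:
    adj = set()
    for s in strings:
        for p, q in zip(s.placements, s.placements[1:]):
            end_p = (p.contig_id, TAIL if p.orient == 1 else HEAD)
            end_q = (q.contig_id, HEAD if q.orient == 1 else TAIL)
            adj.add(frozenset((end_p, end_q)))
    return adj


def classify_adjacency(
    edge: LinkEdge,
    internal: set[frozenset[Endpoint]],
    statuses: Mapping[str, str],
) -> str:
    """Classify an edge against the cGOF-predicted order.

    consistent: the exact facing-end adjacency already predicted by a string.
    conflicting: it would displace a cGOF adjacency (an endpoint is an
    interior end of a string) or touches an ambiguous contig.
    uninformative: both endpoints are free string termini or ends of
    unindexed contigs — the cGOF order says nothing about it.
    """
    pair = frozenset(edge.ends)
    if pair in internal:
        return CONSISTENT
    interior = {e for a in internal for e in a}
    for end in edge.ends:
        if end in interior:
            return CONFLICTING
        if statuses.get(end[0]) == "ambiguous":
            return CONFLICTING
    return UNINFORMATIVE


def edge_confidence(edge: LinkEdge, cfg: GaapConfig) -> float:
    """The weighted confidence of a classified, count-filtered edge."""
    if edge.category == CONSISTENT:
        return 1.0
    if edge.category == CONFLICTING:
        return 0.0
    link = min(1.0, edge.count / cfg.l_sat)
    return cfg.alpha * 0.0 + (1.0 - cfg.alpha) * link


def classify_and_score(
    edges: Sequence[LinkEdge],
    strings: Sequence[ScaffoldString],
    indices: Sequence[ContigIndex],
    cfg: GaapConfig,
) -> list[LinkEdge]:
    internal = string_internal_adjacencies(strings)
    statuses = {idx.contig_id: idx.status for idx in indices}
    out = []
    for edge in edges:
        category = classify_adjacency(edge, internal, statuses)
        edge = replace(edge, category=category)
        out.append(replace(edge, confidence=edge_confidence(edge, cfg)))
    return out


# ---------------------------------------------------------------------------
# chain resolution
# ---------------------------------------------------------------------------


def _repeat_copy_counts(
    edges: Sequence[LinkEdge],
    indices: Sequence[ContigIndex],
    depths: Mapping[str, float],
    cfg: GaapConfig,
) -> dict[str, int]:
    """How many placements each repeat-like unindexed contig may take."""
    if not depths:
        return {}
    median_depth = statistics.median(depths.values())
    if median_depth <= 0:
        return {}
    strong: Counter[str] = Counter()
    for edge in edges:
        if edge.confidence >= cfg.repeat_min_conf:
            for end in edge.ends:
                strong[end[0]] += 1
    copies = {}
    for idx in indices:
        cid = idx.contig_id
        depth = depths.get(cid, 0.0)
        if (
            idx.status == "unindexed"
            and depth >= cfg.repeat_depth_factor * median_depth
            and strong[cid] >= cfg.repeat_min_edges
        ):
            copies[cid] = min(cfg.max_repeat_copies, max(2, round(depth / median_depth)))
            logger.info("contig %s treated as repeat (%d copies allowed)", cid, copies[cid])
    return copies


def resolve_chains(
    edges: Sequence[LinkEdge],
    strings: Sequence[ScaffoldString],
    indices: Sequence[ContigIndex],
    depths: Mapping[str, float],
    cfg: GaapConfig,
) -> tuple[list[ScaffoldString], list[LinkEdge]]:
    """Greedy maximum-confidence matching, then emit the extended strings.

    Edges are attached in order of descending confidence (ties: higher count,
    then endpoint ids) and only when both endpoints are free; zero-confidence
    edges never attach, so the cGOF-internal adjacencies are never displaced.
    Repeat-like contigs are cloned so they can bridge several junctions.
    Cycles are opened at their lowest-confidence attached edge.
    """
    internal = string_internal_adjacencies(strings)
    interior = {e for a in internal for e in a}
    copies = _repeat_copy_counts(edges, indices, depths, cfg)

    clone_of: dict[str, str] = {}  # clone node -> real contig

    def clone_nodes(cid: str) -> list[str]:
        return [f"{cid}\x00{i}" for i in range(copies[cid])]

    matched: dict[Endpoint, tuple[Endpoint, LinkEdge]] = {}

    def resolve_endpoint(end: Endpoint) -> Endpoint | None:
        cid, side = end
        if cid not in copies:
            return None if (end in interior or end in matched) else end
        # prefer a clone whose other side is already matched but this side free
        free = None
        for node in clone_nodes(cid):
            this, other = (node, side), (node, TAIL if side == HEAD else HEAD)
            if this in matched:
                continue
            if other in matched:
                return this
            if free is None:
                free = this
        return free

    attached: list[LinkEdge] = []
    order = sorted(edges, key=lambda e: (-e.confidence, -e.count, e.ends))
    for edge in order:
        if edge.confidence <= 0.0 or edge.category == CONSISTENT:
            continue
        a = resolve_endpoint(edge.end_a)
        b = resolve_endpoint(edge.end_b)
        if a is None or b is None:
            continue
        for node in (a[0], b[0]):
            if "\x00" in node:
                clone_of[node] = node.split("\x00")[0]
        matched[a] = (b, edge)
        matched[b] = (a, edge)
        attached.append(edge)

    extended = _emit_chains(strings, indices, matched, clone_of, cfg)
    return extended, attached


def _emit_chains(strings, indices, matched, clone_of, cfg) -> list[ScaffoldString]:
    # nodes: existing strings (as rigid units) + unindexed contigs/clones with edges
    placements_of = {s.string_id: list(s.placements) for s in strings}
    node_ends: dict[Endpoint, tuple[str, str]] = {}  # contig end -> (node, node side)
    for s in strings:
        first, last = s.placements[0], s.placements[-1]
        node_ends[(first.contig_id, HEAD if first.orient == 1 else TAIL)] = (s.string_id, HEAD)
        node_ends[(last.contig_id, TAIL if last.orient == 1 else HEAD)] = (s.string_id, TAIL)
    loose = sorted({e[0] for e in matched} - {e[0] for e in node_ends})
    for node in loose:
        node_ends[(node, HEAD)] = (node, HEAD)
        node_ends[(node, TAIL)] = (node, TAIL)

    # node-level adjacency from matched contig-end pairs
    node_adj: dict[tuple[str, str], tuple[tuple[str, str], LinkEdge]] = {}
    for end, (other, edge) in matched.items():
        if end not in node_ends or other not in node_ends:
            continue
        node_adj[node_ends[end]] = (node_ends[other], edge)

    # break cycles at the lowest-confidence edge
    visited_nodes: set[str] = set()
    node_ids = sorted({n for n, _ in node_ends.values()})
    for nid in node_ids:
        if nid in visited_nodes or (nid, HEAD) not in node_adj and (nid, TAIL) not in node_adj:
            continue
        # find component; if it is a cycle, open it
        comp, cycle = _trace_component(nid, node_adj)
        visited_nodes |= comp
        if cycle:
            worst = min(cycle, key=lambda item: (item[2].confidence, item[0], item[1]))
            del node_adj[worst[0]], node_adj[worst[1]]
            logger.info("cycle opened at edge %s", worst[2].ends)

    # walk node chains
    seen: set[str] = set()
    out: list[ScaffoldString] = []

    def emit(start_node: str, enter_side: str):
        placements: list[Placement] = []
        node, side = start_node, enter_side
        while True:
            seen.add(node)
            unit = _node_placements(node, side, placements_of, clone_of)
            if placements:
                placements[-1].gap_after = cfg.default_gap
            placements.extend(unit)
            exit_side = TAIL if side == HEAD else HEAD
            nxt = node_adj.get((node, exit_side))
            if nxt is None:
                break
            (node, side) = nxt[0]
        out.append(ScaffoldString(f"str{len(out) + 1}", placements))

    termini = sorted(
        (nid, side)
        for nid in node_ids
        for side in (HEAD, TAIL)
        if (nid, side) not in node_adj
    )
    for nid, side in termini:
        if nid not in seen:
            emit(nid, side)
    for nid in node_ids:
        if nid not in seen:  # pragma: no cover - cycles were opened above
            emit(nid, HEAD)
    for i, s in enumerate(out, start=1):
        s.string_id = f"str{i}"
    return out


def _trace_component(start, node_adj):
    comp, cycle_edges = {start}, []
    for first_side in (HEAD, TAIL):
        node, side = start, first_side
        while (node, side) in node_adj:
            (nxt, nxt_side), edge = node_adj[(node, side)]
            key_a, key_b = (node, side), (nxt, nxt_side)
            cycle_edges.append((key_a, key_b, edge))
            if nxt in comp:
                return comp, cycle_edges  # closed a cycle
            comp.add(nxt)
            node, side = nxt, (TAIL if nxt_side == HEAD else HEAD)
    return comp, []


def _node_placements(node, enter_side, placements_of, clone_of):
    if node in placements_of:  # a string unit
        unit = [Placement(p.contig_id, p.orient, p.gap_after) for p in placements_of[node]]
        if enter_side == TAIL:
            _reverse_unit(unit)
        return unit
    cid = clone_of.get(node, node)
    return [Placement(cid, 1 if enter_side == HEAD else -1, None)]


def _reverse_unit(unit: list[Placement]) -> None:
    gaps = [p.gap_after for p in unit]
    unit.reverse()
    for p in unit:
        p.orient = -p.orient
    rev_gaps = (gaps[-2::-1] if len(gaps) > 1 else []) + [None]
    for p, g in zip(unit, rev_gaps):
        p.gap_after = g


# ---------------------------------------------------------------------------
# witnessed segment junctions (for guide-permutation filtering)
# ---------------------------------------------------------------------------


def witnessed_junctions(
    strings: Sequence[ScaffoldString], indices: Sequence[ContigIndex]
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Signed segment adjacencies directly observed in the extended strings.

    Both overbridge contigs and read-pair joins between strings leave their
    mark here: walking each string yields a sequence of signed segments, and
    every transition between two distinct segments is a witnessed junction
    (canonicalized so (x, y) equals (-y, -x)).
    """
    by_id = {idx.contig_id: idx for idx in indices}
    junctions = set()
    for s in strings:
        signed: list[tuple[str, int]] = []
        for p in s.placements:
            idx = by_id.get(p.contig_id)
            if idx is None or not idx.intervals:
                continue
            ivs = idx.intervals if p.orient == 1 else list(reversed(idx.intervals))
            for iv in ivs:
                entry = (iv.segment_id, iv.orient * p.orient)
                if not signed or signed[-1] != entry:
                    signed.append(entry)
        for a, b in zip(signed, signed[1:]):
            if a[0] != b[0]:
                junctions.add(canonical_junction(a, b))
    return junctions


def canonical_junction(
    a: tuple[str, int], b: tuple[str, int]
) -> tuple[tuple[str, int], tuple[str, int]]:
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class LocalScaffoldResult:
    strings: list[ScaffoldString]
    edges: list[LinkEdge]
    attached: list[LinkEdge]
    junctions: set
    insert_size: int
    depths: dict[str, float]


def local_scaffold(
    strings: Sequence[ScaffoldString],
    indices: Sequence[ContigIndex],
    pairs: Iterable[ReadPairAlignment],
    contig_lengths: Mapping[str, int],
    cfg: GaapConfig,
) -> LocalScaffoldResult:
    """Run the full local-scaffolding pass over a stream of read pairs."""
    pairs = list(pairs)
    window = cfg.end_window if cfg.end_window is not None else estimate_insert_size(pairs)
    depths = contig_depths(pairs, contig_lengths)
    counts, _ = count_pe_links(pairs, contig_lengths, window)
    edges = filter_links(counts, cfg.link_cutoff)
    edges = classify_and_score(edges, strings, indices, cfg)
    extended, attached = resolve_chains(edges, strings, indices, depths, cfg)
    junctions = witnessed_junctions(extended, indices)
    return LocalScaffoldResult(extended, edges, attached, junctions, window, depths)
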