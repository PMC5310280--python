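"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's algorithms: segment finding is done by
exhaustive enumeration of consecutive runs, link counting by a literal
case-table classifier, and pattern compatibility by materializing every
rotation/reflection of a pattern.
"""

from __future__ import annotations

from collections import Counter

SignedGene = tuple[str, int]


def _flip_run(run):
    return [(g, -s) for g, s in reversed(run)]


def occurs(run, order, circular: bool) -> bool:
    """Does the run (or its signed reversal) appear consecutively in order?"""
    n, l = len(order), len(run)
    if l > n:
        return False
    hay = list(order) + (list(order) if circular else [])
    starts = range(n) if circular else range(n - l + 1)
    for candidate in (list(run), _flip_run(run)):
        for s in starts:
            if hay[s : s + l] == candidate:
                return True
    return False


def canonical_run(run, full_circle: bool):
    """Orientation- (and for full circles rotation-) independent key."""
    variants = [tuple(run), tuple(_flip_run(run))]
    if full_circle:
        base = list(variants)
        variants = []
        for v in base:
            for r in range(len(v)):
                variants.append(v[r:] + v[:r])
    return min(variants)


def brute_force_segments(orders, circular: bool = True, min_len: int = 2) -> set:
    """Maximal runs of the first order conserved (fwd or reversed) in all.

    ``orders`` must be sorted by genome id; enumeration tests every
    consecutive run of the first order against every other order.
    """
    first = list(orders[0])
    n = len(first)
    others = [list(o) for o in orders[1:]]

    def run_at(s, l):
        if circular:
            return [first[(s + i) % n] for i in range(l)]
        return first[s : s + l]

    conserved = set()
    max_l = n if circular else n
    for l in range(1, max_l + 1):
        starts = range(n) if circular else range(n - l + 1)
        for s in starts:
            if all(occurs(run_at(s, l), o, circular) for o in others):
                conserved.add((s, l))

    def extendable(s, l):
        if l >= n:
            return False
        if circular:
            return ((s - 1) % n, l + 1) in conserved or (s, l + 1) in conserved
        left = s > 0 and (s - 1, l + 1) in conserved
        right = s + l < n and (s, l + 1) in conserved
        return left or right

    out = set()
    for (s, l) in conserved:
        if l >= min_len and not extendable(s, l):
            out.add(canonical_run(run_at(s, l), full_circle=(circular and l == n)))
    return out


# ---------------------------------------------------------------------------
# paired-end link counting
# ---------------------------------------------------------------------------

# literal case table: (mate strand, which end it can support)
_STRAND_END = {"+": "T", "-": "H"}


def _mate_end(mate, length: int, window: int):
    end = _STRAND_END[mate.strand]
    if end == "T":
        return (mate.contig_id, "T") if length - mate.pos <= window else None
    return (mate.contig_id, "H") if mate.pos + mate.read_len <= window else None


def brute_force_link_counts(pairs, lengths, window: int) -> dict:
    counts: Counter = Counter()
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if not (m1.mapped and m2.mapped) or m1.contig_id == m2.contig_id:
            continue
        e1 = _mate_end(m1, lengths[m1.contig_id], window)
        e2 = _mate_end(m2, lengths[m2.contig_id], window)
        if e1 and e2:
            counts[tuple(sorted((e1, e2)))] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# pattern compatibility
# ---------------------------------------------------------------------------


def pattern_variants(pattern):
    """Every rotation of the pattern and of its signed reflection."""
    seqs = [tuple(pattern), tuple((sid, -s) for sid, s in reversed(pattern))]
    out = []
    for seq in seqs:
        for r in range(len(seq)):
            out.append(seq[r:] + seq[:r])
    return out


def brute_force_compatible(pattern, junctions) -> bool:
    """A pattern is compatible iff some variant realizes every witnessed
    junction as a literal consecutive pair (circularly)."""

    def realized(variant, junction):
        a, b = junction
        n = len(variant)
        for i in range(n):
            x, y = variant[i], variant[(i + 1) % n]
            if (x, y) == (a, b):
                return True
        return False

    for junction in junctions:
        a, b = junction
        mirrored = ((b[0], -b[1]), (a[0], -a[1]))
        if not any(
            realized(v, junction) or realized(v, mirrored) for v in pattern_variants(pattern)
        ):
            return False
    return True
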