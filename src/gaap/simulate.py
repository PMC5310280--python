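"""Synthetic pangenome, draft-contig and read-pair simulator.

The generator emulates the statistical structure the scaffolder relies on: a
set of circular reference genomes that all carry the same single-copy core
genes with conserved within-segment order, while the segments themselves are
rearranged between genomes (free signed shuffles, or symmetric in-place
inversions of the kind seen around the Ori-Ter replication axis); dispensable
genes present in only some genomes at volatile positions; a target genome
whose segment arrangement is drawn from the references (or deliberately from
none of them, to exercise the novel-arrangement verdict); draft contigs cut
from the target; and 2 x 100 bp paired-end reads with a 2% substitution
error rate.  A truth SAM places every read at its exact contig of origin,
standing in for a production read mapper; a small exact-seed mapper is also
provided for FASTQ input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import ClusterTable, MateAlignment, ReadPairAlignment
from .pseudo import canonicalize_permutation, revcomp

logger = logging.getLogger("gaap")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated species.

    Defaults mirror a small intra-species pangenome sequenced with a standard
    short-insert library: ten complete references, a few hundred core genes in
    a handful of rearranging segments, 2 x 100 bp pairs at >= 100x coverage
    with a 2% base error rate.
    """

    n_refs: int = 10
    n_core: int = 200
    n_dispensable: int = 40
    n_segments: int = 4
    gene_len: tuple[int, int] = (400, 800)
    spacer_len: tuple[int, int] = (50, 150)
    rearrangement: str = "free"          # 'free' | 'symmetric'
    target_pattern: str = "reference"    # 'reference' | 'novel'
    dispensable_presence: float = 0.5
    n_repeat_copies: int = 4
    repeat_len: int = 600
    n_breaks: int = 40
    break_policy: str = "uniform"        # 'uniform' | 'at-repeats'
    min_contig_len: int = 300
    read_len: int = 100
    insert_mean: int = 500
    insert_sd: int = 50
    error_rate: float = 0.02
    coverage: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments > self.n_core // 2:
            raise ValueError("each segment needs at least two core genes")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert size must exceed twice the read length")
        if self.rearrangement not in ("free", "symmetric"):
            raise ValueError(f"unknown rearrangement model {self.rearrangement!r}")
        if self.target_pattern not in ("reference", "novel"):
            raise ValueError(f"unknown target_pattern mode {self.target_pattern!r}")
        for name in ("n_refs", "n_core", "n_segments", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthSet:
    """Everything needed to score a scaffolding result without external tools."""

    target_seq: str
    target_gene_coords: pd.DataFrame       # cluster_id, start, end, strand (0-based half-open)
    target_pattern: tuple                   # planted signed segment order
    repeat_intervals: list[tuple[int, int]]
    contig_placements: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (contig_id, start on target, length, orient)

    @property
    def length(self) -> int:
        return len(self.target_seq)


@dataclass
class SimulatedPangenome:
    config: SimConfig
    gene_seqs: dict[str, str]
    core_genes: list[str]
    planted_segments: list[list[tuple[str, int]]]
    ref_patterns: dict[str, tuple]
    references: dict[str, str]
    cluster_table: ClusterTable  # reference genomes only
    truth: TruthSet


def _rand_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _pattern_adjacency_sets(patterns):
    from .linking import canonical_junction

    sets = []
    for pattern in patterns:
        n = len(pattern)
        sets.append(
            {canonical_junction(pattern[i], pattern[(i + 1) % n]) for i in range(n)}
            if n > 1
            else set()
        )
    return sets


def _draw_pattern(segment_names: list[str], model: str, rng: np.random.Generator):
    signs = rng.integers(0, 2, len(segment_names)) * 2 - 1
    if model == "symmetric":
        order = list(range(len(segment_names)))
    else:
        order = list(rng.permutation(len(segment_names)))
    return tuple((segment_names[i], int(signs[j])) for j, i in enumerate(order))


def simulate_pangenome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedPangenome:
    """Generate references, cluster table, target genome and its truth set.

    Every reference carries all core genes single-copy with conserved
    within-segment order; segment permutations vary per the rearrangement
    model.  In ``target_pattern='novel'`` mode the reference patterns are
    additionally required to share no segment adjacency, so the identified
    segments coincide with the planted ones and the target's arrangement is
    guaranteed to match no reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    core = [f"g{i + 1:04d}" for i in range(cfg.n_core)]
    disp = [f"d{i + 1:04d}" for i in range(cfg.n_dispensable)]
    gene_seqs = {
        g: _rand_dna(rng, int(rng.integers(cfg.gene_len[0], cfg.gene_len[1] + 1)))
        for g in core + disp
    }
    base_strand = {g: int(s) for g, s in zip(core, rng.integers(0, 2, cfg.n_core) * 2 - 1)}

    # partition the core order into contiguous planted segments (each >= 2 genes)
    cuts = np.sort(rng.choice(np.arange(2, cfg.n_core - 1, 2), cfg.n_segments - 1, replace=False))
    bounds = [0, *cuts.tolist(), cfg.n_core]
    planted = [
        [(g, base_strand[g]) for g in core[a:b]] for a, b in zip(bounds, bounds[1:])
    ]
    seg_names = [f"P{i + 1}" for i in range(cfg.n_segments)]

    ref_ids = [f"ref{i + 1:02d}" for i in range(cfg.n_refs)]
    for _ in range(1000):
        patterns = {rid: _draw_pattern(seg_names, cfg.rearrangement, rng) for rid in ref_ids}
        if cfg.target_pattern != "novel":
            break
        shared = set.intersection(*_pattern_adjacency_sets(list(patterns.values())))
        if not shared:
            break
    else:
        raise ValueError("could not draw reference patterns without a shared adjacency")

    if cfg.target_pattern == "reference":
        target_pattern = patterns[ref_ids[int(rng.integers(0, cfg.n_refs))]]
    else:
        ref_canon = {canonicalize_permutation(p) for p in patterns.values()}
        for _ in range(1000):
            target_pattern = _draw_pattern(seg_names, "free", rng)
            if canonicalize_permutation(target_pattern) not in ref_canon:
                break
        else:
            raise ValueError("no novel arrangement exists for this configuration")

    seg_by_name = dict(zip(seg_names, planted))
    presence = {
        rid: {d for d in disp if rng.random() < cfg.dispensable_presence} for rid in ref_ids
    }
    presence["target"] = {d for d in disp if rng.random() < cfg.dispensable_presence}
    # dispensable means not shared by all strains: a gene drawn into every
    # reference would otherwise masquerade as a (position-volatile) core gene
    for d in disp:
        carriers = [rid for rid in ref_ids if d in presence[rid]]
        if len(carriers) == len(ref_ids):
            presence[carriers[int(rng.integers(0, len(carriers)))]].discard(d)

    rows, references = [], {}
    for rid in ref_ids:
        seq, coords = _layout_genome(
            rid, patterns[rid], seg_by_name, presence[rid], gene_seqs, cfg, rng
        )
        references[rid] = seq
        rows.extend(coords)
    table = ClusterTable(
        pd.DataFrame(rows, columns=["cluster_id", "genome_id", "replicon_id", "start", "end", "strand"])
    )

    target_seq, target_coords, repeat_ivs = _layout_genome(
        "target", target_pattern, seg_by_name, presence["target"], gene_seqs, cfg, rng,
        with_repeats=True,
    )
    truth = TruthSet(
        target_seq=target_seq,
        target_gene_coords=pd.DataFrame(
            target_coords,
            columns=["cluster_id", "genome_id", "replicon_id", "start", "end", "strand"],
        ),
        target_pattern=target_pattern,
        repeat_intervals=repeat_ivs,
    )
    return SimulatedPangenome(
        cfg, gene_seqs, core, planted, patterns, references, table, truth
    )


def _layout_genome(genome_id, pattern, seg_by_name, present_disp, gene_seqs, cfg, rng,
                   with_repeats: bool = False):
    """Lay genes end to end with random spacers; returns seq, coord rows[, repeats]."""
    gene_walk: list[tuple[str, int]] = []
    for sid, sign in pattern:
        genes = seg_by_name[sid]
        gene_walk.extend(genes if sign == 1 else [(g, -s) for g, s in reversed(genes)])
    # dispensable genes drop in at volatile slots (after the i-th core gene)
    slots: dict[int, list[tuple[str, int]]] = {}
    for d in sorted(present_disp):
        slot = int(rng.integers(0, len(gene_walk) + 1))
        strand = int(rng.integers(0, 2)) * 2 - 1
        slots.setdefault(slot, []).append((d, strand))
    repeat_seq = _rand_dna(rng, cfg.repeat_len) if with_repeats else ""
    repeat_slots = (
        set(rng.choice(len(gene_walk), min(cfg.n_repeat_copies, len(gene_walk)), replace=False).tolist())
        if with_repeats and cfg.n_repeat_copies
        else set()
    )

    parts: list[str] = []
    rows = []
    repeats: list[tuple[int, int]] = []
    pos = 0

    def spacer():
        nonlocal pos
        n = int(rng.integers(cfg.spacer_len[0], cfg.spacer_len[1] + 1))
        parts.append(_rand_dna(rng, n))
        pos += n

    def place(gene: str, strand: int):
        nonlocal pos
        seq = gene_seqs[gene]
        parts.append(seq if strand == 1 else revcomp(seq))
        rows.append((gene, genome_id, "chr", pos, pos + len(seq), "+" if strand == 1 else "-"))
        pos += len(seq)

    for i, (gene, strand) in enumerate(gene_walk):
        for d, s in slots.get(i, []):
            place(d, s)
            spacer()
        if i in repeat_slots:
            parts.append(repeat_seq)
            repeats.append((pos, pos + len(repeat_seq)))
            pos += len(repeat_seq)
            spacer()
        place(gene, strand)
        spacer()
    for d, s in slots.get(len(gene_walk), []):
        place(d, s)
        spacer()

    seq = "".join(parts)
    if with_repeats:
        return seq, rows, repeats
    return seq, rows


# ---------------------------------------------------------------------------
# fragmentation into draft contigs
# ---------------------------------------------------------------------------


def fragment_target(
    truth: TruthSet,
    n_breaks: int,
    policy: str = "uniform",
    rng: np.random.Generator | None = None,
    min_len: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Cut the circular target into contigs; truth placements are recorded.

    The circle is always opened at position 0; ``n_breaks`` additional break
    points produce ``n_breaks + 1`` contigs.  ``uniform`` draws fragment
    lengths with a hard floor of ``min_len``; ``at-repeats`` places every
    break inside a planted repeat element.  Contigs are emitted on a random
    strand so orientation recovery is actually exercised.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = truth.length
    if n_breaks >= L // 1000:
        raise ValueError("too many breaks for this target size")
    if policy == "uniform":
        k = n_breaks + 1
        extra = rng.multinomial(L - min_len * k, np.full(k, 1.0 / k))
        lengths = extra + min_len
        breaks = np.cumsum(lengths)[:-1].tolist()
    elif policy == "at-repeats":
        if not truth.repeat_intervals:
            raise ValueError("no planted repeats to break at")
        ivs = [truth.repeat_intervals[int(i)] for i in
               rng.choice(len(truth.repeat_intervals), n_breaks, replace=n_breaks > len(truth.repeat_intervals))]
        breaks = sorted({int(rng.integers(a + 1, b - 1)) for a, b in ivs})
    else:
        raise ValueError(f"unknown break policy {policy!r}")
    edges = [0, *breaks, L]
    contigs: dict[str, str] = {}
    placements = []
    for i, (a, b) in enumerate(zip(edges, edges[1:]), start=1):
        cid = f"ctg{i:04d}"
        seq = truth.target_seq[a:b]
        orient = 1 if rng.random() < 0.5 else -1
        contigs[cid] = seq if orient == 1 else revcomp(seq)
        placements.append((cid, a, b - a, orient))
    truth.contig_placements = placements
    return contigs


def tile_reference(
    sequence: str,
    gene_coords: pd.DataFrame,
    n_pieces: int,
    rng: np.random.Generator,
    flip: bool = True,
) -> dict[str, str]:
    """Cut a genome into an exact tiling with every cut between two core genes.

    Each tile then carries at least one complete gene, so the tiling is fully
    indexable without read data.  Tiles are emitted on a random strand when
    ``flip`` is set.
    """
    coords = gene_coords.sort_values("start")
    mids = [
        (int(a) + int(b)) // 2
        for a, b in zip(coords["end"].values[:-1], coords["start"].values[1:])
        if b > a
    ]
    if n_pieces - 1 > len(mids):
        raise ValueError("not enough intergenic positions for that many pieces")
    picks = sorted(rng.choice(len(mids), n_pieces - 1, replace=False).tolist())
    edges = [0, *[mids[i] for i in picks], len(sequence)]
    contigs = {}
    for i, (a, b) in enumerate(zip(edges, edges[1:]), start=1):
        seq = sequence[a:b]
        if flip and rng.random() < 0.5:
            seq = revcomp(seq)
        contigs[f"tile{i:03d}"] = seq
    return contigs


# ---------------------------------------------------------------------------
# paired-end reads with truth alignments
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    reads1: list[tuple[str, str]]
    reads2: list[tuple[str, str]]
    truth_pairs: list[ReadPairAlignment]


def simulate_pe_reads(
    truth: TruthSet, cfg: SimConfig, rng: np.random.Generator | None = None
) -> ReadSet:
    """Uniform 2 x ``read_len`` pairs from the circular target.

    Substitution errors only, at ``cfg.error_rate`` per base (no indels).
    The truth alignments place each mate on the contig its span falls inside
    (a mate straddling a contig break or the origin is unmapped).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L, rl = truth.length, cfg.read_len
    n_pairs = int(round(cfg.coverage * L / (2 * rl)))
    starts = rng.integers(0, L, n_pairs)
    inserts = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)), 2 * rl + 10, None
    ).astype(np.int64)

    genome = np.frombuffer(truth.target_seq.encode(), dtype=np.uint8)
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    genome_codes = code[genome]

    offs = np.arange(rl)
    idx1 = (starts[:, None] + offs) % L
    m2_start = (starts + inserts - rl) % L
    idx2 = (m2_start[:, None] + offs) % L
    codes1 = genome_codes[idx1]
    codes2 = 3 - genome_codes[idx2][:, ::-1]  # reverse-complement mate

    for codes in (codes1, codes2):
        mask = rng.random(codes.shape) < cfg.error_rate
        shift = rng.integers(1, 4, codes.shape, dtype=np.uint8)
        codes[mask] = (codes[mask] + shift[mask]) % 4

    seqs1 = _BASES[codes1]
    seqs2 = _BASES[codes2]

    # contig-of-origin lookup
    placements = sorted(truth.contig_placements, key=lambda p: p[1])
    c_starts = np.array([p[1] for p in placements])
    c_lens = np.array([p[2] for p in placements])

    def locate(a: int, span: int):
        b = a + span
        if b > L:
            return None  # wraps the origin, and the origin is a contig break
        i = int(np.searchsorted(c_starts, a, side="right")) - 1
        cid, cstart, clen, orient = placements[i]
        if b > cstart + clen:
            return None
        if orient == 1:
            return cid, a - cstart, 1
        return cid, cstart + clen - b, -1

    pairs: list[ReadPairAlignment] = []
    reads1, reads2 = [], []
    for i in range(n_pairs):
        name = f"pair{i:07d}"
        reads1.append((name, seqs1[i].tobytes().decode()))
        reads2.append((name, seqs2[i].tobytes().decode()))
        mates = []
        for a, target_strand in ((int(starts[i]), 1), (int(m2_start[i]), -1)):
            loc = locate(a, rl)
            if loc is None:
                mates.append(MateAlignment(None, 0, "+", False, rl))
            else:
                cid, pos, flip = loc
                strand = target_strand * flip
                mates.append(MateAlignment(cid, pos, "+" if strand == 1 else "-", True, rl))
        pairs.append(ReadPairAlignment(name, mates[0], mates[1]))
    return ReadSet(reads1, reads2, pairs)


# ---------------------------------------------------------------------------
# toy exact-seed mapper (test fixture; production input is SAM)
# ---------------------------------------------------------------------------


def map_reads_exact(
    reads1: Sequence[tuple[str, str]],
    reads2: Sequence[tuple[str, str]],
    contigs: Mapping[str, str],
    k: int = 21,
) -> list[ReadPairAlignment]:
    """Map reads by unique exact k-mer seeds.

    Deliberately minimal: the first seed that occurs at exactly one position
    across the contigs (forward or reverse-complement) places the read.
    Reads whose seeds are all absent or repeated go unmapped.  Good enough to
    exercise the SAM-free path on clean simulated data; not a real aligner.
    """
    index: dict[str, tuple[str, int] | None] = {}
    for cid, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            index[kmer] = None if kmer in index else (cid, i)

    def map_one(seq: str) -> MateAlignment:
        for candidate, strand in ((seq, "+"), (revcomp(seq), "-")):
            for off in range(0, len(candidate) - k + 1, k):
                hit = index.get(candidate[off : off + k])
                if hit is not None:
                    cid, pos = hit
                    start = pos - off
                    if 0 <= start <= len(contigs[cid]) - len(seq):
                        return MateAlignment(cid, start, strand, True, len(seq))
        return MateAlignment(None, 0, "+", False, len(seq))

    pairs = []
    for (name, s1), (_, s2) in zip(reads1, reads2):
        pairs.append(ReadPairAlignment(name, map_one(s1), map_one(s2)))
    return pairs
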