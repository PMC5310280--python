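"""Readers and writers for the external formats the pipeline touches.

Input side: the ortholog-cluster table (TSV), core-gene alignment hits (PSL
or 12-column BLAST tabular) and paired-end read alignments (SAM, via pysam).
Output side: FASTA, AGP 2.1 and the TSV reports (segments, permutations,
strings, edges).

Coordinates are 0-based half-open everywhere inside the package; dialect
conversion happens only at the file boundary.  AGP is emitted 1-based
inclusive as its standard requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("gaap")

_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-", "1": "+", "-1": "-"}

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _norm_strand(token: str, path, lineno: int) -> str:
    try:
        return _STRAND_ALIASES[str(token).strip()]
    except KeyError:
        raise ParseError(path, lineno, f"bad strand {token!r}") from None


# ---------------------------------------------------------------------------
# cluster table
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = ("cluster_id", "genome_id", "replicon_id", "start", "end", "strand")


@dataclass
class ClusterTable:
    """Single-copy placements of ortholog clusters on reference replicons.

    ``rows`` holds one row per (cluster, genome) pair that is single-copy in
    that genome, with 0-based half-open coordinates.  Pairs that appeared more
    than once in the input are recorded in ``multi_copy`` and excluded from
    core-gene use.
    """

    rows: pd.DataFrame
    multi_copy: set = field(default_factory=set)

    def genomes(self) -> list[str]:
        return sorted(self.rows["genome_id"].unique())

    def core_clusters(self, genomes: Sequence[str] | None = None) -> list[str]:
        """Clusters present (single-copy) in every one of ``genomes``."""
        genomes = list(genomes) if genomes is not None else self.genomes()
        sub = self.rows[self.rows["genome_id"].isin(genomes)]
        counts = sub.groupby("cluster_id")["genome_id"].nunique()
        return sorted(counts.index[counts == len(genomes)])

    def __len__(self) -> int:
        return len(self.rows)


def read_cluster_table(path: str | Path, dialect: str = "one_based") -> ClusterTable:
    """Read a cluster-membership TSV into a normalized :class:`ClusterTable`.

    ``dialect`` is ``"one_based"`` (inclusive coordinates, the usual
    annotation convention) or ``"zero_based"`` (half-open).  Rows whose
    (cluster, genome) pair occurs more than once are flagged as multi-copy
    and dropped from the table proper.
    """
    if dialect not in ("one_based", "zero_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            logger.warning("cluster table %s is empty", path)
            return ClusterTable(pd.DataFrame(columns=list(CLUSTER_COLUMNS)))
        cols = header.rstrip("\n").split("\t")
        missing = set(CLUSTER_COLUMNS) - set(cols)
        if missing:
            raise ParseError(path, 1, f"missing columns {sorted(missing)}")
        idx = {c: cols.index(c) for c in CLUSTER_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(cols):
                raise ParseError(path, lineno, f"expected {len(cols)} fields, got {len(parts)}")
            try:
                start = int(parts[idx["start"]])
                end = int(parts[idx["end"]])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if dialect == "one_based":
                start -= 1
            if start >= end:
                raise ParseError(path, lineno, f"empty interval {start}..{end}")
            records.append(
                (
                    parts[idx["cluster_id"]],
                    parts[idx["genome_id"]],
                    parts[idx["replicon_id"]],
                    start,
                    end,
                    _norm_strand(parts[idx["strand"]], path, lineno),
                )
            )
    df = pd.DataFrame(records, columns=list(CLUSTER_COLUMNS))
    dup_mask = df.duplicated(subset=["cluster_id", "genome_id"], keep=False)
    multi = set(map(tuple, df.loc[dup_mask, ["cluster_id", "genome_id"]].itertuples(index=False)))
    if multi:
        logger.warning("%d (cluster, genome) pairs are multi-copy; excluded from core use", len(multi))
    return ClusterTable(df[~dup_mask].reset_index(drop=True), multi)


def write_cluster_table(table: ClusterTable, path: str | Path, dialect: str = "one_based") -> None:
    df = table.rows.copy()
    if dialect == "one_based":
        df["start"] = df["start"] + 1
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene alignment hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a core-gene representative sequence on a contig."""

    query_id: str
    target_id: str
    query_span: tuple[int, int]   # 0-based half-open on the gene
    target_span: tuple[int, int]  # 0-based half-open on the contig, ascending
    strand: str                   # '+' gene forward on contig, '-' reverse
    identity: float
    query_coverage: float

    def score(self) -> float:
        return self.identity * self.query_coverage


def _parse_psl_line(parts: list[str], path, lineno: int) -> AlignmentHit:
    matches, mismatches, rep_matches = int(parts[0]), int(parts[1]), int(parts[2])
    strand = parts[8][0]
    q_name, q_size, q_start, q_end = parts[9], int(parts[10]), int(parts[11]), int(parts[12])
    t_name, t_start, t_end = parts[13], int(parts[15]), int(parts[16])
    aligned = matches + mismatches + rep_matches
    identity = (matches + rep_matches) / aligned if aligned else 0.0
    coverage = (q_end - q_start) / q_size if q_size else 0.0
    return AlignmentHit(
        query_id=q_name,
        target_id=t_name,
        query_span=(q_start, q_end),
        target_span=(t_start, t_end),
        strand=_norm_strand(strand, path, lineno),
        identity=identity,
        query_coverage=coverage,
    )


def _parse_tabular_line(
    parts: list[str], path, lineno: int, query_lengths: Mapping[str, int] | None
) -> AlignmentHit:
    qseqid, sseqid = parts[0], parts[1]
    pident = float(parts[2])
    qstart, qend = int(parts[6]), int(parts[7])
    sstart, send = int(parts[8]), int(parts[9])
    strand = "+" if send >= sstart else "-"
    t_lo, t_hi = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
    q_lo, q_hi = qstart - 1, qend
    if query_lengths is not None and qseqid in query_lengths:
        coverage = (q_hi - q_lo) / query_lengths[qseqid]
    else:
        coverage = 1.0
    return AlignmentHit(
        query_id=qseqid,
        target_id=sseqid,
        query_span=(q_lo, q_hi),
        target_span=(t_lo, t_hi),
        strand=strand,
        identity=pident / 100.0,
        query_coverage=min(1.0, coverage),
    )


def read_gene_hits(
    path: str | Path,
    format: str = "psl",
    query_lengths: Mapping[str, int] | None = None,
    known_contigs: set[str] | None = None,
) -> list[AlignmentHit]:
    """Read core-gene hits from a PSL or BLAST-tabular file.

    For the tabular layout the gene (query) lengths are not in the file, so
    ``query_lengths`` should be supplied to compute query coverage; without
    it coverage defaults to 1.0 with a warning.  Hits on contigs not in
    ``known_contigs`` (when given) are dropped with a warning.
    """
    if format not in ("psl", "tabular"):
        raise ValueError(f"unknown gene-hit format {format!r}")
    if format == "tabular" and query_lengths is None:
        logger.warning("tabular hits without query lengths: query coverage assumed 1.0")
    hits: list[AlignmentHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            # skip the optional psLayout header block
            if format == "psl" and not line.split("\t")[0].isdigit():
                continue
            parts = line.split("\t")
            try:
                if format == "psl":
                    hit = _parse_psl_line(parts, path, lineno)
                else:
                    hit = _parse_tabular_line(parts, path, lineno, query_lengths)
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, f"malformed {format} line: {exc}") from None
            if known_contigs is not None and hit.target_id not in known_contigs:
                dropped += 1
                continue
            hits.append(hit)
    if dropped:
        logger.warning("%d hits referenced unknown contigs and were dropped", dropped)
    return hits


# ---------------------------------------------------------------------------
# paired-end alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MateAlignment:
    contig_id: str | None
    pos: int          # 0-based leftmost
    strand: str       # '+' or '-'
    mapped: bool
    read_len: int


@dataclass(frozen=True)
class ReadPairAlignment:
    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def both_mapped(self) -> bool:
        return self.mate1.mapped and self.mate2.mapped


def _mate_from_record(rec: pysam.AlignedSegment) -> MateAlignment:
    if rec.is_unmapped:
        return MateAlignment(None, 0, "+", False, rec.query_length or 0)
    return MateAlignment(
        contig_id=rec.reference_name,
        pos=rec.reference_start,
        strand="-" if rec.is_reverse else "+",
        mapped=True,
        read_len=rec.query_length or (rec.reference_end - rec.reference_start),
    )


def read_pe_alignments(path: str | Path) -> Iterator[ReadPairAlignment]:
    """Stream mate pairs from a SAM file, joining records by query name.

    Secondary and supplementary records are ignored; orphan records (only
    one primary record for a query name) are skipped with a count logged.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            first, second = (other, rec) if other.is_read1 else (rec, other)
            yield ReadPairAlignment(rec.query_name, _mate_from_record(first), _mate_from_record(second))
    if pending:
        logger.warning("%d orphan SAM records skipped", len(pending))


def write_pe_alignments(
    pairs: Iterable[ReadPairAlignment], contig_lengths: Mapping[str, int], path: str | Path
) -> None:
    """Write mate pairs as a minimal coordinate-less SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": int(ln)} for cid, ln in sorted(contig_lengths.items())],
    }
    tid = {cid: i for i, (cid, _) in enumerate(sorted(contig_lengths.items()))}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for pair in pairs:
            for i, mate in enumerate((pair.mate1, pair.mate2)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = pair.pair_id
                rec.flag = 0x1 | (0x40 if i == 0 else 0x80)
                if mate.mapped:
                    rec.reference_id = tid[mate.contig_id]
                    rec.reference_start = mate.pos
                    rec.cigarstring = f"{mate.read_len}M"
                    if mate.strand == "-":
                        rec.flag |= 0x10
                else:
                    rec.flag |= 0x4
                rec.query_sequence = "N" * max(1, mate.read_len)
                rec.query_qualities = pysam.qualitystring_to_array("I" * max(1, mate.read_len))
                out.write(rec)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, topology: Mapping[str, str] | None = None) -> None:
    """Write sequences; ``topology`` entries add a ``topology=...`` header tag."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            tag = f" topology={topology[name]}" if topology and name in topology else ""
            fh.write(f">{name}{tag}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq_pair(
    reads1: Sequence[tuple[str, str]], reads2: Sequence[tuple[str, str]], prefix: str | Path
) -> tuple[Path, Path]:
    paths = (Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq"))
    for path, reads, suffix in zip(paths, (reads1, reads2), ("/1", "/2")):
        with open(path, "w") as fh:
            for name, seq in reads:
                fh.write(f"@{name}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# AGP 2.1
# ---------------------------------------------------------------------------


def write_agp(objects: Sequence[tuple[str, Sequence[tuple]]], path: str | Path) -> None:
    """Write AGP 2.1.

    ``objects`` is a list of (object_id, parts); each part is either
    ``("W", contig_id, contig_len, orientation)`` for a placed component or
    ``("N", gap_len)`` for an estimated scaffold gap.  Object coordinates are
    computed here so components always tile the object.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for obj_id, parts in objects:
            pos = 0
            for part_no, part in enumerate(parts, start=1):
                if part[0] == "W":
                    _, cid, length, orient = part
                    fh.write(
                        f"{obj_id}\t{pos + 1}\t{pos + length}\t{part_no}\tW\t"
                        f"{cid}\t1\t{length}\t{orient}\n"
                    )
                    pos += length
                elif part[0] == "N":
                    gap = int(part[1])
                    fh.write(
                        f"{obj_id}\t{pos + 1}\t{pos + gap}\t{part_no}\tN\t"
                        f"{gap}\tscaffold\tyes\tpaired-ends\n"
                    )
                    pos += gap
                else:  # pragma: no cover - defensive
                    raise ValueError(f"unknown AGP part type {part[0]!r}")


# ---------------------------------------------------------------------------
# TSV reports for segments / permutations (round-trippable)
# ---------------------------------------------------------------------------


def _render_signed(items: Iterable[tuple[str, int]]) -> str:
    return ",".join(("+" if sign > 0 else "-") + name for name, sign in items)


def _parse_signed(text: str) -> list[tuple[str, int]]:
    out = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        sign = -1 if token[0] == "-" else 1
        out.append((token.lstrip("+-"), sign))
    return out


def write_segments_tsv(segments, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment_id\tn_genes\tgenes\n")
        for seg in segments:
            fh.write(f"{seg.segment_id}\t{len(seg.genes)}\t{_render_signed(seg.genes)}\n")


def read_segments_tsv(path: str | Path):
    from .cgof import CgofSegment

    segments = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            seg_id, _, genes = line.rstrip("\n").split("\t")
            segments.append(CgofSegment(seg_id, tuple(_parse_signed(genes))))
    return segments


def write_permutations_tsv(permutations, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\treplicon_id\tsegments\n")
        for perm in permutations:
            fh.write(f"{perm.genome_id}\t{perm.replicon_id}\t{_render_signed(perm.segments)}\n")


def read_permutations_tsv(path: str | Path):
    from .cgof import SegmentPermutation

    perms = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            genome, replicon, segs = line.rstrip("\n").split("\t")
            perms.append(SegmentPermutation(genome, replicon, tuple(_parse_signed(segs))))
    return perms
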