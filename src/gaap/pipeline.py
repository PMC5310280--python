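"""End-to-end orchestration: identify -> index -> local scaffold -> pseudo.

The functions here wire the per-stage modules together and collect one result
object that the writers (and the CLI) can serialize.  Each stage is also
usable on its own from Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import formats
from .cgof import (
    CgofSegment,
    CoreGeneOrder,
    SegmentPermutation,
    build_core_orders,
    derive_permutations,
    identify_segments,
)
from .config import GaapConfig
from .formats import AlignmentHit, ClusterTable, ReadPairAlignment
from .indexing import (
    ContigIndex,
    ReferenceGapEstimator,
    ScaffoldString,
    assign_gene_hits,
    exact_gene_hits,
    index_contigs,
    merge_strings,
)
from .linking import LocalScaffoldResult, local_scaffold
from .pseudo import (
    PermutationVote,
    PseudoGenome,
    build_pseudo_genome,
    count_patterns,
    filter_conflicting,
    select_guide,
)

logger = logging.getLogger("gaap")

NOVEL_ARRANGEMENT = "novel arrangement"


@dataclass
class CgofResult:
    orders: list[CoreGeneOrder]
    segments: list[CgofSegment]
    permutations: list[SegmentPermutation]


def identify(table: ClusterTable, cfg: GaapConfig | None = None, circular: bool = True) -> CgofResult:
    """Extract cGOF segments and per-reference permutations from a cluster table."""
    cfg = cfg or GaapConfig()
    orders = build_core_orders(table, circular=circular)
    segments = identify_segments(orders, cfg.min_seg_len)
    permutations = derive_permutations(segments, orders)
    return CgofResult(orders, segments, permutations)


@dataclass
class ScaffoldResult:
    indices: list[ContigIndex]
    initial_strings: list[ScaffoldString]
    local: LocalScaffoldResult
    ambiguous_genes: set[str]

    @property
    def strings(self) -> list[ScaffoldString]:
        return self.local.strings


def scaffold(
    cgof: CgofResult,
    contigs: Mapping[str, str],
    hits: Sequence[AlignmentHit],
    pairs: Iterable[ReadPairAlignment],
    table: ClusterTable,
    cfg: GaapConfig | None = None,
) -> ScaffoldResult:
    """Index contigs by cGOF genes, merge into strings, extend with PE links."""
    cfg = cfg or GaapConfig()
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    per_contig, ambiguous_genes = assign_gene_hits(
        hits, cfg.min_identity, cfg.min_coverage, cfg.ambiguity_margin
    )
    indices = index_contigs(per_contig, cgof.segments, lengths)
    estimator = ReferenceGapEstimator(table, cfg.default_gap)
    strings, indices = merge_strings(indices, cgof.segments, estimator)
    local = local_scaffold(strings, indices, pairs, lengths, cfg)
    n_idx = sum(1 for i in indices if i.status == "indexed")
    logger.info(
        "%d/%d contigs indexed; %d strings before PE extension, %d after",
        n_idx, len(indices), len(strings), len(local.strings),
    )
    return ScaffoldResult(indices, strings, local, ambiguous_genes)


@dataclass
class PseudoResult:
    verdict: str  # 'pseudo-genome' | NOVEL_ARRANGEMENT
    pseudo: PseudoGenome | None
    votes: list[PermutationVote]
    guide: PermutationVote | None
    leftover_contigs: list[str] = field(default_factory=list)


def build_pseudo(
    cgof: CgofResult,
    scaf: ScaffoldResult,
    contigs: Mapping[str, str],
    table: ClusterTable,
    cfg: GaapConfig | None = None,
    name: str = "pseudogenome",
) -> PseudoResult:
    """Vote on reference permutations and emit the circular pseudo-genome,
    or report a novel arrangement when every reference pattern conflicts."""
    cfg = cfg or GaapConfig()
    votes = count_patterns(cgof.permutations)
    compatible = filter_conflicting(votes, scaf.local.junctions)
    guide = select_guide(compatible)
    placed: set[str] = set()
    if guide is None:
        logger.warning("all reference permutations conflict: %s", NOVEL_ARRANGEMENT)
        pseudo = None
        verdict = NOVEL_ARRANGEMENT
        for s in scaf.strings:
            placed.update(s.contig_ids())
    else:
        estimator = ReferenceGapEstimator(table, cfg.default_gap)
        pseudo, leftover_strings = build_pseudo_genome(
            scaf.strings, guide, scaf.indices, cgof.segments, contigs, estimator, cfg, name
        )
        verdict = "pseudo-genome"
        placed = {p.contig_id for p in pseudo.placements}
        del leftover_strings  # their contigs fall through to the leftovers below
    leftovers = sorted(set(contigs) - placed)
    return PseudoResult(verdict, pseudo, votes, guide, leftovers)


@dataclass
class PipelineResult:
    cgof: CgofResult
    scaffold: ScaffoldResult
    pseudo: PseudoResult
    contigs: Mapping[str, str]
    config: GaapConfig


def run_all(
    table: ClusterTable,
    contigs: Mapping[str, str],
    hits: Sequence[AlignmentHit] | None = None,
    gene_seqs: Mapping[str, str] | None = None,
    pairs: Iterable[ReadPairAlignment] = (),
    cfg: GaapConfig | None = None,
    circular: bool = True,
) -> PipelineResult:
    """The whole pipeline; give alignment ``hits`` or ``gene_seqs`` for the
    built-in exact matcher."""
    cfg = cfg or GaapConfig()
    cfg.log_parameters()
    if hits is None:
        if gene_seqs is None:
            raise ValueError("need gene hits or gene sequences")
        hits = exact_gene_hits(gene_seqs, contigs)
    cgof = identify(table, cfg, circular=circular)
    scaf = scaffold(cgof, contigs, hits, pairs, table, cfg)
    pres = build_pseudo(cgof, scaf, contigs, table, cfg)
    return PipelineResult(cgof, scaf, pres, contigs, cfg)


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Serialize a finished run: FASTA, AGP 2.1, TSV reports and leftovers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats.write_segments_tsv(result.cgof.segments, outdir / "segments.tsv")
    formats.write_permutations_tsv(result.cgof.permutations, outdir / "permutations.tsv")
    _write_contig_status(result.scaffold.indices, outdir / "contig_status.tsv")
    _write_edges(result.scaffold.local.edges, outdir / "edges.tsv")
    _write_strings(result.scaffold.strings, outdir / "chains.tsv")
    _write_guide_report(result.pseudo.votes, outdir / "guide_report.tsv", result.pseudo.verdict)

    contigs = result.contigs
    pseudo = result.pseudo.pseudo
    if pseudo is not None:
        formats.write_fasta(
            {pseudo.name: pseudo.sequence}, outdir / "pseudo.fasta", {pseudo.name: pseudo.topology}
        )
        parts = []
        pos = 0
        for placement in pseudo.placements:
            if placement.start > pos:
                parts.append(("N", placement.start - pos))
            parts.append((
                "W", placement.contig_id, placement.end - placement.start,
                "+" if placement.orient == 1 else "-",
            ))
            pos = placement.end
        if len(pseudo.sequence) > pos:
            parts.append(("N", len(pseudo.sequence) - pos))
        formats.write_agp([(pseudo.name, parts)], outdir / "pseudo.agp")
        with open(outdir / "unverified_adjacencies.tsv", "w") as fh:
            fh.write("left_string\tright_string\n")
            for a, b in pseudo.unverified:
                fh.write(f"{a}\t{b}\n")
    else:
        draft, topo, agp_objects = {}, {}, []
        from .formats import revcomp

        for s in result.scaffold.strings:
            seq_parts, agp_parts = [], []
            for p in s.placements:
                seq = contigs[p.contig_id]
                if p.orient == -1:
                    seq = revcomp(seq)
                seq_parts.append(seq)
                agp_parts.append(("W", p.contig_id, len(seq), "+" if p.orient == 1 else "-"))
                if p.gap_after:
                    seq_parts.append("N" * p.gap_after)
                    agp_parts.append(("N", p.gap_after))
            draft[s.string_id] = "".join(seq_parts)
            topo[s.string_id] = "linear"
            agp_objects.append((s.string_id, agp_parts))
        formats.write_fasta(draft, outdir / "draft.fasta", topo)
        formats.write_agp(agp_objects, outdir / "draft.agp")

    leftovers = {cid: contigs[cid] for cid in result.pseudo.leftover_contigs}
    formats.write_fasta(leftovers, outdir / "leftovers.fasta")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(f"verdict\t{result.pseudo.verdict}\n")
        if result.pseudo.guide is not None:
            fh.write(f"guide_prevalence\t{result.pseudo.guide.prevalence}\n")


def _write_contig_status(indices, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstatus\tn_gene_hits\tsegments\n")
        for idx in indices:
            segs = ";".join(
                f"{iv.segment_id}:{iv.gene_lo}-{iv.gene_hi}:{'+' if iv.orient == 1 else '-'}"
                for iv in idx.intervals
            )
            fh.write(f"{idx.contig_id}\t{idx.status}\t{idx.n_hits}\t{segs}\n")


def _write_edges(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tend_a\tcontig_b\tend_b\ttype\tn_links\tclass\tconfidence\n")
        for e in edges:
            fh.write(
                f"{e.end_a[0]}\t{e.end_a[1]}\t{e.end_b[0]}\t{e.end_b[1]}\t"
                f"{e.connection_type}\t{e.count}\t{e.category}\t{e.confidence:.4f}\n"
            )


def _write_strings(strings, path) -> None:
    with open(path, "w") as fh:
        fh.write("string_id\twalk\n")
        for s in strings:
            walk = ",".join(
                f"{p.contig_id}({'+' if p.orient == 1 else '-'})"
                + (f":{p.gap_after}" if p.gap_after is not None else "")
                for p in s.placements
            )
            fh.write(f"{s.string_id}\t{walk}\n")


def _write_guide_report(votes, path, verdict) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tprevalence\tgenomes\tcompatible\tverdict\n")
        for v in votes:
            pattern = ",".join(("+" if s > 0 else "-") + sid for sid, s in v.pattern)
            fh.write(
                f"{pattern}\t{v.prevalence}\t{';'.join(v.genomes)}\t"
                f"{'yes' if v.compatible else 'no'}\t{verdict}\n"
            )
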