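"""Truth-based scoring of a scaffolding result.

The evaluator compares the output's circular (or draft) order and orientation
of contigs against the known placements on the simulated target.  Because
output coordinates contain estimated gaps, scoring is order-based: the output
is split into maximal blocks whose signed contig order is consistent with the
truth (contigs absent from the output may be skipped silently — an omission
costs coverage, not an error).  Within each scaffold the largest block
anchors the frame; everything outside it is counted falsely located, and each
inconsistent junction is one error (a relocation or inversion breakpoint).
Corrected N50 is the N50 of the blocks, i.e. of the scaffolds after breaking
them at every detected error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .simulate import TruthSet

logger = logging.getLogger("gaap")

SignedContig = tuple[str, int]


@dataclass
class EvalMetrics:
    recovered_pct: float
    falsely_located_pct: float
    errors: int
    corrected_n50: int
    n_scaffolds: int


@dataclass
class OutputScaffold:
    """One output sequence as an ordered list of signed contigs."""

    contigs: list[SignedContig]
    circular: bool = False


def _truth_order(truth: TruthSet) -> list[SignedContig]:
    placed = sorted(truth.contig_placements, key=lambda p: p[1])
    return [(cid, orient) for cid, _, _, orient in placed]


def _successor_map(order: Sequence[SignedContig]) -> dict[SignedContig, SignedContig]:
    n = len(order)
    succ = {}
    for i, item in enumerate(order):
        succ[item] = order[(i + 1) % n]
    return succ


def _consistent(a: SignedContig, b: SignedContig, succ, present: set[str]) -> bool:
    """True when b follows a in truth with only absent contigs in between."""
    cur = succ.get(a)
    for _ in range(len(succ)):
        if cur is None:
            return False
        if cur == b:
            return True
        if cur[0] in present:
            return False
        cur = succ.get(cur)
    return False


def _flip_scaffold(s: OutputScaffold) -> OutputScaffold:
    return OutputScaffold([(c, -o) for c, o in reversed(s.contigs)], s.circular)


def _score(
    scaffolds: Sequence[OutputScaffold],
    succ,
    lengths: dict[str, int],
    present: set[str],
) -> tuple[int, int, list[int]]:
    """(falsely located bp, error count, block weights) for one global flip."""
    falsely = 0
    errors = 0
    blocks_all: list[int] = []
    for s in scaffolds:
        items = s.contigs
        ok = [
            _consistent(a, b, succ, present) for a, b in zip(items, items[1:])
        ]
        if s.circular and len(items) > 1:
            ok.append(_consistent(items[-1], items[0], succ, present))
        blocks: list[list[SignedContig]] = [[items[0]]]
        for i, good in enumerate(ok[: len(items) - 1]):
            if good:
                blocks[-1].append(items[i + 1])
            else:
                blocks.append([items[i + 1]])
        if s.circular and len(blocks) > 1 and ok[-1]:
            blocks[0] = blocks.pop() + blocks[0]
        errors += sum(1 for good in ok if not good)
        if s.circular and len(blocks) == 1 and all(ok):
            pass  # perfectly circular: the wrap is not an error
        weights = [sum(lengths[c] for c, _ in blk) for blk in blocks]
        blocks_all.extend(weights)
        falsely += sum(weights) - max(weights)
    return falsely, errors, blocks_all


def _n50(weights: Sequence[int]) -> int:
    total = sum(weights)
    acc = 0
    for w in sorted(weights, reverse=True):
        acc += w
        if acc * 2 >= total:
            return w
    return 0


def evaluate_against_truth(
    scaffolds: Sequence[OutputScaffold], truth: TruthSet
) -> EvalMetrics:
    """Score output scaffolds against the simulated truth.

    recovered %: summed length of output contigs over the target length.
    falsely located %: length of contigs outside each scaffold's largest
    truth-consistent block, over the target length.
    errors: junctions whose signed order contradicts the truth.
    The whole output is also scored reverse-complemented and the better
    global orientation wins, since output strand is arbitrary.
    """
    lengths = {cid: ln for cid, _, ln, _ in truth.contig_placements}
    unknown = {c for s in scaffolds for c, _ in s.contigs} - set(lengths)
    if unknown:
        raise ValueError(f"output names unknown contigs: {sorted(unknown)[:5]}")
    order = _truth_order(truth)
    succ = _successor_map(order)
    present = {c for s in scaffolds for c, _ in s.contigs}
    placed_len = sum(lengths[c] for s in scaffolds for c, _ in s.contigs)

    candidates = []
    for flipped in (False, True):
        scafs = [(_flip_scaffold(s) if flipped else s) for s in scaffolds]
        candidates.append(_score(scafs, succ, lengths, present))
    falsely, errors, blocks = min(candidates, key=lambda t: (t[0], t[1]))

    L = truth.length
    return EvalMetrics(
        recovered_pct=100.0 * placed_len / L,
        falsely_located_pct=100.0 * falsely / L,
        errors=errors,
        corrected_n50=_n50(blocks),
        n_scaffolds=len(scaffolds),
    )
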