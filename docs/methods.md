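# Methods

## Model and assumptions

The scaffolder assumes the target genome is a single circular chromosome of a
species whose single-copy core genes keep a stable order inside large
syntenic segments, while the segments themselves rearrange between strains.
Input contigs are taken as correct (no splitting or sequence editing); the
pipeline only orders, orients and joins them. Plasmids and other replicons
are not assembled into the pseudo-genome — contigs that cannot be anchored
end up in a leftovers file, never silently dropped.

## cGOF segments

"Conserved consecutive order" is operationalized as conservation of every
internal signed adjacency: (a, b) holds in a genome iff that genome carries
`…, a, b, …` or `…, −b, −a, …` consecutively, circularly within one replicon.
Because core genes are single-copy, a run whose internal adjacencies all hold
is itself consecutive (forward or fully reversed) in every genome, so the
segment set equals the set of maximal conserved runs — the test suite checks
this equivalence against exhaustive enumeration on a thousand random
instances. Design choices, made where several definitions were defensible:

- **Circularity.** Replicons are circular; adjacencies wrap the origin.
  Multi-replicon genomes contribute no adjacency across replicons.
- **Canonical orientation / numbering.** A segment is reported in the
  orientation it has in the lexicographically first genome and numbered by
  first occurrence along that genome's order, making output independent of
  input row order.
- **Minimum segment length** is 2 genes: a single gene carries no order
  information. Lowering the cutoff can only add segments (tested property).

## Indexing and strings

Gene hits need ≥ 0.90 identity and ≥ 0.80 query coverage — conventional
intra-species thresholds, config-exposed. "Uniquely mapped" is enforced at
two levels: a gene whose top two hits tie within 1% is discarded, and a
contig whose intervals contradict each other (mixed orientations, overlapping
sub-ranges, out-of-order sub-ranges) is set aside as ambiguous. A contig may
legitimately carry one segment's tail at its start and the same segment's
head at its end — that is what a contig spanning the circular origin looks
like — so interval layouts are validated circularly (at most one wrap).

Gaps between chained contigs are estimated from reference coordinates: the
median (across references) circular distance between the two anchor genes,
minus the contig overhangs beyond them, clamped at ≥ 0. Replicon length is
approximated by the last gene's end coordinate, so wrap-around distances are
underestimated by one terminal intergenic stretch; the clamp absorbs this.
Junctions supported only by read pairs get a flat 100 bp gap (no insert-based
re-estimation).

## Local scaffolding

The end window W (how close to a contig end a mate must sit) defaults to the
mean insert size estimated from same-contig inner-oriented pairs, falling
back to 500 bp. Links are kept when strictly more than `link_cutoff`
(default 5) pairs support them. The confidence combines the cGOF verdict and
the link count, `c = a·permutation + (1−a)·link`:

- consistent with a string adjacency (or a contig's own head–tail edge): 1;
- contradicting a string adjacency (any endpoint is an interior end of a
  string, or an ambiguous contig): 0;
- otherwise `permutation = 0` and `link = min(1, n/L_sat)` with `a = 0.5`,
  `L_sat = 10`. The saturating ramp keeps c in [0, 1] and makes the cutoff
  and the saturation independently tunable; the fixed 1/0 for
  consistent/conflicting edges takes precedence over the blended formula
  wherever the two disagree.

Resolution is a greedy maximum-confidence matching (ties: higher count, then
endpoint ids), attaching an edge only when both endpoints are free — a global
optimization could differ in principle, but greedy is deterministic and the
c = 1 adjacencies can never be displaced by weaker edges (tested). A contig
counts as a reusable repeat when its read depth is ≥ 1.5× the median contig
depth *and* it has ≥ 2 disjoint edges with c ≥ 0.5; it may then be cloned
into at most `round(depth/median)` (≤ 4) junctions. Cycles among chains are
opened at their lowest-confidence attached edge.

## Guide selection and the pseudo-genome

Reference permutations are canonicalized over rotations and the
reflection-with-sign-flip (the deposited strand of a reference is arbitrary),
so equivalent arrangements pool their prevalence. A pattern is discarded iff
it lacks a signed segment adjacency the strings directly witness — junctions
are read off the final extended strings, which covers both overbridge contigs
and read-pair joins. Among compatible patterns the most prevalent wins; ties
go to the pattern whose supporting genome set contains the lexicographically
first genome id, so adding an unrelated reference cannot flip a tie between
equally supported patterns. An empty compatible set is reported as a novel
arrangement and no pseudo-genome is forced.

Strings are embedded on the guide via their segment gene-ranges (erroring on
overlap or ambiguity rather than guessing), inter-string gaps come from the
reference distance between the flanking anchor genes clamped to
[100 bp, 10 kb], and every inter-string junction — whose only evidence is the
guide — is listed as unverified. A single string spanning the whole guide is
circularized as-is (wrap gap clamped at ≥ 0), which makes re-scaffolding an
emitted pseudo-genome reproduce it byte-for-byte.

## Synthetic data

The generator emulates the study conditions the scaffolder targets: 10
references by default, a few hundred core genes (400–800 bp) in a handful of
segments with 50–150 bp intergenic spacers; per-reference segment
permutations drawn freely (signed shuffles) or symmetrically (in-place
inversions, the Ori–Ter-axis style); dispensable genes present in a random
half of the genomes at per-genome random positions — never in all references,
by definition; a 600 bp repeat element planted in four copies in the target;
uniform (or repeat-targeted) fragmentation with a 300 bp contig floor; and
uniformly drawn 2 × 100 bp pairs, insert 500 ± 50 bp, substitution errors at
2%, ≥ 100× coverage by default. A truth SAM places each read at its exact
contig of origin and substitutes for a production mapper in tests (a minimal
exact-seed mapper covers the FASTQ path); real runs supply aligner SAM.

What the simulation does *not* model — indel sequencing errors, chimeric
contigs/misassemblies, GC or coverage bias, gene gain/loss inside segments,
paralogy beyond the planted repeat, plasmids — bounds what passing tests
show: they validate the order/orientation logic and the permutation voting
under the stated noise model, not robustness to assembler artifacts.

In the novel-arrangement mode the reference patterns are additionally
resampled until they share no segment adjacency, which pins the identified
segments to the planted ones and guarantees the target arrangement is
genuinely out-of-reference.

## Evaluation

Because output coordinates contain estimated gaps, scoring is order-based:
output scaffolds are split into maximal blocks whose signed contig order is
consistent with the truth circle (contigs missing from the output may be
skipped — an omission costs coverage, not an error). Recovered % is placed
contig length over the true genome length; falsely located % sums, per
scaffold, everything outside the largest consistent block; each inconsistent
junction is one error; corrected N50 is the N50 of the blocks. The whole
output is also scored reverse-complemented and the better global orientation
is used. Truth scored against itself gives 100 / 0 / 0 by construction.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the end-to-end experiments at
200 core genes (~130 kb genomes), 30–60 contigs and 50× coverage — small
enough to iterate quickly, large enough that every junction is covered by
tens of read pairs, so conclusions about the logic transfer. The scaffolder
itself is deterministic; all simulation randomness flows from one seed, and
runs log their parameters.
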