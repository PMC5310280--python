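"""Extract cGOF segments from a toy set of three rearranged references.

Three strains share six single-copy core genes; strain B has inverted the
g4-g5 block and strain C has translocated it.  The conserved runs (the cGOF
segments) and each strain's signed segment permutation are printed.
"""

import pandas as pd

from gaap import ClusterTable, identify

order = {
    "strainA": ["+g1", "+g2", "+g3", "+g4", "+g5", "+g6"],
    "strainB": ["+g1", "+g2", "+g3", "-g5", "-g4", "+g6"],
    "strainC": ["+g4", "+g5", "+g1", "+g2", "+g3", "+g6"],
}

rows = []
for genome, genes in order.items():
    pos = 0
    for token in genes:
        rows.append((token[1:], genome, "chr", pos, pos + 900, token[0]))
        pos += 1000
table = ClusterTable(
    pd.DataFrame(rows, columns=["cluster_id", "genome_id", "replicon_id", "start", "end", "strand"])
)

result = identify(table, circular=False)

print("cGOF segments (conserved core-gene runs):")
for seg in result.segments:
    genes = ",".join(("+" if s > 0 else "-") + g for g, s in seg.genes)
    print(f"  {seg.segment_id}: {genes}")
print("\nsigned segment permutation per reference:")
for perm in result.permutations:
    pattern = ",".join(("+" if s > 0 else "-") + sid for sid, s in perm.segments)
    print(f"  {perm.genome_id}: {pattern}")
print(
    "\nGene g6 borders a rearrangement on both sides in some strain, so it"
    "\nforms no run of >= 2 conserved genes and belongs to no segment."
)
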