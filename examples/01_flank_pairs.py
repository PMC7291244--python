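"""From transcript models to flank pairs.

A gene's transcripts are flattened into disjoint exonic counting bins, the
gaps between bins become introns, and every methylation probe inside an
intron is paired with the exon bin on each side.  These intron-exon and
exon-intron pairs are the observation unit of the flank regression.
"""

import pandas as pd

from methsplice import (
    GeneModel,
    build_flank_pairs,
    derive_introns,
    flatten_gene_models,
    median_pair_distance,
)

# A two-transcript gene: the short isoform skips the middle exon, and its
# start at 150 introduces an extra boundary inside the first exon.
gene = GeneModel(
    gene_id="DEMO",
    chrom="chr2",
    strand="+",
    transcripts=[
        ("long", [(100, 200), (400, 520), (800, 900)]),
        ("short", [(150, 200), (800, 900)]),
    ],
)

bins = flatten_gene_models([gene])
print("Exonic bins (split at every transcript boundary):")
print(bins.to_string(index=False), "\n")

introns = derive_introns(bins)
print("Introns (gaps between consecutive bins):")
print(introns.to_string(index=False), "\n")

# Three CpG probes: one in each intron, one exonic (yields no pair).
probes = pd.DataFrame({
    "probe_id": ["cg000001", "cg000002", "cg000003"],
    "chrom": ["chr2", "chr2", "chr2"],
    "pos": [250, 600, 850],
})

pairs = build_flank_pairs(probes, introns, bins)
print("Flank pairs (probe vs adjacent bin, with genomic distance):")
print(pairs.to_string(index=False), "\n")
print(f"Median pair distance: {median_pair_distance(pairs):.0f} bp")
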