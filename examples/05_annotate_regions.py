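"""Gene annotation of candidate regions.

Cores are extended by 100 kb on both sides before intersecting with gene
intervals, so regulatory neighborhoods and haplotype edges clipped by the
fixed window grid are not missed; a gene counts if it overlaps the extended
span by at least one base.
"""
from poolscan import (
    GeneInterval,
    GenomeLayout,
    ScrRegion,
    extend_scr,
    genes_in_scr,
    summarize_scr_table,
)

layout = GenomeLayout(["22"], {"22": 51_000_000})
core = ScrRegion("22", 22_050_000, 22_250_000, group="A")
genes = [
    GeneInterval("22", 21_980_000, 22_010_000, "upstreamGene"),
    GeneInterval("22", 22_100_000, 22_140_000, "coreGene"),
    GeneInterval("22", 22_300_000, 22_340_000, "downstreamGene"),
    GeneInterval("22", 23_000_000, 23_050_000, "farGene"),
]

(with_flank,) = genes_in_scr(extend_scr([core], layout, flank=100_000), genes)
(no_flank,) = genes_in_scr(extend_scr([core], layout, flank=0), genes)
print("genes with 100 kb flanks:", ", ".join(with_flank.gene_ids))
print("genes without flanks    :", ", ".join(no_flank.gene_ids))

table, summary = summarize_scr_table([with_flank])
print("\nregion report:")
print(table.to_string(index=False))
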