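"""The SCR gap-collapse rule on the published chromosome-6 worked example.

Three continuous stretches of significant 200 kb / 50 kb windows at
36.45-37.0, 37.05-38.1 and 38.2-38.4 Mb are separated by one and two window
steps; the merge rule collapses them into a single 1.95 Mb candidate sweep
region, the longest in the published sheep table.
"""
from poolscan import GenomeLayout, build_scr, make_windows
from poolscan.datasets import OAR6_MERGE_PARTS

layout = GenomeLayout(["6"], {"6": 120_000_000})
windows = make_windows(layout, size=200_000, step=50_000)
mask = [
    any(w.chrom == c and w.start >= s and w.end <= e for c, s, e in OAR6_MERGE_PARTS)
    for w in windows
]
print("input stretches:")
for c, s, e in OAR6_MERGE_PARTS:
    print(f"  chr{c}:{s:,}-{e:,} ({(e - s) // 1000} kb)")

(region,) = build_scr(windows, mask, max_gap_windows=2)
print(
    f"\nmerged region: chr{region.chrom}:{region.core_start:,}-{region.core_end:,}"
    f"  span {region.core_length / 1e6:.2f} Mb from {len(region.member_indices)}"
    " significant windows"
)
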