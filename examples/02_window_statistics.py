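"""The three window statistics on tiny hand-built windows.

Hp is the pooled heterozygosity of a window's summed major/minor read
counts (0.5 = maximally balanced, ~0 = swept). Tajima's D contrasts pairwise
diversity with the segregating-site count (negative = excess rare variants,
as after a sweep). F_st measures how much of the total expected
heterozygosity lies between two pools.
"""
from poolscan import SnpRecord, pooled_heterozygosity, window_fst, window_tajima_d


def snp(pos, n_maj, n_min):
    return SnpRecord("1", pos, "A", "A", "C", n_maj, n_min, n_maj + n_min)


balanced = [snp(100 + i, 8, 8) for i in range(12)]
swept = [snp(100 + i, 15, 1) for i in range(3)] + [snp(200 + i, 16, 0) for i in range(9)]

print(f"Hp balanced window : {pooled_heterozygosity(balanced):.3f}  (maximum 0.5)")
print(f"Hp swept window    : {pooled_heterozygosity(swept):.3f}  (diversity lost)")

tpi, tw, d = window_tajima_d(balanced, pool_haploid_size=50)
print(f"\nbalanced: theta_pi={tpi:.2f} theta_w={tw:.2f} D={d:+.2f} (positive)")
tpi, tw, d = window_tajima_d([snp(100 + i, 15, 1) for i in range(12)], 50)
print(f"rare-excess: theta_pi={tpi:.2f} theta_w={tw:.2f} D={d:+.2f} (negative)")

pool_a = [snp(100, 8, 2)]   # major-allele frequency 0.8
pool_b = [snp(100, 4, 6)]   # major-allele frequency 0.4
print(f"\nF_st for p1=0.8 vs p2=0.4: {window_fst(pool_a, pool_b):.4f} (= 1/6)")
print(f"F_st for identical pools : {window_fst(pool_a, pool_a):.4f}")
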