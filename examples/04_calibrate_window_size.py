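"""Window-size calibration on simulated data.

Windows with fewer than 10 SNPs bias the window statistics and are excluded
from the scan, so the window size should be chosen to keep their fraction
near zero. The table below shows that fraction for candidate sizes on a
simulated pool: it shrinks as windows grow, and the scan's 200 kb default
leaves (essentially) no sparse windows at this SNP density.
"""
from poolscan import SimConfig, calibrate_window_size, call_snps_pool, simulate

# a sparse experiment (10x fewer SNPs than the package default) where the
# choice of window size genuinely matters
cfg = SimConfig(seed=5, snp_density=0.0004)
sites, _ = simulate(cfg)
snps = call_snps_pool(sites, pool_index=0)
print(f"{len(snps)} SNPs called in pool 0")

table = calibrate_window_size(
    snps, cfg.layout(), candidate_sizes=[25_000, 50_000, 100_000, 200_000],
    step=25_000, min_snps=10,
)
print(table.to_string(index=False))
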