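"""Synthetic pooled sequencing data with known truth.

The generator emulates the study design the scan is built for: 2-3 pools of
25 diploid individuals each, sequenced at ~16x mean depth, with an ancestral
neutral-like allele-frequency spectrum (density proportional to 1/x on
[1/(2N), 0.5]), per-pool frequencies drawn from a Balding-Nichols
distribution around the ancestral frequency (one-parameter control of the
expected F_st), and phenomenological selective sweeps: inside a sweep the
target pool's allele frequencies are pushed toward fixation with a linearly
decaying intensity from the sweep center. Read counts arise from two-stage
binomial sampling (pool of 2N chromosomes, then reads at truncated-Poisson
depth), which is the statistical core of Pool-Seq.

What this deliberately does not model: linkage and haplotype structure,
recombination, sequencing error beyond binomial sampling, and read-level
artifacts. The scan consumes per-site frequency summaries only, so planted
sweeps still produce the three signatures it detects (depressed Hp, skewed
frequency spectrum, elevated between-pool F_st).

The default scale — one 10 Mb chromosome at 0.004 sites/bp, ~40 k sites —
keeps a full simulate-and-scan cycle in the low seconds on one CPU. The
default sweep half-width of 200 kb was fixed by a design power analysis: on
a ~200-window grid the attainable |Z| is bounded by roughly sqrt(#windows),
so a detectable sweep must concentrate its signal in a few windows while
each individual scan carries only one sweep; 200 kb is the smallest
half-width whose planted signals clear the 6-SD cut-off with a comfortable
margin in every scan that should see them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ALLELES, GenomeLayout, SiteCounts, write_bed
from .snp_calling import SnpRecord
from .window_engine import make_windows

__all__ = [
    "Sweep",
    "SimConfig",
    "SimFrequencies",
    "TruthSet",
    "default_scenario",
    "simulate_frequencies",
    "plant_sweep",
    "simulate_reads",
    "simulate",
    "calibrate_window_size",
]


@dataclass(frozen=True)
class Sweep:
    """A planted sweep: pools' frequencies inside [center-half_width,
    center+half_width] are moved toward fixation, fully at the center, not at
    all at the edge. ``pools`` is a pool index, a tuple of indices, or
    "shared" (every pool)."""

    pools: int | tuple[int, ...] | str
    chrom: str = "1"
    center: int = 2_500_000
    half_width: int = 200_000
    intensity: float = 1.0

    def targets(self, n_pops: int) -> tuple[int, ...]:
        if self.pools == "shared":
            return tuple(range(n_pops))
        if isinstance(self.pools, int):
            return (self.pools,)
        return tuple(self.pools)

    def interval(self) -> tuple[int, int]:
        return self.center - self.half_width, self.center + self.half_width


@dataclass
class SimConfig:
    seed: int = 0
    n_pops: int = 3
    pool_diploids: int = 25
    mean_depth: float = 16.0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 10_000_000})
    snp_density: float = 0.004
    divergence: float = 0.05
    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self):
        if self.n_pops < 2:
            raise ConfigError("need at least 2 pools")
        if not (0.0 <= self.divergence < 1.0):
            raise ConfigError("divergence must be in [0, 1)")
        if self.snp_density < 0 or self.mean_depth <= 0 or self.pool_diploids < 1:
            raise ConfigError("rates and sizes must be positive")
        for s in self.sweeps:
            if not (0.0 <= s.intensity <= 1.0):
                raise ConfigError("sweep intensity must be in [0, 1]")
            L = self.chrom_lengths.get(s.chrom)
            if L is None:
                raise ConfigError(f"sweep on unknown chromosome {s.chrom!r}")
            lo, hi = s.interval()
            if lo < 0 or hi > L:
                raise ConfigError("sweep exceeds chromosome bounds")
            if max(s.targets(self.n_pops)) >= self.n_pops:
                raise ConfigError("sweep pool index out of range")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(list(self.chrom_lengths), dict(self.chrom_lengths))


@dataclass
class SimFrequencies:
    """True allele frequencies per chromosome: 1-based positions, ancestral
    alternate-allele frequency, and an (n_pops, n_sites) per-pool matrix."""

    pos: dict[str, np.ndarray]
    anc: dict[str, np.ndarray]
    freqs: dict[str, np.ndarray]

    def copy(self) -> "SimFrequencies":
        return SimFrequencies(
            {c: p.copy() for c, p in self.pos.items()},
            {c: a.copy() for c, a in self.anc.items()},
            {c: f.copy() for c, f in self.freqs.items()},
        )


@dataclass(frozen=True)
class TruthSet:
    """Planted-sweep intervals (0-based half-open) and the true frequencies."""

    sweeps: tuple[tuple[str, int, int, tuple[int, ...]], ...]
    frequencies: SimFrequencies


def default_scenario(seed: int = 0) -> SimConfig:
    """The canonical three-pool test scenario.

    Pool 0 plays the focal (naturally selected) population and carries a
    private sweep at 2.5 Mb — the group-A analog. Pool 1 plays the
    intensively selected sister population and carries a private sweep at
    6.5 Mb, which only the pool1-vs-pool2 F_st scan should attribute — the
    group-C analog.
    """
    cfg = SimConfig(seed=seed)
    cfg.sweeps = [
        Sweep(pools=0, chrom="1", center=2_500_000),
        Sweep(pools=1, chrom="1", center=6_500_000),
    ]
    return cfg


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimFrequencies:
    """Draw site positions and neutral per-pool allele frequencies.

    Ancestral minor-allele frequencies follow a 1/x density on
    [1/(2N), 0.5]; per-pool frequencies are Balding-Nichols
    (Beta(a(1-F)/F, (1-a)(1-F)/F)) around the ancestral value. Sweeps are
    NOT applied here; see :func:`plant_sweep`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo = 1.0 / (2 * cfg.pool_diploids)
    pos_d, anc_d, freq_d = {}, {}, {}
    for chrom, length in cfg.chrom_lengths.items():
        n = rng.poisson(length * cfg.snp_density)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        a = lo * (0.5 / lo) ** rng.random(len(pos))
        if cfg.divergence == 0.0:
            f = np.tile(a, (cfg.n_pops, 1))
        else:
            alpha = a * (1 - cfg.divergence) / cfg.divergence
            beta = (1 - a) * (1 - cfg.divergence) / cfg.divergence
            f = rng.beta(alpha, beta, size=(cfg.n_pops, len(pos)))
        pos_d[chrom], anc_d[chrom], freq_d[chrom] = pos, a, f
    return SimFrequencies(pos_d, anc_d, freq_d)


def plant_sweep(frequencies: SimFrequencies, sweep: Sweep, n_pops: int | None = None) -> SimFrequencies:
    """Return a copy with the sweep applied: f' = f + I*w(d)*(round(f) - f)
    with w decaying linearly from 1 at the center to 0 at the half-width."""
    out = frequencies.copy()
    pos = out.pos[sweep.chrom]
    w = np.clip(1.0 - np.abs(pos - sweep.center) / sweep.half_width, 0.0, 1.0)
    if n_pops is None:
        n_pops = out.freqs[sweep.chrom].shape[0]
    for k in sweep.targets(n_pops):
        f = out.freqs[sweep.chrom][k]
        out.freqs[sweep.chrom][k] = f + sweep.intensity * w * (np.round(f) - f)
    return out


def _truncated_poisson(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    d = rng.poisson(mean, n)
    while (d == 0).any():
        zero = d == 0
        d[zero] = rng.poisson(mean, int(zero.sum()))
    return d


def simulate_reads(
    frequencies: SimFrequencies,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SiteCounts]:
    """Sample pooled read counts from true frequencies.

    Per site and pool: the pool's realized frequency is a Binomial(2N, f)/2N
    draw (the finite pool of chromosomes), depth is Poisson(mean_depth)
    truncated at >= 1, and alternate reads are Binomial(depth, realized).
    The reference base is the ancestral major allele; reference and alternate
    bases are drawn at random per site.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    two_n = 2 * cfg.pool_diploids
    sites: list[SiteCounts] = []
    for chrom in frequencies.pos:
        pos = frequencies.pos[chrom]
        freqs = frequencies.freqs[chrom]
        n = len(pos)
        ref_idx = rng.integers(0, 4, n)
        alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
        alt_reads = np.empty((cfg.n_pops, n), dtype=np.int64)
        depth = np.empty((cfg.n_pops, n), dtype=np.int64)
        for k in range(cfg.n_pops):
            realized = rng.binomial(two_n, freqs[k]) / two_n
            depth[k] = _truncated_poisson(rng, cfg.mean_depth, n)
            alt_reads[k] = rng.binomial(depth[k], realized)
        for j in range(n):
            pools = []
            for k in range(cfg.n_pops):
                c = [0, 0, 0, 0]
                c[alt_idx[j]] = int(alt_reads[k, j])
                c[ref_idx[j]] = int(depth[k, j] - alt_reads[k, j])
                pools.append(tuple(c))
            sites.append(SiteCounts(chrom, int(pos[j]), ALLELES[ref_idx[j]], tuple(pools)))
    return sites


def simulate(cfg: SimConfig) -> tuple[list[SiteCounts], TruthSet]:
    """Full generation: frequencies, sweeps, reads. One rng stream per seed."""
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    for sweep in cfg.sweeps:
        freqs = plant_sweep(freqs, sweep, cfg.n_pops)
    sites = simulate_reads(freqs, cfg, rng)
    truth = TruthSet(
        tuple(
            (s.chrom, max(0, s.center - s.half_width), s.center + s.half_width,
             s.targets(cfg.n_pops))
            for s in cfg.sweeps
        ),
        freqs,
    )
    return sites, truth


def write_truth(truth: TruthSet, prefix: str) -> None:
    """Write the sweep intervals as BED and the true frequencies as TSV."""
    write_bed(
        [(c, s, e, "pop" + "+".join(map(str, pops))) for c, s, e, pops in truth.sweeps],
        f"{prefix}.truth.bed",
    )
    frames = []
    fr = truth.frequencies
    for chrom in fr.pos:
        df = pd.DataFrame({"chrom": chrom, "pos": fr.pos[chrom], "anc": fr.anc[chrom]})
        for k in range(fr.freqs[chrom].shape[0]):
            df[f"freq_pool{k}"] = fr.freqs[chrom][k]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        f"{prefix}.truth_freqs.tsv", sep="\t", index=False, float_format="%.6g"
    )


def calibrate_window_size(
    snps: Sequence[SnpRecord],
    layout: GenomeLayout,
    candidate_sizes: Sequence[int],
    step: int = 50_000,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Window-size calibration: for each candidate size, the fraction of
    windows holding fewer than ``min_snps`` SNPs. Larger windows on the same
    data can only lower the fraction of sparse windows; the table supports
    choosing the smallest size that keeps that fraction acceptably low."""
    if not list(candidate_sizes):
        raise ConfigError("candidate_sizes must not be empty")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in snps:
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos - 1)
    pos_by_chrom = {c: np.sort(np.asarray(p)) for c, p in pos_by_chrom.items()}
    rows = []
    for size in candidate_sizes:
        windows = make_windows(layout, size=size, step=min(step, size))
        below = total = 0
        for w in windows:
            p = pos_by_chrom.get(w.chrom)
            count = 0
            if p is not None:
                count = int(np.searchsorted(p, w.end) - np.searchsorted(p, w.start))
            below += count < min_snps
            total += 1
        rows.append(
            {"size": size, "n_windows": total, "n_below": below,
             "fraction_below": below / total if total else float("nan")}
        )
    return pd.DataFrame(rows)
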