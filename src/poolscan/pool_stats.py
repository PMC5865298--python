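"""Window statistics for pooled sequencing data.

Three statistics per sliding window:

* pooled heterozygosity  Hp = 2 (Σ n_maj)(Σ n_min) / (Σ n_maj + Σ n_min)^2,
  sums over the window's SNPs — depressed inside selective sweeps;
* pooled Tajima's D — the normalized difference between the window's summed
  per-site pairwise diversity (θπ) and the Watterson estimator (θW), negative
  when rare variants are in excess;
* pairwise pooled F_st from read allele frequencies, elevated where pools
  diverged.

Because SNPs are ascertained by a minimum non-reference read count, the
low-frequency allele classes are truncated, which deflates the segregating
site count relative to π and biases classical Tajima's D upward. The default
``bias="min_count"`` mode corrects both estimators by dropping the truncated
classes from their neutral expectations: with min count b and effective
sample size n,

    θW = S / (a1 - Σ_{i<b} 1/i),
    θπ = Σ π_i / (1 - Σ_{i<b} 2(n-i)/(n(n-1))).

With b = 1 this reduces to the classical estimators, which remain available
via ``bias="none"``. The variance normalization of D keeps Tajima's classical
constants; downstream analysis consumes Z-transformed values, which are
insensitive to residual monotone miscalibration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .snp_calling import SnpRecord

__all__ = [
    "TajimaConstants",
    "tajima_constants",
    "pooled_heterozygosity",
    "window_tajima_d",
    "window_fst",
]


@dataclass(frozen=True)
class TajimaConstants:
    """Tajima's normalization constants for an effective sample size n_eff."""

    n_eff: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n_eff: int) -> TajimaConstants:
    if n_eff < 2:
        raise ConfigError(f"n_eff must be >= 2, got {n_eff}")
    i = np.arange(1, n_eff)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n_eff + 1) / (3.0 * (n_eff - 1))
    b2 = 2.0 * (n_eff**2 + n_eff + 3) / (9.0 * n_eff * (n_eff - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_eff + 2) / (a1 * n_eff) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n_eff, a1, a2, b1, b2, c1, c2, e1, e2)


def pooled_heterozygosity(window_snps: Sequence[SnpRecord]) -> float:
    """Hp over a window's SNPs; NaN when the window has no SNPs."""
    if not window_snps:
        return math.nan
    s_maj = sum(s.n_maj for s in window_snps)
    s_min = sum(s.n_min for s in window_snps)
    total = s_maj + s_min
    if total == 0:
        return math.nan
    return 2.0 * s_maj * s_min / total**2


def _ascertainment_factors(n_eff: int, min_count: int) -> tuple[float, float]:
    """(harmonic mass removed from θW, π fraction removed) for allele-count
    classes below ``min_count`` in a sample of ``n_eff``."""
    excl_w = sum(1.0 / i for i in range(1, min_count))
    excl_pi = sum(2.0 * (n_eff - i) / (n_eff * (n_eff - 1)) for i in range(1, min_count))
    return excl_w, excl_pi


def window_tajima_d(
    window_snps: Sequence[SnpRecord],
    pool_haploid_size: int,
    neff_mode: str = "pool_capped",
    bias: str = "min_count",
    min_count: int = 2,
) -> tuple[float, float, float]:
    """(theta_pi, theta_w, tajima_d) for one window in one pool.

    Per-site diversity is π_i = 2 n_maj n_min / (c (c-1)) with
    c = n_maj + n_min. The effective sample size is the floored window median
    of c (``neff_mode="read_depth"``), by default capped at the haploid pool
    size (``"pool_capped"``): read depth above 2N cannot sample more than 2N
    distinct chromosomes. Returns NaNs when the window has no SNPs or the
    variance term degenerates.
    """
    if neff_mode not in ("read_depth", "pool_capped"):
        raise ConfigError(f"unknown neff_mode {neff_mode!r}")
    if bias not in ("min_count", "none"):
        raise ConfigError(f"unknown bias mode {bias!r}")
    if pool_haploid_size < 2:
        raise ConfigError("pool_haploid_size must be >= 2")
    if not window_snps:
        return math.nan, math.nan, math.nan
    c = np.array([s.n_maj + s.n_min for s in window_snps], dtype=float)
    if (c < 2).any():
        raise ConfigError("window_tajima_d requires every SNP to have depth >= 2")
    n_eff = int(np.floor(np.median(c)))
    if neff_mode == "pool_capped":
        n_eff = min(n_eff, pool_haploid_size)
    if n_eff < 2:
        return math.nan, math.nan, math.nan
    k = tajima_constants(n_eff)
    pi = np.array(
        [2.0 * s.n_maj * s.n_min / ((s.n_maj + s.n_min) * (s.n_maj + s.n_min - 1))
         for s in window_snps]
    )
    S = len(window_snps)
    if bias == "min_count" and min_count > 1:
        excl_w, excl_pi = _ascertainment_factors(n_eff, min_count)
        denom_w = k.a1 - excl_w
        if denom_w <= 0 or excl_pi >= 1:
            return math.nan, math.nan, math.nan
        theta_pi = float(np.sum(pi)) / (1.0 - excl_pi)
        theta_w = S / denom_w
    else:
        theta_pi = float(np.sum(pi))
        theta_w = S / k.a1
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        # degenerate variance term; D is 0 when the numerator also vanishes
        d = 0.0 if theta_pi == theta_w else math.nan
        return theta_pi, theta_w, d
    d = (theta_pi - theta_w) / math.sqrt(var)
    return theta_pi, theta_w, d


def window_fst(
    snps_a: Sequence[SnpRecord],
    snps_b: Sequence[SnpRecord],
    scheme: str = "ratio_of_sums",
) -> float:
    """Pairwise window F_st from read frequencies of the shared major allele.

    Inputs are aligned per-pool records of the same common-SNP sites under a
    shared allele labeling. Per SNP, with p_k the major-allele read frequency
    in pool k: H_S = mean of within-pool expected heterozygosities and
    H_T = 2 p̄ (1 - p̄). ``ratio_of_sums`` (default) is Σ(H_T - H_S)/Σ H_T over
    the window; ``mean_of_ratios`` averages per-SNP ratios over SNPs with
    H_T > 0. Negative results are clamped to 0; NaN when Σ H_T = 0 or the
    window is empty.
    """
    if scheme not in ("ratio_of_sums", "mean_of_ratios"):
        raise ConfigError(f"unknown F_st scheme {scheme!r}")
    if len(snps_a) != len(snps_b):
        raise ConfigError("window_fst needs aligned SNP lists of equal length")
    if not snps_a:
        return math.nan
    p1 = np.array([s.n_maj / (s.n_maj + s.n_min) for s in snps_a])
    p2 = np.array([s.n_maj / (s.n_maj + s.n_min) for s in snps_b])
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    if scheme == "ratio_of_sums":
        denom = float(np.sum(ht))
        if denom == 0.0:
            return math.nan
        fst = float(np.sum(ht - hs)) / denom
    else:
        keep = ht > 0
        if not keep.any():
            return math.nan
        fst = float(np.mean((ht[keep] - hs[keep]) / ht[keep]))
    return max(fst, 0.0)
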