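"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths and numpy vectorization:
plain-Python term-by-term evaluation of the window statistics, and direct
enumeration for window grids. They define the expected values the fast
implementations must match.
"""
from __future__ import annotations

import math
from fractions import Fraction


def hp_bruteforce(pairs):
    """Pooled heterozygosity from (n_maj, n_min) pairs via exact rationals."""
    smaj = sum(Fraction(a) for a, _ in pairs)
    smin = sum(Fraction(b) for _, b in pairs)
    return float(2 * smaj * smin / (smaj + smin) ** 2)


def tajima_constants_bruteforce(n):
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {k: float(v) for k, v in
            dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2).items()}


def tajima_d_bruteforce(pairs, pool_haploid_size, neff_mode="pool_capped",
                        bias="min_count", min_count=2):
    """(theta_pi, theta_w, D) evaluated termwise from (n_maj, n_min) pairs."""
    depths = sorted(a + b for a, b in pairs)
    m = len(depths)
    median = (
        depths[m // 2] if m % 2 == 1 else (depths[m // 2 - 1] + depths[m // 2]) / 2
    )
    n_eff = int(math.floor(median))
    if neff_mode == "pool_capped":
        n_eff = min(n_eff, pool_haploid_size)
    k = tajima_constants_bruteforce(n_eff)
    theta_pi = 0.0
    for a, b in pairs:
        c = a + b
        theta_pi += 2.0 * a * b / (c * (c - 1))
    S = len(pairs)
    if bias == "min_count" and min_count > 1:
        excl_w = sum(1.0 / i for i in range(1, min_count))
        excl_pi = sum(
            2.0 * (n_eff - i) / (n_eff * (n_eff - 1)) for i in range(1, min_count)
        )
        if k["a1"] - excl_w <= 0 or excl_pi >= 1:
            return math.nan, math.nan, math.nan
        theta_pi = theta_pi / (1.0 - excl_pi)
        theta_w = S / (k["a1"] - excl_w)
    else:
        theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var > 0:
        d = (theta_pi - theta_w) / math.sqrt(var)
    else:
        d = 0.0 if theta_pi == theta_w else math.nan
    return theta_pi, theta_w, d


def fst_bruteforce(pairs_a, pairs_b, scheme="ratio_of_sums"):
    """Pairwise window F_st evaluated per SNP from (n_maj, n_min) pairs."""
    num = den = 0.0
    ratios = []
    for (a1, b1), (a2, b2) in zip(pairs_a, pairs_b, strict=True):
        p1 = a1 / (a1 + b1)
        p2 = a2 / (a2 + b2)
        hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        num += ht - hs
        den += ht
        if ht > 0:
            ratios.append((ht - hs) / ht)
    if scheme == "ratio_of_sums":
        if den == 0:
            return math.nan
        return max(num / den, 0.0)
    if not ratios:
        return math.nan
    return max(sum(ratios) / len(ratios), 0.0)


def windows_bruteforce(length, size, step):
    """Enumerate (start, end) windows: every multiple of step below length."""
    out = []
    start = 0
    while start < length:
        out.append((start, min(start + size, length)))
        start += step
    return out


def call_site_bruteforce(counts, ref, min_nonref=2):
    """SNP rule on one 4-vector (A,C,G,T order), biallelic drop policy.

    Returns (major, minor, n_maj, n_min) or None.
    """
    alleles = "ACGT"
    ref_i = alleles.index(ref)
    nonref = [(c, i) for i, c in enumerate(counts) if i != ref_i]
    over = [t for t in nonref if t[0] >= min_nonref]
    if not over:
        return None
    if len(over) > 1:
        return None
    top_count, top_i = over[0]
    if counts[ref_i] >= top_count:
        return alleles[ref_i], alleles[top_i], counts[ref_i], top_count
    return alleles[top_i], alleles[ref_i], top_count, counts[ref_i]
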