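"""SNP calling from pooled read counts.

A site is called a SNP in a pool when the highest-count non-reference allele
reaches a minimum read count (default 2). Within-population statistics use
each pool's own SNP set; the between-population F_st uses the intersection of
the per-pool sets ("common SNPs") with one allele labeling shared across
pools, chosen from the summed counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigError, DataError
from .io_formats import ALLELES, SiteCounts

_IDX = {a: i for i, a in enumerate(ALLELES)}


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP in one pool.

    ``n_maj``/``n_min`` are the read counts of the major/minor allele; reads
    of any third allele are excluded from the pair but still count in
    ``depth``. The major allele is the higher-count allele of the pair, ties
    broken toward the reference.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    major_allele: str
    minor_allele: str
    n_maj: int
    n_min: int
    depth: int


@dataclass(frozen=True)
class CommonSnp:
    """A SNP called in every pool, with a single shared major/minor labeling."""

    chrom: str
    pos: int
    ref_allele: str
    major_allele: str
    minor_allele: str
    n_maj: tuple[int, ...]  # per pool
    n_min: tuple[int, ...]
    depth: tuple[int, ...]


def _call_site(
    counts: Sequence[int],
    ref: str,
    min_nonref_reads: int,
    multiallelic_policy: str,
) -> tuple[str, str, int, int] | None:
    """Apply the read-count rule to one pool's 4-vector; return
    (major, minor, n_maj, n_min) or None if the site is not a SNP here."""
    ref_i = _IDX[ref]
    nonref = [(counts[i], i) for i in range(4) if i != ref_i]
    # highest-count non-reference allele; ties broken by allele order (A<C<G<T)
    top_count, top_i = max(nonref, key=lambda t: (t[0], -t[1]))
    if top_count < min_nonref_reads:
        return None
    others_over = [c for c, i in nonref if i != top_i and c >= min_nonref_reads]
    if others_over:
        if multiallelic_policy == "drop":
            return None
        # top_two: keep the two highest-count alleles overall
        # (count ties broken toward the reference, then allele order)
        order = sorted(range(4), key=lambda i: (-counts[i], i != ref_i, i))
        maj_i, min_i = order[0], order[1]
        return ALLELES[maj_i], ALLELES[min_i], counts[maj_i], counts[min_i]
    # standard biallelic case: pair is (ref, top non-ref)
    if counts[ref_i] >= top_count:  # tie -> reference is major
        return ALLELES[ref_i], ALLELES[top_i], counts[ref_i], top_count
    return ALLELES[top_i], ALLELES[ref_i], top_count, counts[ref_i]


def call_snps_pool(
    sites: Iterable[SiteCounts],
    pool_index: int,
    min_nonref_reads: int = 2,
    multiallelic_policy: str = "drop",
) -> list[SnpRecord]:
    """Call SNPs in one pool from a stream of SiteCounts.

    Sites whose reference allele is N are skipped. With the default
    ``multiallelic_policy="drop"``, sites where a second non-reference allele
    also reaches the threshold are discarded (the downstream statistics are
    biallelic); ``"top_two"`` instead keeps the two highest-count alleles.
    """
    if min_nonref_reads < 1:
        raise ConfigError("min_nonref_reads must be >= 1")
    if multiallelic_policy not in ("drop", "top_two"):
        raise ConfigError(f"unknown multiallelic_policy {multiallelic_policy!r}")
    out: list[SnpRecord] = []
    for site in sites:
        if pool_index < 0 or pool_index >= site.n_pools:
            raise ConfigError(
                f"pool_index {pool_index} out of range for {site.n_pools} pools"
            )
        if site.ref_allele == "N":
            continue
        counts = site.counts_per_pool[pool_index]
        called = _call_site(counts, site.ref_allele, min_nonref_reads, multiallelic_policy)
        if called is None:
            continue
        maj, mnr, n_maj, n_min = called
        out.append(
            SnpRecord(
                site.chrom, site.pos, site.ref_allele, maj, mnr,
                n_maj, n_min, int(sum(counts)),
            )
        )
    return out


def common_snps(per_pool_snp_lists: Sequence[Sequence[SnpRecord]]) -> list[CommonSnp]:
    """Intersect per-pool SNP sets and relabel alleles consistently.

    A site survives when every pool called it, the reference alleles agree
    (otherwise the inputs are inconsistent and a DataError is raised) and all
    pools identified the same allele pair. The shared major allele is the one
    with the larger read count summed over pools, ties broken toward the
    reference; per-pool n_maj/n_min are re-extracted under that labeling.
    """
    if len(per_pool_snp_lists) < 2:
        raise ConfigError("common_snps needs at least 2 pools")
    maps = [{(s.chrom, s.pos): s for s in pool} for pool in per_pool_snp_lists]
    keys = set(maps[0])
    for m in maps[1:]:
        keys &= set(m)
    out: list[CommonSnp] = []
    for key in sorted(keys):
        recs = [m[key] for m in maps]
        refs = {r.ref_allele for r in recs}
        if len(refs) > 1:
            raise DataError(
                f"inconsistent reference alleles {sorted(refs)} at {key[0]}:{key[1]}"
            )
        pairs = {frozenset((r.major_allele, r.minor_allele)) for r in recs}
        if len(pairs) > 1:
            continue  # pools disagree on the segregating pair; not comparable
        a, b = sorted(pairs.pop())
        ref = recs[0].ref_allele
        count = {a: 0, b: 0}
        for r in recs:
            count[r.major_allele] += r.n_maj
            count[r.minor_allele] += r.n_min
        if count[a] > count[b]:
            maj, mnr = a, b
        elif count[b] > count[a]:
            maj, mnr = b, a
        else:  # summed tie -> reference major when it is in the pair
            maj = ref if ref in (a, b) else a
            mnr = b if maj == a else a
        n_maj, n_min, depth = [], [], []
        for r in recs:
            if r.major_allele == maj:
                n_maj.append(r.n_maj)
                n_min.append(r.n_min)
            else:
                n_maj.append(r.n_min)
                n_min.append(r.n_maj)
            depth.append(r.depth)
        out.append(
            CommonSnp(key[0], key[1], ref, maj, mnr,
                      tuple(n_maj), tuple(n_min), tuple(depth))
        )
    return out
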