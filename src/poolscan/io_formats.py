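"""Readers and writers for the file formats the scan touches.

Formats: PoPoolation "sync" allele-count files, two-column chromosome-length
tables, BED intervals, GFF3 gene annotation, and the tab-separated
window-statistic report.

Coordinate conventions: everything in memory is 0-based half-open. sync and
GFF3 are 1-based on disk and are converted at the parser/writer boundary;
BED passes through unchanged. `SiteCounts.pos` keeps the 1-based genomic
coordinate of the sync line, because that is how Pool-Seq sites are usually
referred to; window assignment converts with ``pos - 1``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigError, DataError, SyncParseError

#: internal allele order used everywhere
ALLELES = ("A", "C", "G", "T")
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}
#: sync column order is A:T:C:G:N:del; this maps internal A,C,G,T -> sync column
_SYNC_COL_FOR_INTERNAL = (0, 2, 3, 1)


@dataclass(frozen=True)
class SiteCounts:
    """Per-pool A,C,G,T read counts at one genomic site (the atomic scan input)."""

    chrom: str
    pos: int  # 1-based, as printed in sync
    ref_allele: str  # one of A,C,G,T,N
    counts_per_pool: tuple[tuple[int, int, int, int], ...]

    @property
    def n_pools(self) -> int:
        return len(self.counts_per_pool)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span, half-open 0-based. Strand is carried but never used for overlap."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths and an autosome flag.

    By default every chromosome counts as an autosome; callers exclude sex
    chromosomes/scaffolds by listing autosomes explicitly.
    """

    chroms: list[str]
    lengths: dict[str, int]
    autosomes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if len(set(self.chroms)) != len(self.chroms):
            raise DataError("duplicate chromosome names in layout")
        for c in self.chroms:
            if self.lengths.get(c, 0) <= 0:
                raise DataError(f"chromosome {c} has non-positive length")
        if not self.autosomes:
            self.autosomes = set(self.chroms)

    def autosome_list(self) -> list[str]:
        return [c for c in self.chroms if c in self.autosomes]


def read_sync(path: str | os.PathLike, n_pools: int) -> Iterator[SiteCounts]:
    """Stream SiteCounts from a sync file.

    Each line: chrom, pos, ref, then ``n_pools`` colon-separated count fields
    of six integers (A:T:C:G:N:del). N and deletion columns are parsed and
    discarded; counts are re-ordered to the internal A,C,G,T order.
    """
    if n_pools < 1:
        raise ConfigError("n_pools must be >= 1")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise DataError(
                    f"line {lineno}: expected {3 + n_pools} columns "
                    f"({n_pools} pools), found {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"non-integer position {pos_s!r}", lineno)
            if pos < 1:
                raise SyncParseError(f"position {pos} < 1", lineno)
            if ref not in ("A", "C", "G", "T", "N"):
                raise SyncParseError(f"bad reference allele {ref!r}", lineno)
            pools = []
            for f in fields[3:]:
                parts = f.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"count field {f!r} does not have 6 entries", lineno
                    )
                try:
                    sync_counts = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(f"non-integer count in {f!r}", lineno)
                if any(x < 0 for x in sync_counts):
                    raise SyncParseError(f"negative count in {f!r}", lineno)
                pools.append(tuple(sync_counts[c] for c in _SYNC_COL_FOR_INTERNAL))
            yield SiteCounts(chrom, pos, ref, tuple(pools))


def write_sync(sites: Iterable[SiteCounts], path: str | os.PathLike) -> None:
    """Write SiteCounts in sync format (inverse of :func:`read_sync`)."""
    with open(path, "w") as fh:
        for s in sites:
            cols = [s.chrom, str(s.pos), s.ref_allele]
            for pool in s.counts_per_pool:
                sync6 = [0] * 6
                for internal_i, sync_i in enumerate(_SYNC_COL_FOR_INTERNAL):
                    sync6[sync_i] = pool[internal_i]
                cols.append(":".join(str(x) for x in sync6))
            fh.write("\t".join(cols) + "\n")


def read_chrom_lengths(path: str | os.PathLike) -> GenomeLayout:
    """Read a two-column TSV of chromosome name and length in bp."""
    chroms, lengths = [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"line {lineno}: expected 'chrom<TAB>length'")
            try:
                length = int(parts[1])
            except ValueError:
                raise DataError(f"line {lineno}: non-integer length {parts[1]!r}")
            chroms.append(parts[0])
            lengths[parts[0]] = length
    return GenomeLayout(chroms, lengths)


def _bed_fields(region) -> tuple[str, int, int, str]:
    """Accept ScrRegion-like objects or (chrom, start, end[, name]) tuples."""
    if hasattr(region, "core_start"):
        name = getattr(region, "group", None) or ""
        return region.chrom, region.core_start, region.core_end, name
    chrom, start, end = region[0], region[1], region[2]
    name = region[3] if len(region) > 3 else ""
    return str(chrom), int(start), int(end), str(name)


def write_bed(regions: Iterable, path: str | os.PathLike) -> None:
    """Write half-open 0-based intervals as BED, sorted by (chrom, start)."""
    rows = [_bed_fields(r) for r in regions]
    for chrom, start, end, _ in rows:
        if start >= end:
            raise DataError(f"BED interval {chrom}:{start}-{end} has start >= end")
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            cols = [chrom, str(start), str(end)]
            if name:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for kv in attrs.strip().split(";"):
        kv = kv.strip()
        if kv.startswith(key + "="):
            return kv[len(key) + 1 :]
    return None


def read_genes(path: str | os.PathLike, format: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED or GFF3.

    GFF3: only ``gene``-type records are kept; 1-based inclusive coordinates
    are converted to half-open 0-based. The gene identifier is taken from the
    ID, gene_id, or Name attribute, in that order.
    """
    if format not in ("bed", "gff3"):
        raise ConfigError(f"unknown gene annotation format {format!r}")
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format == "bed":
                if len(f) < 3:
                    raise DataError(f"line {lineno}: BED needs >= 3 columns")
                gene_id = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "."
                genes.append(GeneInterval(f[0], int(f[1]), int(f[2]), gene_id, strand))
            else:
                if len(f) < 9:
                    raise DataError(f"line {lineno}: GFF3 needs 9 columns")
                if f[2] != "gene":
                    continue
                gene_id = (
                    _gff3_attr(f[8], "ID")
                    or _gff3_attr(f[8], "gene_id")
                    or _gff3_attr(f[8], "Name")
                    or f"{f[0]}:{f[3]}-{f[4]}"
                )
                genes.append(
                    GeneInterval(f[0], int(f[3]) - 1, int(f[4]), gene_id, f[6])
                )
    return genes


def write_window_table(df, path: str | os.PathLike) -> None:
    """Write the per-window statistic report as TSV with a fixed float format."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
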