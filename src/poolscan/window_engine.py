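"""Sliding-window grid construction and SNP-to-window assignment.

Windows start at every multiple of the step below the chromosome length and
are truncated at the chromosome end, so the tail of each chromosome is still
scanned (subject to the minimum-SNP filter). With the default 200 kb windows
sliding by 50 kb, each SNP falls into up to four windows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import GenomeLayout


@dataclass(frozen=True)
class Window:
    """Half-open 0-based window [start, end); ``index`` counts windows on its chromosome."""

    chrom: str
    start: int
    end: int
    index: int


def make_windows(
    layout: GenomeLayout,
    size: int = 200_000,
    step: int = 50_000,
    autosomes_only: bool = True,
) -> list[Window]:
    """Build the genome-wide window grid, ordered by (chromosome order, start)."""
    if step <= 0:
        raise ConfigError("window step must be > 0")
    if size < step:
        raise ConfigError(f"window size {size} < step {step}")
    chroms = layout.autosome_list() if autosomes_only else layout.chroms
    windows: list[Window] = []
    for chrom in chroms:
        length = layout.lengths[chrom]
        for i, start in enumerate(range(0, length, step)):
            windows.append(Window(chrom, start, min(start + size, length), i))
    return windows


def assign_snps(windows: Sequence[Window], snps: Sequence) -> list[np.ndarray]:
    """Index SNPs into windows.

    ``snps`` must be sorted by (chrom, pos); each element needs ``chrom`` and
    a 1-based ``pos``. A SNP at pos p belongs to window [s, e) iff
    s <= p - 1 < e. Returns, per window, the array of SNP indices.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    chrom_order: list[str] = []
    for i, s in enumerate(snps):
        if not chrom_order or chrom_order[-1] != s.chrom:
            chrom_order.append(s.chrom)
    start = 0
    all_chrom = [s.chrom for s in snps]
    all_pos0 = np.asarray([s.pos - 1 for s in snps], dtype=np.int64)
    for chrom in chrom_order:
        end = start
        while end < len(snps) and all_chrom[end] == chrom:
            end += 1
        pos_by_chrom[chrom] = all_pos0[start:end]
        idx_by_chrom[chrom] = np.arange(start, end)
        start = end
    out: list[np.ndarray] = []
    empty = np.empty(0, dtype=np.int64)
    for w in windows:
        pos0 = pos_by_chrom.get(w.chrom)
        if pos0 is None or len(pos0) == 0:
            out.append(empty)
            continue
        lo = int(np.searchsorted(pos0, w.start, side="left"))
        hi = int(np.searchsorted(pos0, w.end, side="left"))
        out.append(idx_by_chrom[w.chrom][lo:hi])
    return out


def filter_windows(
    windows: Sequence[Window],
    n_snps: Sequence[int],
    min_snps: int = 10,
) -> np.ndarray:
    """Boolean eligibility mask: windows with fewer than ``min_snps`` SNPs are
    excluded from statistics and from the Z-score distributions."""
    if len(windows) != len(n_snps):
        raise ConfigError("windows and n_snps length mismatch")
    return np.asarray(n_snps) >= min_snps
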