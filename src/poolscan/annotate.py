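"""Gene annotation of selected candidate regions.

Genes are assigned to an SCR when their interval overlaps the region's
extended span by at least 1 bp (half-open abutment does not count). The
report mirrors the usual SCR table: one row per region sorted by group,
chromosome and start, plus per-group counts and core-length summaries.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError
from .io_formats import GeneInterval
from .outlier_scan import ScrRegion


def genes_in_scr(
    regions: Sequence[ScrRegion],
    genes: Sequence[GeneInterval],
) -> list[ScrRegion]:
    """Fill gene_ids (deduplicated, ordered by gene start) for each region's
    extended span. Regions must have extended spans computed."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out = []
    for r in regions:
        if r.ext_start is None or r.ext_end is None:
            raise ConfigError(
                f"region {r.chrom}:{r.core_start}-{r.core_end} has no extended span"
            )
        tree = trees.get(r.chrom)
        hits = sorted(tree.overlap(r.ext_start, r.ext_end)) if tree else []
        seen: dict[str, int] = {}
        for iv in hits:
            gid = iv.data.gene_id
            if gid not in seen:
                seen[gid] = iv.data.start
        ordered = tuple(sorted(seen, key=lambda gid: (seen[gid], gid)))
        out.append(replace(r, gene_ids=ordered))
    return out


_COLUMNS = [
    "group", "scr_id", "chrom", "core_start", "core_end", "core_length",
    "ext_start", "ext_end", "n_genes", "genes",
]


def summarize_scr_table(
    regions: Sequence[ScrRegion],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-region table, per-group summary).

    The table has one row per SCR sorted by (group, chromosome, start) with
    sequential SCR ids; the summary reports the region count and the
    min/mean/max core length per group and overall.
    """
    rows = sorted(
        regions,
        key=lambda r: (r.group or "", r.chrom, r.core_start),
    )
    table = pd.DataFrame(
        [
            {
                "group": r.group or "",
                "scr_id": i + 1,
                "chrom": r.chrom,
                "core_start": r.core_start,
                "core_end": r.core_end,
                "core_length": r.core_length,
                "ext_start": r.ext_start,
                "ext_end": r.ext_end,
                "n_genes": r.n_genes,
                "genes": ",".join(r.gene_ids),
            }
            for i, r in enumerate(rows)
        ],
        columns=_COLUMNS,
    )
    if len(table):
        grouped = table.groupby("group")["core_length"]
        summary = grouped.agg(n="count", min_length="min",
                              mean_length="mean", max_length="max").reset_index()
        overall = pd.DataFrame(
            [{
                "group": "all",
                "n": len(table),
                "min_length": table["core_length"].min(),
                "mean_length": table["core_length"].mean(),
                "max_length": table["core_length"].max(),
            }]
        )
        summary = pd.concat([summary, overall], ignore_index=True)
    else:
        summary = pd.DataFrame(
            columns=["group", "n", "min_length", "mean_length", "max_length"]
        )
    return table, summary
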