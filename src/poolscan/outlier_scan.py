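"""Z-score outlier extraction and selected-candidate-region (SCR) construction.

Genome-wide window statistics are standardized to Z-scores over the eligible
windows; windows beyond the (default) 6-SD cut-off — Z(Hp) or Z(D) below -6,
Z(F_st) above +6 — are significant. Runs of significant windows become SCR
cores; cores separated by at most ``max_gap_windows`` grid steps are
collapsed into one region (the span then includes the gap). Cores are
extended by a flank (default 100 kb) for gene annotation, and classified:

* group A — regions specific to the focal population (no core overlap with
  either sister population's within-population regions);
* group B — regions where the two sister populations' within-population
  cores overlap (reported as the merged span);
* group C — regions from the between-population F_st scan of the two sister
  populations.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io_formats import GenomeLayout
from .window_engine import Window

__all__ = [
    "ScrRegion",
    "ztransform",
    "significant_windows",
    "combine_within",
    "build_scr",
    "extend_scr",
    "classify_groups",
]


@dataclass(frozen=True)
class ScrRegion:
    """A selected candidate region.

    The core span is the union of member windows (plus any collapsed gap);
    the extended span adds the annotation flank, clipped to the chromosome.
    """

    chrom: str
    core_start: int
    core_end: int
    member_indices: tuple[int, ...] = ()
    ext_start: int | None = None
    ext_end: int | None = None
    group: str | None = None
    source: str | None = None
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.core_start >= self.core_end:
            raise DataError(
                f"SCR {self.chrom}:{self.core_start}-{self.core_end} has start >= end"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start

    def overlaps(self, other: "ScrRegion") -> bool:
        """Core-span overlap of >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.core_start < other.core_end
            and other.core_start < self.core_end
        )


def ztransform(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, n-1) over defined entries.

    NaN entries (windows without a defined statistic) stay NaN and do not
    enter the mean/SD.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if len(np.unique(finite)) < 2:
        raise DataError("ztransform needs at least 2 distinct defined values")
    sd = float(np.std(finite, ddof=1))
    if sd == 0.0:
        raise DataError("degenerate distribution: zero standard deviation")
    return (x - float(np.mean(finite))) / sd


def significant_windows(
    z: Sequence[float],
    threshold: float = 6.0,
    direction: str = "lower",
) -> np.ndarray:
    """Strict-inequality outlier mask: z < -threshold (lower) or z > +threshold
    (upper). NaN scores are never significant."""
    if direction not in ("lower", "upper"):
        raise ConfigError(f"unknown direction {direction!r}")
    z = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = z < -threshold if direction == "lower" else z > threshold
    mask[np.isnan(z)] = False
    return mask


def combine_within(
    mask_hp: Sequence[bool],
    mask_d: Sequence[bool],
    mode: str = "union",
) -> np.ndarray:
    """Combine the Hp and D outlier masks (union: either suffices)."""
    if mode not in ("union", "intersection"):
        raise ConfigError(f"unknown combine mode {mode!r}")
    a = np.asarray(mask_hp, dtype=bool)
    b = np.asarray(mask_d, dtype=bool)
    if a.shape != b.shape:
        raise DataError("mask length mismatch")
    return a | b if mode == "union" else a & b


def _grid_step(windows: Sequence[Window]) -> int:
    for prev, cur in zip(windows, windows[1:]):
        if cur.chrom == prev.chrom:
            return cur.start - prev.start
    return windows[0].end - windows[0].start if windows else 0


def build_scr(
    windows: Sequence[Window],
    significant: Sequence[bool],
    max_gap_windows: int = 2,
    step: int | None = None,
    source: str | None = None,
) -> list[ScrRegion]:
    """Merge significant windows into SCR cores.

    Windows must be ordered by (chromosome, start). Two stretches on the same
    chromosome are collapsed when the gap between their spans is at most
    ``max_gap_windows`` grid steps; the collapsed gap is included in the core
    span but its windows are not members. Because windows overlap when
    size > step, spans of near-adjacent significant windows merge naturally.
    """
    significant = np.asarray(significant, dtype=bool)
    if len(windows) != len(significant):
        raise DataError("windows and significance mask length mismatch")
    if step is None:
        step = _grid_step(windows)
    regions: list[ScrRegion] = []
    cur_chrom = None
    cur_start = cur_end = 0
    members: list[int] = []

    def close():
        if members:
            regions.append(
                ScrRegion(cur_chrom, cur_start, cur_end,
                          member_indices=tuple(members), source=source)
            )

    for i in np.flatnonzero(significant):
        w = windows[i]
        if (
            cur_chrom == w.chrom
            and w.start - cur_end <= max_gap_windows * step
        ):
            cur_end = max(cur_end, w.end)
            members.append(int(i))
        else:
            close()
            cur_chrom, cur_start, cur_end = w.chrom, w.start, w.end
            members = [int(i)]
    close()
    return regions


def extend_scr(
    regions: Sequence[ScrRegion],
    layout: GenomeLayout,
    flank: int = 100_000,
) -> list[ScrRegion]:
    """Add the annotation flank to each core, clipped to [0, chromosome length)."""
    out = []
    for r in regions:
        length = layout.lengths[r.chrom]
        out.append(
            replace(
                r,
                ext_start=max(0, r.core_start - flank),
                ext_end=min(length, r.core_end + flank),
            )
        )
    return out


def _coalesce(regions: list[ScrRegion]) -> list[ScrRegion]:
    """Merge overlapping cores within a list (used for group-B pair spans)."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.core_start))
    merged: list[ScrRegion] = []
    for r in regions:
        if merged and merged[-1].overlaps(r):
            last = merged[-1]
            merged[-1] = replace(
                last,
                core_start=min(last.core_start, r.core_start),
                core_end=max(last.core_end, r.core_end),
                member_indices=tuple(sorted(set(last.member_indices) | set(r.member_indices))),
            )
        else:
            merged.append(r)
    return merged


def classify_groups(
    focal_scrs: Sequence[ScrRegion],
    sister1_scrs: Sequence[ScrRegion],
    sister2_scrs: Sequence[ScrRegion],
    between_scrs: Sequence[ScrRegion],
) -> list[ScrRegion]:
    """Assign SCR groups A/B/C (see module docstring); overlap is >= 1 bp on cores."""
    out: list[ScrRegion] = []
    sisters = list(sister1_scrs) + list(sister2_scrs)
    for r in focal_scrs:
        if not any(r.overlaps(s) for s in sisters):
            out.append(replace(r, group="A"))
    pair_spans: list[ScrRegion] = []
    for r1 in sister1_scrs:
        for r2 in sister2_scrs:
            if r1.overlaps(r2):
                pair_spans.append(
                    ScrRegion(
                        r1.chrom,
                        min(r1.core_start, r2.core_start),
                        max(r1.core_end, r2.core_end),
                        member_indices=tuple(
                            sorted(set(r1.member_indices) | set(r2.member_indices))
                        ),
                        source="within-pair",
                    )
                )
    for r in _coalesce(pair_spans):
        out.append(replace(r, group="B"))
    for r in between_scrs:
        out.append(replace(r, group="C"))
    return out
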