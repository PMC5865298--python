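"""End-to-end scan driver.

``run_scan`` ties the stages together: per-pool SNP calling, the common-SNP
intersection, the sliding-window grid, the three window statistics, the
Z-transforms, outlier extraction, SCR construction/merging/extension, group
classification and gene annotation. Outputs are pure functions of (inputs,
config); the run log records the same bookkeeping quantities a scan report
usually prints (SNP counts per pool, common-SNP count, eligible windows,
Z means/SDs, significant-window counts).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotate as _annotate
from .errors import ConfigError
from .io_formats import (
    GeneInterval,
    GenomeLayout,
    SiteCounts,
    write_bed,
    write_window_table,
)
from .outlier_scan import (
    ScrRegion,
    build_scr,
    classify_groups,
    combine_within,
    extend_scr,
    significant_windows,
    ztransform,
)
from .pool_stats import pooled_heterozygosity, window_fst, window_tajima_d
from .snp_calling import CommonSnp, SnpRecord, call_snps_pool, common_snps
from .window_engine import Window, assign_snps, filter_windows, make_windows


@dataclass
class RunConfig:
    """All knobs of a scan run, with the scan's standard defaults."""

    pool_names: list[str] = field(default_factory=lambda: ["SAS", "LAS", "LAN"])
    pool_diploids: list[int] = field(default_factory=lambda: [25, 25, 25])
    min_nonref_reads: int = 2
    multiallelic_policy: str = "drop"
    window_size: int = 200_000
    window_step: int = 50_000
    min_snps_per_window: int = 10
    autosomes_only: bool = True
    tajima_neff_mode: str = "pool_capped"
    tajima_bias: str = "min_count"
    fst_scheme: str = "ratio_of_sums"
    z_threshold: float = 6.0
    within_combine_mode: str = "union"
    max_gap_windows: int = 2
    flank_bp: int = 100_000
    focal_pool: int = 0
    between_pair: tuple[int, int] = (1, 2)

    def __post_init__(self):
        if len(self.pool_names) != len(self.pool_diploids):
            raise ConfigError("pool_names and pool_diploids length mismatch")
        if len(set(self.pool_names)) != len(self.pool_names):
            raise ConfigError("pool names must be unique")

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)


@dataclass
class ScanResultBundle:
    """Everything a scan produces, in memory."""

    windows: list[Window]
    table: pd.DataFrame  # per-window statistics and Z-scores
    within_scrs: dict[str, list[ScrRegion]]  # pool name -> SCR list
    between_scrs: dict[str, list[ScrRegion]]  # "A:B" pair -> SCR list
    grouped_scrs: list[ScrRegion]  # classified A/B/C (3-pool runs)
    scr_table: pd.DataFrame
    scr_summary: pd.DataFrame
    log: dict


def _subset(snps: Sequence, idx: np.ndarray) -> list:
    return [snps[int(i)] for i in idx]


def _pool_view(cs: Sequence[CommonSnp], k: int) -> list[SnpRecord]:
    """Single-pool SnpRecords out of common SNPs (shared labeling preserved)."""
    return [
        SnpRecord(s.chrom, s.pos, s.ref_allele, s.major_allele, s.minor_allele,
                  s.n_maj[k], s.n_min[k], s.depth[k])
        for s in cs
    ]


def run_scan(
    sites: Sequence[SiteCounts] | list[SiteCounts],
    layout: GenomeLayout,
    cfg: RunConfig,
    genes: Sequence[GeneInterval] | None = None,
    out_prefix: str | None = None,
) -> ScanResultBundle:
    """Run the full selection scan on a collection of sites.

    ``sites`` may be any re-iterable of SiteCounts (a list, or a sync reader
    wrapped in ``list``). With three pools, SCRs are classified into groups
    A (focal-specific), B (sister-shared) and C (between-pair F_st); the
    focal pool and the between pair come from the config.
    """
    sites = list(sites)
    if sites and sites[0].n_pools != cfg.n_pools:
        raise ConfigError(
            f"config names {cfg.n_pools} pools but sync has {sites[0].n_pools}"
        )
    log: dict = {"config": {k: v for k, v in asdict(cfg).items()}}

    pool_snps: list[list[SnpRecord]] = [
        call_snps_pool(sites, k, cfg.min_nonref_reads, cfg.multiallelic_policy)
        for k in range(cfg.n_pools)
    ]
    log["snps_per_pool"] = {
        cfg.pool_names[k]: len(pool_snps[k]) for k in range(cfg.n_pools)
    }
    cs = common_snps(pool_snps)
    log["common_snps"] = len(cs)

    windows = make_windows(layout, cfg.window_size, cfg.window_step, cfg.autosomes_only)
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )

    log["eligible_windows"] = {}
    log["z_moments"] = {}
    log["significant_windows"] = {}
    within_scrs: dict[str, list[ScrRegion]] = {}

    for k, name in enumerate(cfg.pool_names):
        assigned = assign_snps(windows, pool_snps[k])
        n_snps = np.array([len(a) for a in assigned])
        eligible = filter_windows(windows, n_snps, cfg.min_snps_per_window)
        hp = np.full(len(windows), np.nan)
        d = np.full(len(windows), np.nan)
        tpi = np.full(len(windows), np.nan)
        tw = np.full(len(windows), np.nan)
        for i, idx in enumerate(assigned):
            if not eligible[i]:
                continue
            wsnps = _subset(pool_snps[k], idx)
            hp[i] = pooled_heterozygosity(wsnps)
            tpi[i], tw[i], d[i] = window_tajima_d(
                wsnps,
                pool_haploid_size=2 * cfg.pool_diploids[k],
                neff_mode=cfg.tajima_neff_mode,
                bias=cfg.tajima_bias,
                min_count=cfg.min_nonref_reads,
            )
        z_hp = ztransform(hp)
        z_d = ztransform(d)
        table[f"n_snps_{name}"] = n_snps
        table[f"hp_{name}"] = hp
        table[f"theta_pi_{name}"] = tpi
        table[f"theta_w_{name}"] = tw
        table[f"tajima_d_{name}"] = d
        table[f"z_hp_{name}"] = z_hp
        table[f"z_d_{name}"] = z_d
        log["eligible_windows"][name] = int(eligible.sum())
        log["z_moments"][f"hp_{name}"] = {
            "mean": float(np.nanmean(hp)), "sd": float(np.nanstd(hp[~np.isnan(hp)], ddof=1))
        }
        log["z_moments"][f"d_{name}"] = {
            "mean": float(np.nanmean(d)), "sd": float(np.nanstd(d[~np.isnan(d)], ddof=1))
        }
        m_hp = significant_windows(z_hp, cfg.z_threshold, "lower")
        m_d = significant_windows(z_d, cfg.z_threshold, "lower")
        mask = combine_within(m_hp, m_d, cfg.within_combine_mode)
        table[f"sig_{name}"] = mask
        log["significant_windows"][name] = int(mask.sum())
        within_scrs[name] = extend_scr(
            build_scr(windows, mask, cfg.max_gap_windows, cfg.window_step,
                      source=f"within:{name}"),
            layout, cfg.flank_bp,
        )

    between_scrs: dict[str, list[ScrRegion]] = {}
    for a in range(cfg.n_pools):
        for b in range(a + 1, cfg.n_pools):
            pair = f"{cfg.pool_names[a]}:{cfg.pool_names[b]}"
            va, vb = _pool_view(cs, a), _pool_view(cs, b)
            assigned = assign_snps(windows, va)
            n_snps = np.array([len(x) for x in assigned])
            eligible = filter_windows(windows, n_snps, cfg.min_snps_per_window)
            fst = np.full(len(windows), np.nan)
            for i, idx in enumerate(assigned):
                if not eligible[i]:
                    continue
                fst[i] = window_fst(_subset(va, idx), _subset(vb, idx), cfg.fst_scheme)
            z_fst = ztransform(fst)
            table[f"n_common_{pair}"] = n_snps
            table[f"fst_{pair}"] = fst
            table[f"z_fst_{pair}"] = z_fst
            mask = significant_windows(z_fst, cfg.z_threshold, "upper")
            table[f"sig_fst_{pair}"] = mask
            log["z_moments"][f"fst_{pair}"] = {
                "mean": float(np.nanmean(fst)),
                "sd": float(np.nanstd(fst[~np.isnan(fst)], ddof=1)),
            }
            log["significant_windows"][f"fst_{pair}"] = int(mask.sum())
            between_scrs[pair] = extend_scr(
                build_scr(windows, mask, cfg.max_gap_windows, cfg.window_step,
                          source=f"fst:{pair}"),
                layout, cfg.flank_bp,
            )

    grouped: list[ScrRegion] = []
    if cfg.n_pools == 3:
        s1, s2 = cfg.between_pair
        pair_key = f"{cfg.pool_names[s1]}:{cfg.pool_names[s2]}"
        if pair_key not in between_scrs:
            pair_key = f"{cfg.pool_names[s2]}:{cfg.pool_names[s1]}"
        grouped = classify_groups(
            within_scrs[cfg.pool_names[cfg.focal_pool]],
            within_scrs[cfg.pool_names[s1]],
            within_scrs[cfg.pool_names[s2]],
            between_scrs[pair_key],
        )
        grouped = extend_scr(grouped, layout, cfg.flank_bp)

    if genes is not None and grouped:
        grouped = _annotate.genes_in_scr(grouped, genes)
    scr_table, scr_summary = _annotate.summarize_scr_table(grouped)
    log["scr_counts"] = (
        scr_table.groupby("group").size().to_dict() if len(scr_table) else {}
    )

    bundle = ScanResultBundle(
        windows, table, within_scrs, between_scrs, grouped,
        scr_table, scr_summary, log,
    )
    if out_prefix:
        _write_bundle(bundle, out_prefix)
    return bundle


def _write_bundle(bundle: ScanResultBundle, prefix: str) -> None:
    write_window_table(bundle.table, f"{prefix}.windows.tsv")
    for name, scrs in bundle.within_scrs.items():
        if scrs:
            write_bed(scrs, f"{prefix}.scr_within_{name}.bed")
    for pair, scrs in bundle.between_scrs.items():
        if scrs:
            write_bed(scrs, f"{prefix}.scr_fst_{pair.replace(':', '_')}.bed")
    if bundle.grouped_scrs:
        write_bed(bundle.grouped_scrs, f"{prefix}.scr_grouped.bed")
        write_bed(
            [(r.chrom, r.ext_start, r.ext_end, r.group or "") for r in bundle.grouped_scrs],
            f"{prefix}.scr_grouped_extended.bed",
        )
    bundle.scr_table.to_csv(f"{prefix}.scr_table.tsv", sep="\t", index=False)
    with open(f"{prefix}.log.json", "w") as fh:
        json.dump(bundle.log, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if math.isnan(v) else v
    if isinstance(x, tuple):
        return list(x)
    return str(x)
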