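"""Bundled reference tables.

Currently one: the published core coordinates of the 32 selected candidate
regions from a Pool-Seq selection scan of Western Pyrenees sheep (groups
A/B/C; see the TSV header). Used as a worked-example fixture for the SCR
merge rule and the region-length summaries.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

#: the three continuous significant stretches on chromosome 6 whose merge
#: (gaps of one and two 50-kb steps) forms region 20 of the table, in bp
OAR6_MERGE_PARTS = (
    ("6", 36_450_000, 37_000_000),
    ("6", 37_050_000, 38_100_000),
    ("6", 38_200_000, 38_400_000),
)


def sheep_scr_regions() -> pd.DataFrame:
    """The 32-region table with core spans converted to bp.

    Columns: group, scr, chrom, core_start, core_end, core_length, n_genes.
    """
    with resources.files("poolscan.data").joinpath("sheep_scr_regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["core_start"] = df.pop("start_kb") * 1000
    df["core_end"] = df.pop("end_kb") * 1000
    df["core_length"] = df["core_end"] - df["core_start"]
    df["chrom"] = df["chrom"].astype(str)
    return df
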