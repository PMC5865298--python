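import numpy as np
import pytest

from poolscan import GenomeLayout, SnpRecord


@pytest.fixture
def layout():
    return GenomeLayout(["1", "2"], {"1": 1_000_000, "2": 400_000})


@pytest.fixture
def tiny_sync(tmp_path):
    """Two pools, four sites; pool columns in sync order A:T:C:G:N:del."""
    text = (
        "1\t100\tA\t10:0:0:0:0:0\t8:2:0:0:0:0\n"
        "1\t250\tC\t0:0:9:3:0:1\t1:0:7:0:2:0\n"
        "1\t900\tG\t0:0:0:12:0:0\t5:0:0:7:0:0\n"
        "2\t50\tT\t0:6:0:0:0:0\t2:4:0:0:0:0\n"
    )
    path = tmp_path / "tiny.sync"
    path.write_text(text)
    return path


def snp(pos, n_maj, n_min, chrom="1", maj="A", mnr="C", ref="A", depth=None):
    return SnpRecord(chrom, pos, ref, maj, mnr, n_maj, n_min,
                     depth if depth is not None else n_maj + n_min)


@pytest.fixture
def make_snp():
    return snp
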