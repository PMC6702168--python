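import numpy as np
import pandas as pd
import pytest

from actseq.io import GenomicInterval
from actseq.simulate import SimConfig, make_manifest, make_sim_genome, simulate_cells


@pytest.fixture(scope="session")
def small_genome():
    """1 chromosome x 2 Mb, 50 disjoint 1 kb peaks, 100 TSS anchors."""
    return make_sim_genome(
        n_chroms=1, chrom_size=2_000_000, n_peaks=50, peak_width=1000,
        n_tss=100, seed=11,
    )


@pytest.fixture(scope="session")
def small_manifest():
    return make_manifest(n_combos=24, n_wells=8, barcode_length=8, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimConfig(
        n_wells=8, cells_per_well_sorted=18, n_combos=24,
        mean_unique_reads=300.0, seed=11,
    )
    return simulate_cells(cfg)


def frame(rows):
    """Fragment table from (chrom, start, end, cell_id[, dup]) tuples."""
    out = []
    for r in rows:
        chrom, start, end, cell = r[:4]
        dup = r[4] if len(r) > 4 else 1
        out.append({"chrom": chrom, "start": start, "end": end,
                    "cell_id": cell, "duplicate_count": dup})
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "cell_id", "duplicate_count"]
    )


@pytest.fixture
def make_frame():
    return frame


@pytest.fixture
def iv():
    return GenomicInterval
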