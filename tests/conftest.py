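import numpy as np
import pandas as pd
import pytest

from ecdna_regulome import CountTable, GenomicInterval, PeakSet


@pytest.fixture
def small_table() -> CountTable:
    """4-sample, 10-peak count table with two conditions."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(1, 100, size=(10, 4)).astype(float),
        index=[f"peak_{i}" for i in range(10)],
        columns=["v1", "v2", "t1", "t2"],
    )
    meta = pd.DataFrame(
        {"condition": ["vehicle", "vehicle", "treated", "treated"],
         "replicate": [1, 2, 1, 2]},
        index=pd.Index(["v1", "v2", "t1", "t2"], name="sample"),
    )
    return CountTable(counts=counts, meta=meta)


def random_peakset(rng, n, mark="H3K27ac", chroms=("chr1", "chr2"),
                   max_pos=10_000, prefix="peak") -> PeakSet:
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 500))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ivs.append(GenomicInterval(chrom, start, start + length,
                                   f"{prefix}_{i}"))
    return PeakSet(mark=mark, intervals=ivs)


def brute_force_overlap_names(a: PeakSet, b: PeakSet) -> set[str]:
    """Quadratic all-pairs overlap oracle: names of a's intervals that
    share >= 1 bp with any interval of b."""
    return {
        ia.name
        for ia in a.intervals
        if any(ia.overlaps(ib) for ib in b.intervals)
    }
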