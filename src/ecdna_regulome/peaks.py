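"""Pooled-sample construction, per-peak read counting, and the copy-number
seed-segment filter.

Peak calling itself (an external tool's job) is out of scope: this module
builds the pooled input a caller would consume and quantifies reads in the
regions it returns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import CNSegment, GenomicInterval, PeakSet, ReadSet, ValidationError

logger = logging.getLogger(__name__)


def pool_reads(
    readsets: list[ReadSet], total: int, seed: int
) -> ReadSet:
    """Sample an equal-weight union of reads across samples.

    Each of the k samples contributes ``total // k`` reads (the first
    ``total % k`` samples, in input order, contribute one extra), sampled
    without replacement. A sample with fewer reads than its quota
    contributes everything it has, with a logged warning. Deterministic
    given ``seed``.
    """
    if not readsets:
        raise ValidationError("need at least one readset")
    if total <= 0:
        raise ValidationError("total must be positive")
    rng = np.random.default_rng(seed)
    k = len(readsets)
    base, extra = divmod(total, k)
    pooled: list[GenomicInterval] = []
    for i, rs in enumerate(readsets):
        quota = base + (1 if i < extra else 0)
        n = len(rs.reads)
        if n < quota:
            logger.warning(
                "sample %s has %d reads < quota %d; taking all",
                rs.sample, n, quota,
            )
            pooled.extend(rs.reads)
        else:
            idx = rng.choice(n, size=quota, replace=False)
            pooled.extend(rs.reads[j] for j in sorted(idx))
    return ReadSet(sample="pooled", reads=pooled)


def _build_tree(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv.name
        )
    return trees


def count_reads_in_peaks(reads: ReadSet, peaks: PeakSet) -> pd.Series:
    """Count reads overlapping each peak by >= 1 bp.

    A read overlapping n peaks contributes to all n. Returns a Series
    indexed by peak name in peak order.
    """
    trees = _build_tree(peaks)
    counts = {iv.name: 0 for iv in peaks.intervals}
    for read in reads.reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(read.start, read.end):
            counts[hit.data] += 1
    return pd.Series(counts, name=reads.sample).loc[peaks.names()]


def count_table_from_readsets(
    readsets: list[ReadSet], peaks: PeakSet, meta: pd.DataFrame
):
    """Quantify every sample against one peak set into a CountTable."""
    from .types import CountTable

    cols = {rs.sample: count_reads_in_peaks(rs, peaks) for rs in readsets}
    counts = pd.DataFrame(cols)
    return CountTable(counts=counts, meta=meta.loc[counts.columns])


SEED_CN_MARGIN = 2.5  # copies above chromosome-arm ploidy
VIRAL_CN_MIN = 1.0


def select_seed_segments(segments: list[CNSegment]) -> list[CNSegment]:
    """Keep amplification seed segments.

    Non-viral segments pass when cn >= arm_ploidy + 2.5; viral segments
    pass when cn >= 1. Both thresholds inclusive; input order preserved.
    """
    kept = []
    for seg in segments:
        if seg.is_viral:
            if seg.cn >= VIRAL_CN_MIN:
                kept.append(seg)
        else:
            if seg.arm_ploidy is None:
                raise ValidationError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} missing "
                    "arm_ploidy"
                )
            if seg.cn >= seg.arm_ploidy + SEED_CN_MARGIN:
                kept.append(seg)
    return kept
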