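"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its config and seed, and returns the
truth needed to score the downstream stage (true size factors, differential
labels, mark-overlap memberships, planted Hi-C biases) so nothing has to be
re-derived when benchmarking.

The peak-count generator emulates an 8-sample two-condition ChIP-seq
quantitation (two conditions, four replicate samples each): per-sample
multiplicative size factors, a smooth SD-vs-mean relation s = kappa*m^gamma
produced by a Gamma-Poisson hierarchy, and a configurable fraction of truly
differential peaks with a fixed log2 fold change. The Hi-C generator builds
a small multi-contig genome (including a viral contig), distance-decaying
intra-contig background, constant trans background, an additive contact
signal among cycle bins decaying with circular distance, and planted
multiplicative per-bin biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import build_cycle_bin_map
from .types import (
    ContactMatrix,
    CountTable,
    CycleStructure,
    GenomicInterval,
    PeakSet,
    ReadSet,
    SegmentDef,
    ValidationError,
)


# ------------------------------------------------------- peak counts

@dataclass
class PeakSimConfig:
    n_peaks: int = 5000
    n_replicates: int = 4          # per condition; 2 conditions -> 8 samples
    conditions: tuple[str, str] = ("vehicle", "treated")
    baseline_range: tuple[float, float] = (50.0, 5000.0)  # log-uniform mean
    size_factor_range: tuple[float, float] = (0.5, 2.0)   # log-uniform
    kappa: float = 0.15            # SD model s = kappa * m^gamma
    gamma: float = 1.0
    pi1: float = 0.1               # fraction of truly differential peaks
    spike_log2fc: float = 2.0      # true log2 FC of differential peaks
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pi1 < 1):
            raise ValidationError("pi1 must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValidationError("need >= 1 replicate per condition")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")


@dataclass
class PeakSimTruth:
    size_factors: pd.Series
    is_differential: pd.Series
    true_log2fc: pd.Series
    kappa: float
    gamma: float


def simulate_peak_counts(
    cfg: PeakSimConfig,
) -> tuple[CountTable, PeakSimTruth]:
    """Gamma-Poisson peak counts with known size factors and spikes.

    Baseline means are log-uniform over ``baseline_range``; differential
    peaks multiply the treated-condition mean by 2**spike_log2fc. Counts
    are Poisson around a Gamma-distributed rate whose shape is chosen so
    the SD of size-factor-normalized signal tracks kappa * m**gamma.
    """
    rng = np.random.default_rng(cfg.seed)
    peaks = [f"peak_{i}" for i in range(cfg.n_peaks)]
    samples, conditions, replicates = [], [], []
    for cond in cfg.conditions:
        for r in range(1, cfg.n_replicates + 1):
            samples.append(f"{cond}_{r}")
            conditions.append(cond)
            replicates.append(r)
    meta = pd.DataFrame(
        {"condition": conditions, "replicate": replicates},
        index=pd.Index(samples, name="sample"),
    )

    lo, hi = cfg.baseline_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_peaks))
    flo, fhi = cfg.size_factor_range
    log_f = rng.uniform(np.log(flo), np.log(fhi), size=len(samples))
    log_f -= log_f.mean()  # geometric mean 1, matching the RLE convention
    factors = pd.Series(np.exp(log_f), index=meta.index,
                        name="size_factor")

    n_diff = int(round(cfg.pi1 * cfg.n_peaks))
    diff_idx = rng.choice(cfg.n_peaks, size=n_diff, replace=False)
    is_diff = np.zeros(cfg.n_peaks, dtype=bool)
    is_diff[diff_idx] = True
    log2fc = np.where(is_diff, cfg.spike_log2fc, 0.0)

    counts = np.empty((cfg.n_peaks, len(samples)))
    treated = cfg.conditions[1]
    for j, s in enumerate(samples):
        cond_mult = np.where(
            is_diff & (meta.loc[s, "condition"] == treated),
            2.0 ** cfg.spike_log2fc,
            1.0,
        )
        m = mu * cond_mult  # normalized-scale mean for this sample
        target_var = (cfg.kappa * m ** cfg.gamma) ** 2
        excess = np.maximum(target_var - m, 0.0)  # variance beyond Poisson
        has_od = excess > 0
        shape = np.empty_like(m)
        shape[has_od] = m[has_od] ** 2 / excess[has_od]
        mult = np.ones_like(m)
        mult[has_od] = rng.gamma(shape[has_od], 1.0 / shape[has_od])
        lam = m * mult * factors.iloc[j]
        counts[:, j] = rng.poisson(lam)

    table = CountTable(
        counts=pd.DataFrame(counts, index=peaks, columns=samples),
        meta=meta,
    )
    truth = PeakSimTruth(
        size_factors=factors,
        is_differential=pd.Series(is_diff, index=peaks),
        true_log2fc=pd.Series(log2fc, index=peaks),
        kappa=cfg.kappa,
        gamma=cfg.gamma,
    )
    return table, truth


# ------------------------------------------------------- mark regions

@dataclass
class MarkSimConfig:
    genome_length: int = 10_000_000
    chrom: str = "chr1"
    n_k4me1: int = 200
    k4me1_length: int = 2000
    n_k4me3: int = 100
    k4me3_length: int = 1000
    n_k27ac: int = 500
    k27ac_length: int = 500
    frac_in_k4me1: float = 0.6
    frac_in_k4me3: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_in_k4me1 <= 1 and 0 <= self.frac_in_k4me3 <= 1):
            raise ValidationError("overlap fractions must be in [0, 1]")
        if self.frac_in_k4me1 + self.frac_in_k4me3 > 1:
            raise ValidationError("overlap fractions must sum to <= 1")


@dataclass
class MarkSimTruth:
    in_k4me1: pd.Series  # per K27ac peak name
    in_k4me3: pd.Series


def _place_nonoverlapping(
    rng, n: int, length: int, genome_length: int,
    occupied: list[tuple[int, int]], max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries * max(n, 1):
            raise ValidationError(
                "infeasible packing: cannot place non-overlapping regions"
            )
        tries += 1
        start = int(rng.integers(0, genome_length - length))
        iv = (start, start + length)
        if any(iv[0] < e and s < iv[1] for s, e in occupied + placed):
            continue
        placed.append(iv)
    return placed


def simulate_mark_regions(
    cfg: MarkSimConfig,
) -> tuple[PeakSet, PeakSet, PeakSet, MarkSimTruth]:
    """Mark-region sets with known overlap structure.

    K4me1 and K4me3 regions are placed uniformly without overlaps; each
    K27ac peak is placed inside a K4me1 region, inside a K4me3 region, or
    in clean background according to the configured fractions, and its
    realized membership is recorded. Returns (k27ac, k4me1, k4me3, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    me1 = _place_nonoverlapping(
        rng, cfg.n_k4me1, cfg.k4me1_length, cfg.genome_length, []
    )
    me3 = _place_nonoverlapping(
        rng, cfg.n_k4me3, cfg.k4me3_length, cfg.genome_length, me1
    )
    if cfg.k27ac_length > cfg.k4me1_length or \
            cfg.k27ac_length > cfg.k4me3_length:
        raise ValidationError("K27ac peaks must fit inside mark regions")

    k27, memb1, memb3 = [], [], []
    occupied = me1 + me3
    for i in range(cfg.n_k27ac):
        u = rng.random()
        if u < cfg.frac_in_k4me1:
            s, e = me1[int(rng.integers(0, len(me1)))]
            start = int(rng.integers(s, e - cfg.k27ac_length + 1))
            memb1.append(True)
            memb3.append(False)
        elif u < cfg.frac_in_k4me1 + cfg.frac_in_k4me3:
            s, e = me3[int(rng.integers(0, len(me3)))]
            start = int(rng.integers(s, e - cfg.k27ac_length + 1))
            memb1.append(False)
            memb3.append(True)
        else:
            # background: avoid every mark region
            while True:
                start = int(
                    rng.integers(0, cfg.genome_length - cfg.k27ac_length)
                )
                iv = (start, start + cfg.k27ac_length)
                if not any(iv[0] < e and s < iv[1] for s, e in occupied):
                    break
            memb1.append(False)
            memb3.append(False)
        k27.append(
            GenomicInterval(cfg.chrom, start, start + cfg.k27ac_length,
                            f"k27ac_{i}")
        )

    def _peakset(mark, regions, prefix):
        return PeakSet(mark=mark, intervals=[
            GenomicInterval(cfg.chrom, s, e, f"{prefix}_{i}")
            for i, (s, e) in enumerate(regions)
        ])

    names = [iv.name for iv in k27]
    truth = MarkSimTruth(
        in_k4me1=pd.Series(memb1, index=names),
        in_k4me3=pd.Series(memb3, index=names),
    )
    return (
        PeakSet(mark="H3K27ac", intervals=k27),
        _peakset("H3K4me1", me1, "k4me1"),
        _peakset("H3K4me3", me3, "k4me3"),
        truth,
    )


# ------------------------------------------------------- reads

def simulate_reads(
    peaks: PeakSet,
    depth: int,
    enrichment: float,
    seed: int,
    n_samples: int = 1,
    read_length: int = 100,
    genome_length: int | None = None,
) -> tuple[list[ReadSet], pd.Series]:
    """Fixed-length reads enriched in peaks over uniform background.

    A read lands in peak territory with probability proportional to
    ``enrichment`` times the summed peak length (``enrichment=inf`` puts
    every read in a peak), uniformly within a length-weighted random peak;
    otherwise uniformly in background. Returns the readsets and the
    expected per-peak count per sample.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    rng = np.random.default_rng(seed)
    chrom = peaks.intervals[0].chrom
    if genome_length is None:
        genome_length = max(iv.end for iv in peaks.intervals) + 100_000
    lengths = np.array([len(iv) for iv in peaks.intervals], dtype=float)
    l_peaks = lengths.sum()
    l_bg = genome_length - l_peaks
    if np.isinf(enrichment):
        p_peak = 1.0
    else:
        p_peak = enrichment * l_peaks / (enrichment * l_peaks + l_bg)
    peak_probs = lengths / l_peaks
    expected = pd.Series(
        depth * p_peak * peak_probs, index=peaks.names(),
        name="expected_count",
    )
    readsets = []
    for s in range(n_samples):
        reads = []
        in_peak = rng.random(depth) < p_peak
        choices = rng.choice(len(peaks.intervals), size=depth, p=peak_probs)
        for r in range(depth):
            if in_peak[r]:
                iv = peaks.intervals[choices[r]]
                span = max(len(iv) - read_length, 0)
                start = iv.start + int(rng.integers(0, span + 1))
            else:
                start = int(rng.integers(0, genome_length - read_length))
            reads.append(
                GenomicInterval(chrom, start, start + read_length,
                                f"read_{s}_{r}")
            )
        readsets.append(ReadSet(sample=f"sample_{s}", reads=reads))
    return readsets, expected


# ------------------------------------------------------- Hi-C

@dataclass
class HicSimConfig:
    contig_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 200_000, "chr2": 84_000, "HPV16": 16_000,
        }
    )
    bin_size: int = 1000
    alpha: float = 1.0             # intra-contig decay P(d) ~ (d+1)^-alpha
    background_scale: float = 100.0
    trans_level: float = 1.0
    segments: list[SegmentDef] = field(
        default_factory=lambda: [
            SegmentDef(1, "chr1", 50_000, 90_000),
            SegmentDef(2, "HPV16", 0, 16_000),
            SegmentDef(3, "chr2", 20_000, 44_000),
        ]
    )
    path: list[tuple[int, str]] = field(
        default_factory=lambda: [(1, "+"), (2, "+"), (3, "-")]
    )
    copy_count: float = 4.1
    amplitude: float = 50.0        # cycle contact signal scale
    beta: float = 1.0              # circular-distance decay exponent
    bias_range: tuple[float, float] = (0.5, 2.0)
    poisson_noise: bool = True
    seed: int = 0


def simulate_hic(
    cfg: HicSimConfig,
) -> tuple[ContactMatrix, list[SegmentDef], CycleStructure, np.ndarray]:
    """Genome-wide contact matrix with an embedded circular ecDNA signal.

    Intra-contig background decays as (d+1)^-alpha in bin units; trans
    background is constant. An additive signal amplitude*(dc+1)^-beta
    links every pair of cycle bins at circular bin distance dc. Planted per-bin biases
    b_i multiply entries as b_i*b_j; optional Poisson sampling adds noise.
    Returns (matrix, segment defs, cycle, planted biases).
    """
    rng = np.random.default_rng(cfg.seed)
    bins: list[tuple[str, int]] = []
    for chrom, size in cfg.contig_sizes.items():
        n_c = -(-size // cfg.bin_size)
        bins.extend((chrom, b * cfg.bin_size) for b in range(n_c))
    n = len(bins)
    chrom_of = np.array([c for c, _ in bins])
    pos_of = np.array([s // cfg.bin_size for _, s in bins])

    same = chrom_of[:, None] == chrom_of[None, :]
    d = np.abs(pos_of[:, None] - pos_of[None, :])
    values = np.where(
        same,
        cfg.background_scale * (d + 1.0) ** (-cfg.alpha),
        cfg.trans_level,
    )

    cycle = CycleStructure(
        cycle_id=1, copy_count=cfg.copy_count, path=list(cfg.path)
    )
    bin_map = build_cycle_bin_map(cycle, cfg.segments, cfg.bin_size)
    index = {b: i for i, b in enumerate(bins)}
    gidx = np.array([index[(chrom, start)] for _sid, chrom, start, _o
                     in bin_map])
    m = len(gidx)
    for i in range(m):
        for j in range(i + 1, m):
            dc = min(j - i, m - (j - i))
            sig = cfg.amplitude * (dc + 1.0) ** (-cfg.beta)
            values[gidx[i], gidx[j]] += sig
            values[gidx[j], gidx[i]] += sig

    blo, bhi = cfg.bias_range
    biases = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=n))
    values = values * np.outer(biases, biases)

    if cfg.poisson_noise:
        upper = np.triu(rng.poisson(np.triu(values, k=1)), k=1)
        diag = np.diag(rng.poisson(np.diag(values)))
        values = upper + upper.T + diag

    matrix = ContactMatrix(
        bin_size=cfg.bin_size, bins=bins, values=values.astype(float)
    )
    return matrix, list(cfg.segments), cycle, biases
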