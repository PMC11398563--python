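"""Core domain objects shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention). The viral
contig (e.g. ``HPV16``) is an ordinary chromosome name; nothing downstream
treats it specially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on a named contig."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """An ordered collection of named intervals carrying one chromatin mark.

    Intervals are kept sorted by (chrom, start, end); names must be unique.
    """

    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValidationError(f"duplicate peak names: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]


@dataclass
class ReadSet:
    """Aligned-read footprints for one sample."""

    sample: str
    reads: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CountTable:
    """Raw per-peak, per-sample read counts with condition/replicate metadata.

    ``counts`` is a peaks x samples DataFrame; ``meta`` is indexed by sample
    id with columns ``condition`` and ``replicate``. Conditions partition the
    samples (every sample has exactly one condition).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValidationError("need >= 2 samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValidationError("counts columns must match meta sample ids")
        for col in ("condition", "replicate"):
            if col not in self.meta.columns:
                raise ValidationError(f"meta missing column {col!r}")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate peak names in count table")

    @property
    def peaks(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])


@dataclass(frozen=True)
class SegmentDef:
    """A genomic segment of an amplicon, stored 0-based half-open."""

    id: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.id}: start {self.start} >= end {self.end}"
            )


@dataclass
class CycleStructure:
    """An ordered, oriented, circular path of segments defining an ecDNA.

    The path is interpreted circularly: the last segment adjoins the first.
    """

    cycle_id: int
    copy_count: float
    path: list[tuple[int, str]]  # (segment id, '+'|'-')

    def __post_init__(self) -> None:
        if not self.path:
            raise ValidationError("cycle path must be non-empty")
        if self.copy_count <= 0:
            raise ValidationError("copy_count must be positive")
        for seg_id, orient in self.path:
            if orient not in {"+", "-"}:
                raise ValidationError(f"bad orientation {orient!r}")
            if seg_id == 0:
                raise ValidationError(
                    "segment id 0 (source/sink sentinel) not allowed in path"
                )


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment with its chromosome-arm ploidy context."""

    chrom: str
    start: int
    end: int
    cn: float
    arm_ploidy: float | None = None
    is_viral: bool = False

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValidationError("cn must be >= 0")
        if not self.is_viral:
            if self.arm_ploidy is None:
                raise ValidationError(
                    "non-viral segment requires arm_ploidy"
                )
            if self.arm_ploidy <= 0:
                raise ValidationError("arm_ploidy must be positive")


SYMMETRY_TOL = 1e-9


@dataclass
class ContactMatrix:
    """A binned symmetric contact matrix with its bin table.

    ``bins`` is an ordered list of (chrom, bin start bp); ``values`` is a
    dense symmetric non-negative array aligned with it.
    """

    bin_size: int
    bins: list[tuple[str, int]]
    values: np.ndarray
    balanced: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        n = len(self.bins)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} bins"
            )
        if (self.values < 0).any():
            raise ValidationError("contact counts must be non-negative")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix not symmetric (max |A - A^T| = {asym:g})"
            )

    def bin_index(self) -> dict[tuple[str, int], int]:
        return {b: i for i, b in enumerate(self.bins)}

    @property
    def n_bins(self) -> int:
        return len(self.bins)
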