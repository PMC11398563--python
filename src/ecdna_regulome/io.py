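"""Readers and writers for the pipeline's external text formats.

Formats: BED3/BED4 peaks, AmpliconArchitect-style cycles text, counts TSV
with a sample-metadata sidecar, dense contact-matrix TSV with a bins TSV,
and results TSV. Internally everything is 0-based half-open; the cycles
dialect is 1-based inclusive and converted at this boundary, so writing a
parsed file reproduces the original coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ContactMatrix,
    CycleStructure,
    GenomicInterval,
    PeakSet,
    SegmentDef,
    ValidationError,
)


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def _fmt(x: float) -> str:
    """Format a float at 6 significant digits (deterministic output)."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path, mark: str = "") -> PeakSet:
    """Read a BED3+ file into a PeakSet.

    Coordinates are taken as 0-based half-open per the BED convention.
    Intervals without a name column are auto-named ``peak_<i>`` by file
    order. Strand is read from column 6 when present.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] else \
                f"peak_{len(intervals)}"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, strand)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(mark=mark, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t"
                f"{iv.strand}\n"
            )


# ---------------------------------------------------------------- cycles

_SEG_RE = re.compile(r"^Segment\s+(\d+)\s+(\S+)\s+(\d+)\s+(\d+)\s*$")
_CYC_RE = re.compile(
    r"^Cycle=(\d+);Copy_count=([\d.eE+-]+);Segments=(\S+)\s*$"
)


def read_cycles(
    path: str | Path,
) -> tuple[list[SegmentDef], list[CycleStructure]]:
    """Parse an AmpliconArchitect-style cycles file.

    Segment lines carry 1-based inclusive coordinates; they are converted to
    the internal 0-based half-open convention (start-1, end). Orientation
    order within each cycle path is preserved. Segment id 0 is the linear
    source/sink sentinel and may not appear inside a cycle path.
    """
    segments: list[SegmentDef] = []
    seg_ids: set[int] = set()
    cycles: list[CycleStructure] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _SEG_RE.match(line)
            if m:
                sid = int(m.group(1))
                if sid in seg_ids:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate segment id {sid}"
                    )
                start1, end1 = int(m.group(3)), int(m.group(4))
                segments.append(
                    SegmentDef(sid, m.group(2), start1 - 1, end1)
                )
                seg_ids.add(sid)
                continue
            m = _CYC_RE.match(line)
            if m:
                path_tokens = m.group(3).split(",")
                cyc_path: list[tuple[int, str]] = []
                for tok in path_tokens:
                    tm = re.match(r"^(\d+)([+-−])$", tok)
                    if not tm:
                        raise ParseError(
                            f"{path}:{lineno}: bad segment token {tok!r}"
                        )
                    sid = int(tm.group(1))
                    orient = "-" if tm.group(2) in "-−" else "+"
                    if sid == 0:
                        raise ParseError(
                            f"{path}:{lineno}: segment id 0 (source/sink "
                            "sentinel) inside a cycle path"
                        )
                    if sid not in seg_ids:
                        raise ParseError(
                            f"{path}:{lineno}: undefined segment id {sid}"
                        )
                    cyc_path.append((sid, orient))
                cycles.append(
                    CycleStructure(
                        cycle_id=int(m.group(1)),
                        copy_count=float(m.group(2)),
                        path=cyc_path,
                    )
                )
                continue
            raise ParseError(f"{path}:{lineno}: unrecognized line {line!r}")
    return segments, cycles


def write_cycles(
    segments: list[SegmentDef],
    cycles: list[CycleStructure],
    path: str | Path,
) -> None:
    """Write segments and cycles back in the 1-based inclusive dialect."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"Segment {seg.id} {seg.chrom} {seg.start + 1} {seg.end}\n"
            )
        for cyc in cycles:
            toks = ",".join(f"{sid}{o}" for sid, o in cyc.path)
            fh.write(
                f"Cycle={cyc.cycle_id};Copy_count={_fmt(cyc.copy_count)};"
                f"Segments={toks}\n"
            )


# ---------------------------------------------------------------- counts

def read_counts(
    counts_path: str | Path, meta_path: str | Path
):
    """Read a counts TSV (first column peak name, header of sample ids)
    plus a sample-metadata sidecar TSV (sample, condition, replicate)."""
    from .types import CountTable

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountTable(counts=counts, meta=meta)


def write_counts(
    table, counts_path: str | Path, meta_path: str | Path
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="peak",
                        float_format="%.6g")
    table.meta.to_csv(meta_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- matrix

def read_contact_matrix(
    matrix_path: str | Path, bins_path: str | Path, bin_size: int
) -> ContactMatrix:
    """Read a dense contact-matrix TSV plus its bins TSV (chrom, start).

    The matrix must be square, non-negative and symmetric to 1e-9, and its
    dimension must equal the number of bins.
    """
    values = np.loadtxt(matrix_path, ndmin=2)
    bins_df = pd.read_csv(bins_path, sep="\t")
    if not {"chrom", "start"} <= set(bins_df.columns):
        raise ParseError(f"{bins_path}: need columns 'chrom' and 'start'")
    bins = [(str(c), int(s)) for c, s in
            zip(bins_df["chrom"], bins_df["start"])]
    if values.shape[0] != values.shape[1]:
        raise ValidationError(
            f"matrix is not square: {values.shape}"
        )
    if values.shape[0] != len(bins):
        raise ValidationError(
            f"matrix dimension {values.shape[0]} != {len(bins)} bins"
        )
    return ContactMatrix(bin_size=bin_size, bins=bins, values=values)


def write_contact_matrix(
    matrix: ContactMatrix, matrix_path: str | Path, bins_path: str | Path
) -> None:
    np.savetxt(matrix_path, matrix.values, delimiter="\t", fmt="%.17g")
    pd.DataFrame(matrix.bins, columns=["chrom", "start"]).to_csv(
        bins_path, sep="\t", index=False
    )


# ---------------------------------------------------------------- results

DIFF_COLUMNS = [
    "peak", "mean_ctrl", "mean_trt", "fc", "log2fc", "z", "lfdr", "called",
]


def write_results(obj, path: str | Path, bins_path: str | Path | None = None
                  ) -> None:
    """Write a DiffResult table or an AssembledMatrix to TSV.

    DiffResult tables are written with a fixed column order, rows sorted by
    peak name, floats at 6 significant digits. AssembledMatrix is written as
    a matrix TSV plus a bin-map TSV (``bins_path`` required).
    """
    from .hic import AssembledMatrix

    if isinstance(obj, AssembledMatrix):
        if bins_path is None:
            raise ValueError("AssembledMatrix output needs bins_path")
        np.savetxt(path, obj.values, delimiter="\t", fmt="%.12g")
        rows = [
            {"cycle_bin": i, "segment_id": sid, "chrom": chrom,
             "genome_start": start, "orientation": orient}
            for i, (sid, chrom, start, orient) in enumerate(obj.bin_map)
        ]
        pd.DataFrame(
            rows, columns=["cycle_bin", "segment_id", "chrom",
                           "genome_start", "orientation"]
        ).to_csv(bins_path, sep="\t", index=False)
        return

    df = obj if isinstance(obj, pd.DataFrame) else obj.table
    df = df.sort_index()
    with open(path, "w") as fh:
        fh.write("\t".join(DIFF_COLUMNS) + "\n")
        for peak, row in df.iterrows():
            vals = [str(peak)] + [
                _fmt(row[c]) for c in DIFF_COLUMNS[1:]
            ]
            fh.write("\t".join(vals) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="peak")
    if "called" in df.columns:
        df["called"] = df["called"].astype(str).str.lower() == "true"
    return df
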