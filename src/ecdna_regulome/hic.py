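"""Contact-map reassembly along a circular ecDNA and ICE balancing.

Given a binned genome-wide contact matrix and the ordered, oriented
segments of an ecDNA cycle, the submatrix for every pair of cycle bins is
extracted and laid out along the cycle coordinate; blocks between segments
on different contigs (e.g. a human chromosome and the viral genome) come
from the trans entries of the genome-wide matrix. The assembled matrix is
then balanced by iterative correction (ICE) so every bin has equal
visibility, and two balanced matrices can be compared descriptively by
circular-distance stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ContactMatrix, CycleStructure, SegmentDef, ValidationError

# (segment id, chrom, genome bin start, orientation) per cycle position
CycleBinEntry = tuple[int, str, int, str]


def bins_for_segment(
    seg: SegmentDef, orientation: str, bin_size: int
) -> list[int]:
    """Genome bin starts covering a segment, in cycle order.

    Bins floor(start/b) .. ceil(end/b)-1 inclusive — partial edge bins are
    kept. Order is reversed for '-' orientation.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    first = seg.start // bin_size
    last = -(-seg.end // bin_size) - 1  # ceil(end/b) - 1
    bins = [b * bin_size for b in range(first, last + 1)]
    return bins[::-1] if orientation == "-" else bins


@dataclass
class AssembledMatrix:
    """A contact matrix re-indexed along the cycle coordinate."""

    values: np.ndarray
    bin_map: list[CycleBinEntry]
    bin_size: int
    balanced: bool = False
    bias: np.ndarray | None = None
    missing_bins: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bin_map)


def build_cycle_bin_map(
    cycle: CycleStructure,
    segdefs: dict[int, SegmentDef] | list[SegmentDef],
    bin_size: int,
) -> list[CycleBinEntry]:
    """Concatenate per-segment bin lists along the circular path."""
    if isinstance(segdefs, list):
        segdefs = {s.id: s for s in segdefs}
    bin_map: list[CycleBinEntry] = []
    for seg_id, orient in cycle.path:
        if seg_id not in segdefs:
            raise ValidationError(f"cycle references unknown segment {seg_id}")
        seg = segdefs[seg_id]
        for start in bins_for_segment(seg, orient, bin_size):
            bin_map.append((seg_id, seg.chrom, start, orient))
    return bin_map


def assemble_cycle_matrix(
    matrix: ContactMatrix,
    cycle: CycleStructure,
    segdefs: dict[int, SegmentDef] | list[SegmentDef],
) -> AssembledMatrix:
    """Extract and reassemble the contact matrix along the cycle.

    ``assembled[i, j] = M[bin_map[i], bin_map[j]]`` over the concatenated
    cycle bins; symmetric by construction. A cycle bin absent from the
    genome-wide bin table gets a zero row/column and is flagged in
    ``missing_bins``. The input must be unbalanced (raw counts).
    """
    if matrix.balanced:
        raise ValidationError("assemble from the raw (unbalanced) matrix")
    bin_map = build_cycle_bin_map(cycle, segdefs, matrix.bin_size)
    index = matrix.bin_index()
    n = len(bin_map)
    rows = np.full(n, -1, dtype=int)
    missing: list[int] = []
    for i, (_sid, chrom, start, _o) in enumerate(bin_map):
        j = index.get((chrom, start), -1)
        rows[i] = j
        if j < 0:
            missing.append(i)
    values = np.zeros((n, n))
    present = rows >= 0
    sub = matrix.values[np.ix_(rows[present], rows[present])]
    values[np.ix_(present, present)] = sub
    return AssembledMatrix(
        values=values,
        bin_map=bin_map,
        bin_size=matrix.bin_size,
        missing_bins=missing,
    )


@dataclass
class IceResult:
    """Balanced matrix, per-bin biases, and convergence diagnostics."""

    matrix: np.ndarray
    bias: np.ndarray
    masked: np.ndarray  # boolean, True where bin was excluded
    iterations: int
    marginal_cv: float


def ice_balance(
    A: np.ndarray, tol: float = 1e-5, max_iter: int = 200
) -> IceResult:
    """Iterative correction: remove multiplicative per-bin biases.

    Bins with zero marginal are masked. Each iteration divides rows and
    columns by their marginals (rescaled to mean 1 over unmasked bins)
    until the coefficient of variation of unmasked marginals drops to
    ``tol`` or ``max_iter`` is reached. The result satisfies
    ``balanced = bias_i * raw_ij * bias_j`` with the global scale chosen so
    the mean unmasked marginal is 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("matrix must be square")
    if (A < 0).any():
        raise ValidationError("matrix must be non-negative")
    if np.abs(A - A.T).max() > 1e-9:
        raise ValidationError("matrix must be symmetric")
    W = A.copy()
    marg = W.sum(axis=1)
    masked = marg == 0
    if masked.all():
        raise ValidationError("all bins have zero marginal")
    bias = np.ones(A.shape[0])
    iterations = 0
    while True:
        marg = W.sum(axis=1)
        active = marg[~masked]
        mean_marg = active.mean()
        cv = active.std() / mean_marg
        iterations += 1
        if cv <= tol or iterations > max_iter:
            break
        s = marg / mean_marg
        s[masked] = 1.0
        W /= np.outer(s, s)
        bias /= s
    # Final global rescale: mean unmasked marginal exactly 1.
    marg = W.sum(axis=1)
    mean_marg = marg[~masked].mean()
    W /= mean_marg
    bias /= np.sqrt(mean_marg)
    cv = float(np.std(marg[~masked] / mean_marg) /
               np.mean(marg[~masked] / mean_marg))
    return IceResult(
        matrix=W, bias=bias, masked=masked, iterations=iterations,
        marginal_cv=cv,
    )


def balance_assembled(
    assembled: AssembledMatrix, tol: float = 1e-5, max_iter: int = 200
) -> AssembledMatrix:
    """ICE-balance an assembled cycle matrix."""
    res = ice_balance(assembled.values, tol=tol, max_iter=max_iter)
    return AssembledMatrix(
        values=res.matrix,
        bin_map=assembled.bin_map,
        bin_size=assembled.bin_size,
        balanced=True,
        bias=res.bias,
        missing_bins=list(assembled.missing_bins),
    )


def circular_distance(i: int, j: int, n: int) -> int:
    """Minimum clockwise/counter-clockwise bin separation on the circle."""
    d = abs(i - j) % n
    return min(d, n - d)


def contact_decay(
    assembled: AssembledMatrix, exclude_masked: bool = True
) -> pd.DataFrame:
    """Mean contact frequency per circular-distance stratum."""
    n = assembled.n_bins
    keep = np.ones(n, dtype=bool)
    if exclude_masked and assembled.missing_bins:
        keep[assembled.missing_bins] = False
    rows = []
    for d in range(1, n // 2 + 1):
        vals = [
            assembled.values[i, (i + d) % n]
            for i in range(n)
            if keep[i] and keep[(i + d) % n]
        ]
        if vals:
            rows.append({"distance": d, "mean_contact": float(np.mean(vals)),
                         "n_pairs": len(vals)})
    return pd.DataFrame(rows)


def compare_matrices(
    A: AssembledMatrix, B: AssembledMatrix, pseudocount: float = 1.0
) -> dict:
    """Descriptive comparison of two balanced cycle matrices.

    Per circular-distance stratum, the Pearson correlation of entries at
    that distance; plus the global log2-ratio matrix and the mean absolute
    log2 ratio over unmasked entries (with pseudocount). This is a
    descriptive summary, not an inferential test.
    """
    if A.bin_map != B.bin_map or A.bin_size != B.bin_size:
        raise ValidationError("matrices have different bin maps")
    if not (A.balanced and B.balanced):
        raise ValidationError("compare balanced matrices")
    n = A.n_bins
    keep = np.ones(n, dtype=bool)
    for mb in (A.missing_bins, B.missing_bins):
        if mb:
            keep[mb] = False
    strata = []
    for d in range(1, n // 2 + 1):
        xs, ys = [], []
        for i in range(n):
            j = (i + d) % n
            if keep[i] and keep[j]:
                xs.append(A.values[i, j])
                ys.append(B.values[i, j])
        if len(xs) < 2:
            continue
        xs, ys = np.asarray(xs), np.asarray(ys)
        if np.array_equal(xs, ys):
            r = 1.0  # identical strata correlate perfectly, by definition
        elif xs.std() == 0 or ys.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(xs, ys)[0])
        strata.append({"distance": d, "pearson_r": r, "n_pairs": len(xs)})
    num, den = A.values + pseudocount, B.values + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(num / den)
    log_ratio[num == den] = 0.0  # covers the 0/0 case at pseudocount 0
    sel = np.outer(keep, keep)
    np.fill_diagonal(sel, False)
    return {
        "strata": pd.DataFrame(strata),
        "log2_ratio": log_ratio,
        "mean_abs_log2_ratio": float(np.abs(log_ratio[sel]).mean()),
    }
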