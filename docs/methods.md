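# Methods

## The differential-activation statistic

### Normalization

Raw read counts in peak regions are normalized per sample under the
assumption that the tallest peaks should be comparable across samples.
For each sample, the top-30% threshold is the ⌊0.3·n⌋-th largest raw
count (ties inclusive); the normalization subset is the **intersection**
of the per-sample top sets. The ambiguity here was real — "top 30% for
each sample" could also be read as a union — but RLE needs one common
subset positive in every sample, and the intersection is the only reading
that guarantees this; `q` is configurable if a larger subset is wanted.

On that subset, RLE (median-of-ratios) size factors are computed: the
reference for peak p is the geometric mean of its counts across samples
(subset peaks with a zero in any sample are dropped first), the raw
factor for sample s is the median over subset peaks of `count_ps / ref_p`,
and factors are rescaled to geometric mean 1. The factors are then
applied to **all** peaks, not just the subset. Because the subset holds
only high-signal peaks, the factors are insensitive to differing
low-level background between samples — the property that motivates the
percentile restriction in the first place.

### The SD-vs-mean trend

With two replicates per condition a per-peak SD is meaningless, so the
SD of normalized signal is modeled as a smooth function of mean signal:
per peak, the mean m_p and sample SD s_p are computed across **all**
samples pooled, including between-condition signal ("as if they were
replicates"). A loess fit (local linear, tricube weights, span 0.5, no
robustness iterations) of s_p on m_p is evaluated on a 256-point uniform
grid over the observed mean range; evaluation interpolates linearly
between grid points, extrapolates as a constant beyond the range, and is
clamped below at max(1e-8, the 5th percentile of fitted values) so z
denominators never vanish.

Pooling across conditions inflates the SD for truly differential peaks
and therefore costs power where differential peaks dominate a mean
stratum; this is a deliberate property of the design (it makes the trend
conservative), and it is the main reason the statistic is benchmarked
with 10% spiked peaks rather than an extreme single outlier. None of the
loess particulars (span, grid size, extrapolation rule, floor) are forced
by the method's definition; the values here were chosen once for
stability and are exposed in config.

### z-scores and the empirical-Bayes lfdr

For each peak, `z = (x̄_trt − x̄_ctrl) / (σ̂(m)·√(1/n₁+1/n₂))`, with m the
mean over the samples being compared. The √(1/n₁+1/n₂) factor is the
standard two-sample scaling for a difference of group means with σ̂ as
the per-observation SD; `scale_by_n=False` gives the raw mean difference
over σ̂ instead, since the bare definition of "a z-score with a modeled
SD denominator" admits either. With the scaling, a pure-null z
distribution is approximately standard normal, which the lfdr machinery
then verifies empirically rather than assumes.

The marginal z density f is estimated by a Poisson regression of
histogram counts (120 equal-width bins spanning the data) on a natural
cubic spline basis (7 df, knots at quantiles of the bin midpoints). The
empirical null N(δ, σ₀²) comes from central matching: a quadratic fit to
log f on the central 50% of the z distribution gives δ = −β₁/(2β₂) and
σ₀ = √(−1/(2β₂)). The null proportion is π₀ = min(1, f(δ)·σ₀·√(2π)) —
the value that makes the null density touch f at its mode. Then
`lfdr(z) = min(1, π₀·φ((z−δ)/σ₀)/(σ₀·f(z)))`. The theoretical mode fixes
δ=0, σ₀=1 and still estimates π₀ from f(0). If the spline fit diverges or
the central log-density is not concave, the code falls back to the
theoretical null with a logged warning rather than failing.

A peak is called differentially activated when
`(x̄_trt + c)/(x̄_ctrl + c) > 2` and `lfdr < 0.3` and (by default,
direction "up") z > 0. The pseudocount c = 1 guards against zero control
means; fold change on pseudocounted normalized means is one of several
defensible definitions and is configurable. Called peaks are intersected
(≥ 1 bp overlap, half-open coordinates) with enhancer (H3K4me1) or
promoter (H3K4me3) region sets, and `common_peaks` reports cross-sample
overlap of call sets.

## Hi-C reassembly and ICE

A cycle is an ordered list of oriented segments, interpreted circularly.
Segment bins are ⌊start/b⌋ … ⌈end/b⌉−1 (partial edge bins kept — the
snapping rule loses no signal), reversed for '−' orientation; the cycle
bin map is the concatenation over the path, and
`assembled[i,j] = M[bin_map[i], bin_map[j]]` over the genome-wide matrix,
so blocks between segments on different contigs come from M's trans
entries — this is why the genome-wide (human + viral) matrix is the
canonical input. A genome bin shared by two adjacent segments appears
once per occurrence; duplicated cycle positions are permitted. Bins
absent from M are zero-filled and flagged rather than erroring.

ICE balancing masks zero-marginal bins, then iteratively divides rows and
columns by their marginals (rescaled to mean 1 over unmasked bins each
iteration) until the unmasked-marginal CV ≤ tol (default 1e-5, cap 200
iterations), finishing with a global rescale to mean marginal exactly 1.
The returned bias vector satisfies `balanced = bias_i · raw_ij · bias_j`.
No percentile coverage filter is applied — at the matrix sizes this
package targets, zero-marginal masking is the only exclusion needed.

`compare_matrices` is **descriptive, not inferential**: per
circular-distance stratum (minimum clockwise/counter-clockwise bin
separation) it reports the Pearson correlation of entries at that
distance, plus a global log2-ratio matrix and its mean absolute value
over unmasked off-diagonal entries (pseudocount 1 by default). Strata
with byte-identical entries correlate 1 by definition.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
analysis assumes, plus the truth needed to score it:

- **Peak counts**: 2 conditions × 4 replicate samples (8 total), baseline
  means log-uniform on [50, 5000], size factors log-uniform on [0.5, 2]
  (geometric mean 1), differential fraction π₁ = 0.1 with log2FC = 2
  spikes in the treated condition. Counts are Poisson around a
  Gamma-distributed rate whose shape is set so the SD of normalized
  signal tracks s = κ·m^γ (κ = 0.15, γ = 1); the match is exact only when
  size factors ≈ 1 in the Poisson term, and is verified at 15% tolerance
  in the generator's own test. The smooth, tunable mean–SD relation is
  the one property the loess trend requires.
- **Mark regions**: non-overlapping H3K4me1/H3K4me3 regions placed
  uniformly (rejection sampling; infeasible packing errors out), H3K27ac
  peaks placed inside K4me1 / inside K4me3 / in clean background at
  configured fractions (defaults 0.6 / 0.2), memberships recorded.
- **Reads**: fixed-length reads land in peak territory with probability
  proportional to `enrichment`, uniformly within a length-weighted peak,
  otherwise uniformly in background; expected per-peak counts recorded.
- **Hi-C**: three contigs (200 kb + 84 kb human-like, 16 kb viral;
  300 bins at 1 kb), intra-contig background ∝ (d+1)^−α (α = 1, scale
  100), constant trans background (1), an additive cycle signal
  amplitude·(dc+1)^−β (amplitude 50, β = 1) between all cycle-bin pairs
  at circular distance dc, planted multiplicative per-bin biases
  log-uniform on [0.5, 2], and optional (default on) Poisson sampling.
  The cycle signal being additive keeps human–viral junction blocks
  strictly positive, which makes the monotone circular-decay property
  well-defined.

Every generator is a pure function of config + seed.

What the generators do **not** emulate: mappability and GC structure,
fragment-length effects, duplicate reads, copy-number variation inside
segments, restriction-fragment granularity, or biological replicate
correlation beyond the size-factor/dispersion model. Passing benchmarks
therefore show the statistics behave as designed under their own
assumptions — correct normalization, calibrated nulls, power against
planted effects, exact interval/matrix algebra — not that those
assumptions hold in any particular real dataset.

## Numerical and design notes

- All internal coordinates are 0-based half-open; the cycles file dialect
  is 1-based inclusive and converted only at the I/O boundary, so writing
  a parsed file reproduces the original text. The viral contig is an
  ordinary chromosome name throughout.
- The equal-weight pooling quota is ⌊total/k⌋ with the remainder assigned
  in input order; sampling is without replacement (a union of reads means
  distinct reads), and a sample shorter than its quota contributes
  everything with a warning.
- Read counting is any-overlap (≥ 1 bp), a read contributing to every
  peak it overlaps; midpoint counting was the alternative and is not
  what common quantitation tools do by default.
- Duplicate peak names on read are an error, never silently renamed.
- Percentile-threshold ties are included; both seed-filter thresholds
  are inclusive.
- Benchmark problem sizes (5,000 peaks × 8 samples, 300-bin Hi-C genome,
  50×50 random matrices, 100–200 oracle instances) are desk-scale choices
  that keep every stage's structure exercised — multi-contig trans
  blocks, reverse orientations, partial bins — while each generator runs
  in well under a second.
- Plotting is intentionally out of scope; the comparison and decay tables
  are plain DataFrames that plot trivially downstream.

## Known limitations

- The z-score's two-sample scaling and the fold-change pseudocount are
  conventions, not derivations; both are exposed in config because the
  statistic's bare definition underdetermines them.
- Central matching can misestimate σ₀ when the z distribution is strongly
  non-Gaussian in the bulk (e.g. a heavy-tailed mixture of per-peak
  scales); the caller's FC filter makes final calls robust to moderate
  misestimation, and the theoretical mode is available.
- ICE assumes factorizable (multiplicative) bin biases; copy-number
  steps along an amplicon violate this and will be absorbed into the
  bias vector rather than preserved as signal.
- `compare_matrices` makes no attempt at statistical testing of
  differential contacts; it summarizes.
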