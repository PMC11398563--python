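# ecdna-regulome

Statistical tooling for studying regulatory activity on **hybrid
human–viral ecDNA** — extrachromosomal circular DNA that interleaves human
genomic segments with an integrated HPV genome, as found in HPV-positive
oropharyngeal cancers. The package implements, as a tested and reusable
pipeline, two analyses that such studies need but that no off-the-shelf
tool provides end to end:

1. **A low-replicate differential chromatin-activation statistic** for
   ChIP-seq/ATAC-seq peak counts. With only two biological replicates per
   condition and ~10⁴ peak regions, per-peak variance estimates are
   useless; instead the statistic
   - restricts to peaks in the top 30% of raw signal in *every* sample and
     derives RLE (median-of-ratios) size factors `f_s` from that subset,
     applying them to all peaks (the tallest peaks are assumed comparable
     across samples, making the factors insensitive to differing background);
   - models the standard deviation of normalized signal as a loess function
     σ̂(m) of mean signal, pooling all samples as if they were replicates;
   - forms an approximate z-score per peak,
     `z = (x̄_trt − x̄_ctrl) / (σ̂(m)·√(1/n₁ + 1/n₂))`;
   - assigns each z an empirical-Bayes local false discovery rate,
     `lfdr(z) = π₀ φ((z−δ)/σ₀) / (σ₀ f(z))`, with the mixture density f
     estimated by a spline–Poisson histogram smooth and the null N(δ, σ₀²)
     by central matching;
   - calls peaks at fold change > 2 and lfdr < 0.3 (defaults), and
     intersects calls with H3K4me1 (enhancer) / H3K4me3 (promoter) regions.

2. **Hi-C contact-map reassembly along a circular ecDNA.** Given a binned
   genome-wide contact matrix and the ordered, oriented segments of an
   ecDNA cycle (AmpliconArchitect-style cycles file, with the viral contig
   treated as an ordinary chromosome), the per-segment submatrices —
   including trans blocks at human–viral junctions — are extracted and
   concatenated along the circle, ICE-balanced (iterative correction until
   the marginal coefficient of variation drops below tolerance), and
   summarized by contact frequency per circular-distance stratum.

Supporting stages: equal-weight read pooling for unbiased peak calling,
per-peak read quantitation, the copy-number seed-segment rule
(cn ≥ arm ploidy + 2.5, viral cn ≥ 1), and synthetic-data generators with
recorded ground truth for every stage.

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/01_differential_peaks.py
normalization subset: 1175 of 5000 peaks
size-factor max relative error vs truth: 3.09%
called 500 differential peaks (500 true, 0 false)
recall among spiked peaks: 100.0%
```

A 5,000-peak, 8-sample table with 10% four-fold spiked peaks is simulated;
the RLE factors recover the planted per-sample scales to a few percent and
the caller finds every spike without false positives.

```sh
$ python examples/03_ecdna_contact_map.py
genome-wide matrix: 300 bins of 1000 bp
cycle path: 1+ -> 2+ -> 3- (80 cycle bins)
balanced marginal CV: 9.79e-06
Spearman rho, contact vs circular distance: -0.996
```

After ICE balancing, every cycle bin has equal visibility (marginal CV
~10⁻⁵) and mean contact decreases monotonically with circular distance —
the Hi-C signature of a circular molecule.

The same stages are available as a CLI:

```sh
ecdna-regulome sim peaks --seed 1 --outdir run/
ecdna-regulome diff --counts run/counts.tsv --meta run/samples.tsv --out run/diff.tsv
ecdna-regulome demo --seed 7 --outdir run/   # full deterministic pipeline
```

Every run writes a `manifest.json` with the config and sha256 checksums of
each output; identical config + seed reproduce byte-identical files.

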