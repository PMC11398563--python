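"""Intersecting activated H3K27ac peaks with enhancer/promoter marks.

Simulates H3K4me1 (enhancer) and H3K4me3 (promoter) region sets plus
H3K27ac peaks with a known 60% / 20% membership split, then recovers the
overlap counts with the interval-intersection operations.
"""

import ecdna_regulome as er

k27ac, k4me1, k4me3, truth = er.simulate_mark_regions(
    er.MarkSimConfig(n_k27ac=500, frac_in_k4me1=0.6, frac_in_k4me3=0.2,
                     seed=3)
)

in_me1, n_me1 = er.intersect_marks(k27ac, k4me1)
in_me3, n_me3 = er.intersect_marks(k27ac, k4me3)
common = er.common_peaks(k4me1, k4me3)

print(f"{n_me1} of {len(k27ac)} K27ac peaks overlap K4me1 enhancer regions"
      f" (truth: {int(truth.in_k4me1.sum())})")
print(f"{n_me3} of {len(k27ac)} K27ac peaks overlap K4me3 promoter regions"
      f" (truth: {int(truth.in_k4me3.sum())})")
print(f"{len(common)} K4me1 regions overlap a K4me3 region")
# The intersection counts equal the generator's recorded memberships
# exactly; marks were placed non-overlapping, so the last count is 0.
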