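"""Copy-number seed-segment selection.

Applies the amplification seed rule -- keep non-viral segments whose copy
number is at least 2.5 copies above chromosome-arm ploidy, and viral
segments with copy number >= 1 -- to a small table of boundary cases.
"""

import ecdna_regulome as er

segments = [
    er.CNSegment("chr20", 45_000_000, 45_310_000, cn=6.6, arm_ploidy=2.0),
    er.CNSegment("chr20", 45_310_000, 45_500_000, cn=4.4, arm_ploidy=2.0),
    er.CNSegment("chr9", 10_000_000, 10_050_000, cn=4.5, arm_ploidy=2.0),
    er.CNSegment("HPV16", 0, 7904, cn=4.1, is_viral=True),
    er.CNSegment("HPV16", 0, 1000, cn=0.4, is_viral=True),
]

kept = er.select_seed_segments(segments)
for seg in segments:
    status = "kept" if seg in kept else "dropped"
    ploidy = "viral" if seg.is_viral else f"ploidy {seg.arm_ploidy}"
    print(f"{seg.chrom}:{seg.start}-{seg.end}  cn={seg.cn} ({ploidy}): "
          f"{status}")
# Both thresholds are inclusive: cn exactly ploidy+2.5 (chr9) and viral
# cn exactly 1 are seeds.
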