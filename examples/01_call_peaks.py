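"""Call CAGE peaks from 5'-tag counts.

Builds a small set of collapsed CAGE tags, clusters them by single linkage
(gap <= 50 bp), normalizes expression to tags per million and selects each
peak's single-base representative.
"""

from cagetss import CageTag, PeakCallParams, call_peaks

tags = [
    CageTag("chr1", 100, "+", 5),   # sharp promoter-like cluster ...
    CageTag("chr1", 130, "+", 3),   # ... 30 bp away: merged (gap <= 50)
    CageTag("chr1", 200, "+", 2),   # 70 bp away: its own peak
    CageTag("chr1", 130, "-", 4),   # opposite strand: never merged
]

peaks = call_peaks(tags, PeakCallParams(cluster_distance=50, min_tpm=0.0))

print(f"{len(tags)} tag positions -> {len(peaks)} peaks")
for p in peaks:
    print(f"  {p.interval.chrom}:{p.interval.start}-{p.interval.end} "
          f"({p.interval.strand})  tags={p.tag_count}  tpm={p.tpm:,.0f}  "
          f"representative={p.representative}")

# The representative is the position carrying the most 5' tag ends; tpm is
# count * 1e6 / library size (library = all 14 tags here, hence the large
# values). The two plus-strand tags at 100/130 merged into one peak whose
# representative is 100 (5 tags > 3 tags).
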