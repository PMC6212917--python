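"""Window scans: SNV density hotspots and Cook's-distance nsSNV outliers.

The demo simulation plants a 5-fold SNV hotspot for sample AM1 on chr2
(positions 100-200 kb).  Density scanning finds it directly; the
Cook's-distance detector flags windows where one sample's count profile
departs from the cross-sample consensus.
"""

from macdiv import (
    bin_counts,
    cooks_outliers,
    demo_config,
    density_outliers,
    merge_samples,
    simulate,
)

bundle = simulate(demo_config(seed=1))
m = merge_samples(bundle.per_sample, roster=bundle.config.samples)

carriers = m.carrier_matrix()
positions = {}
for j, s in enumerate(bundle.config.samples):
    sub = m.sites[carriers[:, j]]
    positions[s] = {c: g["pos"].to_numpy() for c, g in sub.groupby("chrom")}

wms = bin_counts(positions, bundle.reference_lengths, window_size=50_000)

print("per-sample SNV density outliers above 9.5/kb (50-kb windows):")
hits = density_outliers(wms["chr2"], rate_per_kb=9.5)
print(hits.to_string(index=False))
# only AM1 exceeds the threshold, in the two hotspot windows on chr2

# The Cook's-distance rule targets SINGLE windows where one sample departs
# from the cross-sample consensus; a broad multi-window hotspot like AM1's is
# partly absorbed by its own fit (that is the density scan's job).  Inject a
# one-window spike to see the influence detector fire.  The 10-kb grid gives
# the toy 500-kb chromosomes enough windows for a 30x-mean threshold to be
# exceedable; a real genome's thousands of 50-kb windows need no such change.
wms10 = bin_counts(positions, bundle.reference_lengths, window_size=10_000)
wm = wms10["chr1"]
j = wm.samples.index("CR1")
wm.counts[30, j] *= 5

print("\nCook's-distance outlier scan (multiplier 30, 10-kb windows, one "
      "5x single-window spike injected for CR1 on chr1):")
for chrom, w in wms10.items():
    res = cooks_outliers(w, multiplier=30)
    if res is None:
        continue
    flagged = res.flagged_windows()
    print(f"  {chrom}: {len(flagged)} flagged of {len(res.windows)} windows "
          f"(max D = {res.max_d.max():.3f})")
    if len(flagged):
        print(res.to_bed().to_string(index=False))
# A window is an outlier when its distance in any per-sample fit exceeds
# 30x that fit's mean Cook's distance.
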