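"""Build a merged peak atlas from replicate peak calls.

Simulates per-population ATAC peak calls around latent loci, clusters
overlapping calls, merges fully overlapping clusters to their mean
coordinates and splits multi-summit clusters, then applies the width
filter.
"""

from ridgemotif import build_atlas, cluster_peaks, filter_atlas
from ridgemotif.synthetic import SimulationConfig, simulate_peak_calls

cfg = SimulationConfig(seed=42, n_peaks=200)
calls, truth = simulate_peak_calls(cfg)
peaks = [p for pop_peaks in calls.values() for p in pop_peaks]

clusters = cluster_peaks(peaks)
full = sum(
    1 for c in clusters
    if all(max(p.start for p in c.peaks) <= q.summit < min(p.end for p in c.peaks)
           for q in c.peaks)
)
atlas = filter_atlas(build_atlas(peaks))

print(f"input peak calls:        {len(peaks)} across {len(calls)} populations")
print(f"overlap clusters:        {len(clusters)}")
print(f"fully overlapping:       {full} ({100 * full / len(clusters):.1f}%)")
print(f"atlas peaks after merge: {len(atlas)}")
print(f"from multi-summit split: {len(atlas) - full}")
# A fully overlapping cluster collapses to one consensus peak at the mean
# start/summit/end of its members; clusters whose summits disagree are
# split into one peak per distinct summit, which is why the atlas can be
# larger than the cluster count.
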