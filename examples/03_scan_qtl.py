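"""Interval-mapping and Kruskal-Wallis QTL scans on a planted effect.

Plants a QTL explaining 20% of trait variance on chromosome 1, scans the
consensus map with Haley-Knott regression on HMM transmission
probabilities, and reports peaks with LOD-drop support intervals plus the
marker-wise Kruskal-Wallis test.
"""

import numpy as np

import f1binmap as fb
from f1binmap import qtlscan
from f1binmap.segtype import SiteTable

cfg = fb.SimConfig(n_chrom=3, snps_per_chrom=300, chrom_len_bp=10_000_000, seed=7)
pop, truth = fb.simulate_population(cfg)
table = SiteTable.from_population(pop).mask_low_confidence().classify().segregation_test()
kept, _ = fb.filter_sites(table)
bins = fb.make_bins(kept)
maternal, paternal = fb.build_parental_maps(bins)
consensus = fb.merge_consensus(maternal, paternal, bins)

rng = np.random.default_rng(42)
values, tt = fb.simulate_traits(truth, [(0, 40.0, [0, 0, 1, 1], 0.20)], rng=rng)
print("planted QTL: chromosome 1 at 40 cM, PVE 20%")

grids = qtlscan.transmission_probs(consensus, bins, step_cM=1.0)
result = qtlscan.interval_mapping(values, grids, lod_threshold=2.5)
for p in result.peaks:
    print(f"peak on {p.lg} at {p.cM:.0f} cM: LOD {p.lod:.2f}, PVE {p.pve:.1f}%, "
          f"1-LOD interval {p.interval_1lod[0]:.0f}-{p.interval_1lod[1]:.0f} cM")

kw = qtlscan.kw_scan(values, bins, alpha=0.005)
top = kw.sort_values("pvalue").head(3)
print("\nstrongest Kruskal-Wallis markers (P < .005 is significant):")
print(top.to_string(index=False))

report = qtlscan.qtl_to_physical(result, consensus, bins, drop=1)
top_peak = result.peaks[0]
report = report[report["peak_cM"] == top_peak.cM]
print("\nphysical intervals under the top peak's 1-LOD support region:")
print(report[["lg", "peak_cM", "chrom", "start", "end"]].head(8).to_string(index=False))
# The top peak should fall within ~10 cM of the planted position; its PVE
# is the realized variance fraction of this draw (around the planted 20%,
# with sizeable sampling spread at n=176).  The KW scan agrees on the
# same region.
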