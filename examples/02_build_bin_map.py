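"""Five-step bin construction and linkage-map building.

Runs the whole chain on a simulated 3-chromosome population: SNPs are
collapsed into recombination-defined bin markers, grouped at independence
LOD 9, ordered, and the parental maps merged through hkxhk bridge markers.
"""

import f1binmap as fb
from f1binmap.segtype import SiteTable

cfg = fb.SimConfig(n_chrom=3, snps_per_chrom=300, chrom_len_bp=10_000_000,
                   chrom_len_cM=80.0, seed=7)
pop, truth = fb.simulate_population(cfg)
table = SiteTable.from_population(pop).mask_low_confidence().classify().segregation_test()
kept, _ = fb.filter_sites(table)

bins = fb.make_bins(kept, window_bp=500_000)
print(f"{len(kept)} SNPs -> {len(bins)} bin markers "
      f"({dict(bins.df['seg_set'].value_counts())})")

maternal, paternal = fb.build_parental_maps(bins)
consensus = fb.merge_consensus(maternal, paternal, bins)
snp_counts = dict(zip(bins.df["id"], bins.df["snp_count"]))
print("\nconsensus map summary (per linkage group):")
print(fb.map_summary(consensus, snp_counts).to_string(
    index=False, float_format=lambda x: f"{x:.2f}"))
# Each simulated chromosome should come back as one linkage group of
# roughly its true genetic length (genotyping error inflates lengths a
# little); the Average row's interval is total length / (markers - groups).
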