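"""Narrow-sense heritability by REML on a marker-based relationship matrix.

Simulates a polygenic trait with a known h2 and recovers it from the bin
genotypes: h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
"""

import numpy as np

import f1binmap as fb
from f1binmap.segtype import SiteTable

cfg = fb.SimConfig(n_chrom=3, snps_per_chrom=250, chrom_len_bp=10_000_000, seed=11)
pop, truth = fb.simulate_population(cfg)
table = SiteTable.from_population(pop).mask_low_confidence().classify().segregation_test()
kept, _ = fb.filter_sites(table)
bins = fb.make_bins(kept)

rng = np.random.default_rng(5)
for h2_true in (0.0, 0.5, 0.8):
    values, _ = fb.simulate_traits(truth, [], h2_polygenic=h2_true, rng=rng)
    est = fb.heritability(bins, values)
    print(f"planted h2 = {h2_true:.1f} -> estimated {est.h2:.2f} "
          f"(sigma_g2 {est.sigma_g2:.2f}, sigma_e2 {est.sigma_e2:.2f})")
# Estimates track the planted values with sampling noise of roughly
# +/-0.1 at n=176; the null case should sit near zero.
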