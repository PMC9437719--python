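"""Collinearity accounting and genetic-map-guided scaffold re-anchoring.

Fragments a simulated genome into 50 scaffolds, misassigns 20% of them in
a mock reference, classifies mapped markers as co-anchored / misaligned /
new-anchored, then re-anchors every scaffold from the genetic map alone
and writes AGP.
"""

from pathlib import Path

import numpy as np

import f1binmap as fb
from f1binmap import synteny
from f1binmap.simdata import marker_scaffold_positions

out = Path("scratch/example_anchor")
out.mkdir(parents=True, exist_ok=True)

cfg = fb.SimConfig(n_chrom=5, snps_per_chrom=300, chrom_len_bp=10_000_000,
                   error_rate=0.0, missing_rate=0.0, seed=3)
pop, truth = fb.simulate_population(cfg)
layout, reference, true_agp = fb.fragment_genome(
    truth, n_scaffolds=50, misassign_rate=0.2, min_markers_per_scaffold=3)

markers = marker_scaffold_positions(truth, layout)
markers["lg"] = markers["chrom"].str.replace("Chr", "LG")

table = synteny.classify_vs_reference(
    markers[["marker", "lg", "scaffold"]], reference[["scaffold", "chrom"]])
print("marker classes against the (partly wrong) reference anchoring:")
print(table[["lg", "co_anchored", "misaligned", "new_anchored",
             "pct_collinearity"]].to_string(index=False))

anchors, agp = synteny.anchor_scaffolds(
    [markers[["marker", "lg", "cM", "scaffold", "scaf_pos"]]],
    layout[["scaffold", "length"]])
synteny.write_agp(agp, out / "reanchored.agp", comment="map-guided re-anchoring")

placed, pct = synteny.assembly_stats(anchors, int(layout["length"].sum()))
acc = synteny.anchoring_accuracy(anchors, layout)
print(f"\nplaced {placed:,} bp ({pct:.1f}% of scaffold bases); "
      f"{100*acc:.1f}% on the true chromosome with the true orientation")
print(f"AGP written to {out/'reanchored.agp'}")
# The per-group collinearity reflects the injected 20% misassignment,
# while re-anchoring from the map recovers placements near-perfectly.
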