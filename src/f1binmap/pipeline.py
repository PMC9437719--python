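"""End-to-end orchestration of the simulate -> classify -> bin -> map ->
qtl -> anchor chain with deterministic seeding and a run manifest."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio, qtlscan, synteny
from .binning import make_bins
from .linkage import build_parental_maps, map_summary, merge_consensus
from .segtype import filter_sites
from .simdata import (SimConfig, fragment_genome, marker_scaffold_positions,
                      simulate_population, simulate_traits)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the conventional settings used
    throughout the package (500 kb window, independence LOD 9, max 9
    missing calls, LOD 2.5, KW alpha .005, 10 cM cross-environment
    tolerance)."""

    sim: SimConfig = field(default_factory=SimConfig)
    window_bp: int = 500_000
    ind_lod_min: float = 9.0
    max_missing: int = 9
    min_joint: int = 20
    min_lod: float = 3.0
    lod_threshold: float = 2.5
    kw_alpha: float = 0.005
    tol_cM: float = 10.0
    min_support: int = 4
    max_support: int = 200
    p_min: float = 0.05
    swap_parents: bool = False
    qtl_pve: float = 0.2
    n_scaffolds: int = 0  # 0 = 3 per chromosome
    misassign_rate: float = 0.2
    seed: int = 0

    def stage_rng(self, stage: str):
        derived = (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)
        return np.random.default_rng(derived)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir, stages=None):
    """Run the full chain (or a contiguous subset named in ``stages``) on a
    fresh simulation, writing every declared artifact plus a manifest.

    Returns the manifest dict.  Stage failures raise with the stage name in
    the message.
    """
    all_stages = ["simulate", "classify", "bin", "map", "qtl", "anchor"]
    stages = stages or all_stages
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    state = {}

    def stage(name):
        return name in stages

    try:
        if stage("simulate"):
            cfg = config.sim
            pop, truth = simulate_population(cfg, rng=config.stage_rng("simulate"))
            fileio.write_vcf(pop, outdir / "population.vcf")
            truth.to_json(outdir / "truth.json")
            artifacts["vcf"] = "population.vcf"
            artifacts["truth"] = "truth.json"
            state.update(pop=pop, truth=truth)
    except Exception as e:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        if stage("classify"):
            if "pop" not in state:
                table = fileio.read_vcf(outdir / "population.vcf")
            else:
                from .segtype import SiteTable

                table = SiteTable.from_population(state["pop"])
            table.mask_low_confidence(config.min_support, config.max_support)
            table.classify(swap_parents=config.swap_parents)
            table.segregation_test()
            kept, log = filter_sites(table, p_min=config.p_min)
            fileio.write_genotype_tsv(kept, outdir / "genotypes.tsv")
            fileio.write_site_meta_tsv(kept, outdir / "sites.tsv")
            log.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
            artifacts.update(genotypes="genotypes.tsv", sites="sites.tsv",
                             rejections="rejections.tsv")
            state["sites"] = kept
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    try:
        if stage("bin"):
            bins = make_bins(state["sites"], window_bp=config.window_bp)
            fileio.write_bins(bins, outdir / "bins.bed", outdir / "bin_genotypes.tsv")
            artifacts.update(bins_bed="bins.bed", bin_genotypes="bin_genotypes.tsv")
            state["bins"] = bins
    except Exception as e:
        raise RuntimeError(f"stage 'bin' failed: {e}") from e

    try:
        if stage("map"):
            bins = state["bins"]
            maternal, paternal = build_parental_maps(
                bins, ind_lod_min=config.ind_lod_min, max_missing=config.max_missing,
                min_joint=config.min_joint, min_lod=config.min_lod,
            )
            consensus = merge_consensus(maternal, paternal, bins,
                                        ind_lod_min=config.ind_lod_min,
                                        max_missing=config.max_missing,
                                        min_joint=config.min_joint, min_lod=config.min_lod)
            snp_counts = dict(zip(bins.df["id"], bins.df["snp_count"]))
            for gmap, tag in ((maternal, "maternal"), (paternal, "paternal"),
                              (consensus, "consensus")):
                fileio.write_map_tsv(gmap, bins, outdir / f"map_{tag}.tsv")
                artifacts[f"map_{tag}"] = f"map_{tag}.tsv"
            map_summary(consensus, snp_counts).to_csv(
                outdir / "map_summary.tsv", sep="\t", index=False, float_format="%.4g"
            )
            artifacts["map_summary"] = "map_summary.tsv"
            state.update(maternal=maternal, paternal=paternal, consensus=consensus)
    except Exception as e:
        raise RuntimeError(f"stage 'map' failed: {e}") from e

    try:
        if stage("qtl"):
            truth, bins, consensus = state["truth"], state["bins"], state["consensus"]
            rng = config.stage_rng("qtl")
            qtl_spec = [(0, truth.config.chrom_len_cM[0] / 2.0, [0, 0, 1, 1], config.qtl_pve)]
            values, _ = simulate_traits(truth, qtl_spec, rng=rng)
            fileio.write_traits_tsv({"sim_trait": values}, bins.progeny_names,
                                    outdir / "traits.tsv")
            grids = qtlscan.transmission_probs(consensus, bins)
            result = qtlscan.interval_mapping(values, grids,
                                              lod_threshold=config.lod_threshold,
                                              peak_sep_cM=config.tol_cM,
                                              trait="sim_trait", environment="sim")
            result.frame.to_csv(outdir / "scan.tsv", sep="\t", index=False,
                                float_format="%.5g")
            kw = qtlscan.kw_scan(values, bins, alpha=config.kw_alpha)
            kw.to_csv(outdir / "kw_scan.tsv", sep="\t", index=False, float_format="%.5g")
            report = qtlscan.qtl_to_physical(result, consensus, bins, drop=1)
            report.to_csv(outdir / "qtl_report.tsv", sep="\t", index=False,
                          float_format="%.5g")
            artifacts.update(traits="traits.tsv", scan="scan.tsv", kw_scan="kw_scan.tsv",
                             qtl_report="qtl_report.tsv")
            state["scan"] = result
    except Exception as e:
        raise RuntimeError(f"stage 'qtl' failed: {e}") from e

    try:
        if stage("anchor"):
            truth, bins, consensus = state["truth"], state["bins"], state["consensus"]
            n_scaffolds = config.n_scaffolds or 3 * truth.config.n_chrom
            layout, ref, true_agp = fragment_genome(
                truth, n_scaffolds, config.misassign_rate, rng=config.stage_rng("anchor")
            )
            layout.to_csv(outdir / "layout.tsv", sep="\t", index=False)
            mk = marker_scaffold_positions(truth, layout)
            bin_scaffold = _bin_scaffold_frame(bins, consensus, mk)
            table = synteny.classify_vs_reference(
                bin_scaffold.rename(columns={"id": "marker"})[["marker", "lg", "scaffold"]],
                ref[["scaffold", "chrom"]],
            )
            table.to_csv(outdir / "collinearity.tsv", sep="\t", index=False,
                         float_format="%.1f")
            anchors, agp = synteny.anchor_scaffolds(
                [bin_scaffold.rename(columns={"id": "marker"})],
                layout[["scaffold", "length"]],
            )
            anchors.to_csv(outdir / "anchors.tsv", sep="\t", index=False,
                           float_format="%.4g")
            synteny.write_agp(agp, outdir / "assembly.agp", comment="map-guided re-anchoring")
            synteny.write_agp(true_agp, outdir / "assembly_true.agp", comment="simulation truth")
            artifacts.update(layout="layout.tsv", collinearity="collinearity.tsv",
                             anchors="anchors.tsv", agp="assembly.agp",
                             true_agp="assembly_true.agp")
    except Exception as e:
        raise RuntimeError(f"stage 'anchor' failed: {e}") from e

    from . import __version__ as _version

    manifest = {
        "version": _version,
        "seed": config.seed,
        "stages": [s for s in all_stages if s in stages],
        "parameters": {
            "window_bp": config.window_bp,
            "ind_lod_min": config.ind_lod_min,
            "max_missing": config.max_missing,
            "lod_threshold": config.lod_threshold,
            "kw_alpha": config.kw_alpha,
            "tol_cM": config.tol_cM,
            "sim": config.sim.to_dict(),
        },
        "artifacts": artifacts,
        "digests": {name: _digest(outdir / rel) for name, rel in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _bin_scaffold_frame(bins, gmap, marker_scaffolds: pd.DataFrame) -> pd.DataFrame:
    """Assign each mapped bin a scaffold and scaffold-local position via its
    member-SNP midpoint."""
    pos_map = gmap.marker_positions()
    mk = marker_scaffolds.set_index(["chrom", "pos"])
    rows = []
    for i in range(len(bins)):
        rec = bins.df.iloc[i]
        if rec["id"] not in pos_map:
            continue
        lg, cm = pos_map[rec["id"]]
        mid = (int(rec["start"]) + int(rec["end"])) // 2
        sub = marker_scaffolds[marker_scaffolds["chrom"] == rec["chrom"]]
        if len(sub) == 0:
            continue
        j = int(np.argmin(np.abs(sub["pos"].to_numpy() - mid)))
        rows.append({
            "id": rec["id"], "lg": lg, "cM": cm,
            "scaffold": sub["scaffold"].iloc[j],
            "scaf_pos": int(sub["scaf_pos"].iloc[j]),
        })
    return pd.DataFrame(rows)
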