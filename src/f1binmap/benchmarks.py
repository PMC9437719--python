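"""Self-validation benchmarks on synthetic populations.

Each routine regenerates data under the reference conditions (176 progeny,
1% genotyping error, 5% missing calls unless stated), runs the relevant
pipeline stages and measures recovery against the simulation ground truth.
They back both the acceptance checks and ad-hoc sanity runs; all randomness
derives from an explicit base seed.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats as sstats

from . import qtlscan, synteny
from .binning import make_bins
from .linkage import build_parental_maps, merge_consensus
from .segtype import SiteTable, filter_sites
from .simdata import (SimConfig, fragment_genome, marker_scaffold_positions,
                      simulate_population, simulate_traits)


def derive_seed(base_seed: int, tag: str, k: int = 0) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(tag.encode()) + 7919 * k) % (2 ** 31)


def build_mapped_population(seed, n_chrom=3, snps_per_chrom=250, chrom_len_bp=10_000_000,
                            chrom_len_cM=80.0, error_rate=0.01, missing_rate=0.05,
                            n_progeny=176, min_joint=20):
    """simulate -> mask -> classify -> filter -> bin -> parental + consensus maps."""
    cfg = SimConfig(n_progeny=n_progeny, n_chrom=n_chrom, snps_per_chrom=snps_per_chrom,
                    chrom_len_bp=chrom_len_bp, chrom_len_cM=chrom_len_cM,
                    error_rate=error_rate, missing_rate=missing_rate, seed=seed)
    pop, truth = simulate_population(cfg)
    table = SiteTable.from_population(pop).mask_low_confidence().classify().segregation_test()
    kept, _ = filter_sites(table)
    bins = make_bins(kept)
    maternal, paternal = build_parental_maps(bins, min_joint=min_joint)
    consensus = merge_consensus(maternal, paternal, bins, min_joint=min_joint)
    return {"cfg": cfg, "truth": truth, "kept": kept, "bins": bins,
            "maternal": maternal, "paternal": paternal, "consensus": consensus}


def map_recovery(base_seed: int = 0, n_seeds: int = 10, n_chrom: int = 3):
    """Group-count and marker-order recovery on noisy simulations.

    Returns per-seed consensus group counts and the minimum absolute
    Spearman correlation between estimated order and true physical order
    over every linkage group of every seed.
    """
    group_counts, rhos = [], []
    for k in range(n_seeds):
        run = build_mapped_population(derive_seed(base_seed, "map_recovery", k),
                                      n_chrom=n_chrom)
        cons = run["consensus"]
        group_counts.append(len(cons.groups))
        meta = run["bins"].df.set_index("id")
        for g in cons.groups:
            if len(g) < 5:
                continue
            phys = [meta.loc[m, "start"] for m in g.markers]
            rhos.append(abs(sstats.spearmanr(phys, g.positions).statistic))
    return {"group_counts": group_counts, "min_abs_spearman": float(np.min(rhos)),
            "mean_abs_spearman": float(np.mean(rhos)), "n_groups_expected": n_chrom}


def _true_peak_position(run, chrom_index, trait_truth):
    """Map position of the bin nearest the planted QTL marker."""
    truth = run["truth"]
    qtl = trait_truth.qtls[0]
    qpos = truth.positions[chrom_index][qtl.marker_index]
    chrom = truth.chrom_names[chrom_index]
    posmap = run["consensus"].marker_positions()
    best = None
    for i in range(len(run["bins"])):
        rec = run["bins"].df.iloc[i]
        if rec["chrom"] != chrom or rec["id"] not in posmap:
            continue
        d = 0 if rec["start"] <= qpos <= rec["end"] else min(
            abs(rec["start"] - qpos), abs(rec["end"] - qpos))
        if best is None or d < best[0]:
            best = (d, posmap[rec["id"]])
    return best[1] if best else (None, None)


def qtl_power(base_seed: int = 0, n_replicates: int = 50, pve: float = 0.2,
              tol_cM: float = 10.0, n_chrom: int = 3):
    """Fraction of replicates where a planted QTL is detected (LOD >= 2.5)
    within ``tol_cM`` of its map-projected true position."""
    hits = 0
    for k in range(n_replicates):
        run = build_mapped_population(derive_seed(base_seed, "qtl_power", k),
                                      n_chrom=n_chrom)
        rng = np.random.default_rng(derive_seed(base_seed, "qtl_power_trait", k))
        values, tt = simulate_traits(run["truth"], [(0, 40.0, [0, 0, 1, 1], pve)], rng=rng)
        grids = qtlscan.transmission_probs(run["consensus"], run["bins"])
        res = qtlscan.interval_mapping(values, grids)
        lg_true, cm_true = _true_peak_position(run, 0, tt)
        hits += any(p.lg == lg_true and abs(p.cM - cm_true) <= tol_cM for p in res.peaks)
    return hits / n_replicates


def qtl_null_calibration(base_seed: int = 0, n_replicates: int = 100, n_chrom: int = 5,
                         n_populations: int = 10):
    """Fraction of genome scans of pure-noise traits whose maximum LOD
    reaches the fixed 2.5 threshold, plus the observed max-LOD quantiles."""
    per_pop = n_replicates // n_populations
    maxima = []
    for p in range(n_populations):
        run = build_mapped_population(derive_seed(base_seed, "qtl_null_pop", p),
                                      n_chrom=n_chrom)
        grids = qtlscan.transmission_probs(run["consensus"], run["bins"])
        rng = np.random.default_rng(derive_seed(base_seed, "qtl_null_trait", p))
        for _ in range(per_pop):
            y = rng.normal(size=run["cfg"].n_progeny)
            maxima.append(qtlscan.interval_mapping(y, grids,
                                                   lod_threshold=np.inf).frame["lod"].max())
    maxima = np.asarray(maxima)
    return {"exceed_fraction": float((maxima >= 2.5).mean()),
            "q50": float(np.quantile(maxima, 0.5)),
            "q95": float(np.quantile(maxima, 0.95)),
            "n": len(maxima)}


def kw_null_rate(base_seed: int = 0, n_traits: int = 10, alpha: float = 0.005):
    """Fraction of marker tests passing the strict Kruskal-Wallis threshold
    for pure-noise traits (nominal rate = alpha)."""
    run = build_mapped_population(derive_seed(base_seed, "kw_null", 0), n_chrom=5)
    rng = np.random.default_rng(derive_seed(base_seed, "kw_null_trait", 0))
    passed = total = 0
    for _ in range(n_traits):
        y = rng.normal(size=run["cfg"].n_progeny)
        kw = qtlscan.kw_scan(y, run["bins"], alpha=alpha)
        passed += int(kw["significant"].sum())
        total += len(kw)
    return {"rate": passed / total, "n_tests": total}


def anchoring_recovery(base_seed: int = 0, n_seeds: int = 10, n_scaffolds: int = 50,
                       misassign_rate: float = 0.2, n_chrom: int = 5):
    """Scaffold re-anchoring from an error-free map on a fragmented genome
    with a partly misassigned reference; plus the exact-AGP check."""
    accs = []
    for k in range(n_seeds):
        cfg = SimConfig(n_chrom=n_chrom, snps_per_chrom=300, chrom_len_bp=10_000_000,
                        error_rate=0.0, missing_rate=0.0,
                        seed=derive_seed(base_seed, "anchor", k))
        pop, truth = simulate_population(cfg)
        layout, ref, _ = fragment_genome(
            truth, n_scaffolds, misassign_rate, min_markers_per_scaffold=3,
            rng=np.random.default_rng(derive_seed(base_seed, "anchor_frag", k)))
        mk = marker_scaffold_positions(truth, layout)
        mk["lg"] = mk["chrom"].str.replace("Chr", "LG")
        anchors, _ = synteny.anchor_scaffolds(
            [mk[["marker", "lg", "cM", "scaffold", "scaf_pos"]]],
            layout[["scaffold", "length"]])
        accs.append(synteny.anchoring_accuracy(anchors, layout))

    cfg = SimConfig(n_chrom=3, snps_per_chrom=200, chrom_len_bp=10_000_000,
                    error_rate=0.0, missing_rate=0.0,
                    seed=derive_seed(base_seed, "anchor_exact", 0))
    pop, truth = simulate_population(cfg)
    layout, _, true_agp = fragment_genome(truth, 12, 0.0, min_markers_per_scaffold=3)
    mk = marker_scaffold_positions(truth, layout)
    mk["lg"] = mk["chrom"].str.replace("Chr", "LG")
    _, agp = synteny.anchor_scaffolds(
        [mk[["marker", "lg", "cM", "scaffold", "scaf_pos"]]],
        layout[["scaffold", "length"]])
    exact = synteny.agp_matches(agp, true_agp)
    return {"base_accuracy": accs, "mean_base_accuracy": float(np.mean(accs)),
            "error_free_exact": bool(exact)}


def heritability_recovery(base_seed: int = 0, n_seeds: int = 50, h2: float = 0.5,
                          n_chrom: int = 3):
    """REML heritability estimates for traits with a planted polygenic h2."""
    ests = []
    for k in range(n_seeds):
        cfg = SimConfig(n_chrom=n_chrom, snps_per_chrom=250, chrom_len_bp=10_000_000,
                        seed=derive_seed(base_seed, "h2", k))
        pop, truth = simulate_population(cfg)
        table = SiteTable.from_population(pop).mask_low_confidence().classify().segregation_test()
        kept, _ = filter_sites(table)
        bins = make_bins(kept)
        rng = np.random.default_rng(derive_seed(base_seed, "h2_trait", k))
        values, _ = simulate_traits(truth, [], h2_polygenic=h2, rng=rng)
        ests.append(qtlscan.heritability(bins, values).h2)
    return ests


def ordering_oracle(base_seed: int = 0, n_instances: int = 100, n_markers: int = 5,
                    brute_force=None):
    """Fraction of noise-free instances where the greedy+2-opt ordering
    attains the exhaustive-search optimum of the same objective.

    ``brute_force(d, w, objective)`` must be an independent exhaustive
    minimiser (kept outside the package so the check stays dual-route).
    """
    from .linkage import kosambi, kosambi_inverse, order_group, ordering_objective

    if brute_force is None:
        raise ValueError("an independent brute-force minimiser is required")
    rng = np.random.default_rng(derive_seed(base_seed, "ordering", 0))
    wins = 0
    for _ in range(n_instances):
        pos = np.sort(rng.uniform(0, 50.0, size=n_markers))
        d_cm = np.abs(pos[:, None] - pos[None, :])
        r = kosambi_inverse(d_cm)
        lod = np.full((n_markers, n_markers), 20.0)
        np.fill_diagonal(lod, 0.0)
        order, _, _ = order_group(r, lod, min_lod=1.0)
        d = kosambi(np.clip(r, 0, 0.49))
        achieved = ordering_objective(list(order), d, lod)
        best = brute_force(d, lod, ordering_objective)
        wins += achieved <= best + 1e-9
    return wins / n_instances
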