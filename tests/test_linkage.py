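import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import f1binmap as fb
from f1binmap.linkage import (GeneticMap, LinkageGroup, estimate_rf, estimate_rf_bulk,
                              group_markers, independence_lod_matrix, kosambi,
                              kosambi_inverse, map_summary, merge_consensus, order_group,
                              ordering_objective, rf_matrix)
from .conftest import build_pipeline


class TestMapFunctions:
    def test_kosambi_zero_and_quarter(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), abs=1e-9)
        assert kosambi(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_kosambi_rejects_free_recombination(self):
        with pytest.raises(ValueError):
            kosambi(0.5)

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_identity(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_haldane_round_trip(self):
        from f1binmap.linkage import haldane, haldane_inverse

        assert haldane_inverse(haldane(0.2)) == pytest.approx(0.2, abs=1e-12)


class TestEstimateRf:
    def test_identical_vectors_give_zero_r_large_lod(self, rng):
        codes = rng.integers(0, 2, size=176).astype(np.int8)
        est = estimate_rf(codes, codes, "lmxll", "lmxll")
        assert est.r == pytest.approx(0.0, abs=1e-9)
        assert est.lod > 20
        assert est.phase[0] == "coupling"

    def test_two_mismatches_in_eight(self):
        c1 = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
        c2 = np.array([1, 1, 1, 0, 0, 0, 0, 1], dtype=np.int8)
        est = estimate_rf(c1, c2, "lmxll", "lmxll", min_joint=1)
        assert est.r == pytest.approx(0.25, abs=1e-6)
        assert est.phase[0] == "coupling"

    def test_repulsion_phase_detected(self, rng):
        codes = rng.integers(0, 2, size=176).astype(np.int8)
        est = estimate_rf(codes, 1 - codes, "lmxll", "lmxll")
        assert est.r == pytest.approx(0.0, abs=1e-9)
        assert est.phase[0] == "repulsion"

    def test_disjoint_parental_information_unusable(self, rng):
        c1 = rng.integers(0, 2, size=176).astype(np.int8)
        c2 = rng.integers(0, 2, size=176).astype(np.int8)
        est = estimate_rf(c1, c2, "lmxll", "nnxnp")
        assert not est.usable
        assert np.isnan(est.r)
        assert est.ind_lod < 2

    def test_symmetry_and_range_on_simulated_pairs(self, small_run):
        bins = small_run["bins"]
        seg = bins.df["seg_set"].to_numpy()
        idx = rngpairs = np.arange(min(30, len(bins)))
        ii, jj = np.triu_indices(len(idx), k=1)
        fwd = estimate_rf_bulk(bins.codes[idx], seg[idx], ii, jj)
        rev = estimate_rf_bulk(bins.codes[idx], seg[idx], jj, ii)
        ok = fwd["usable"] & rev["usable"]
        assert np.allclose(fwd["r"][ok], rev["r"][ok], atol=1e-4)
        assert ((fwd["r"][ok] >= 0) & (fwd["r"][ok] <= 0.5)).all()

    def test_hk_pair_recovers_known_r(self, rng):
        # construct an hkxhk pair from known gametes at r = 0.1, n large
        n = 3000
        am1 = rng.integers(0, 2, size=n)
        ap1 = rng.integers(0, 2, size=n)
        am2 = np.where(rng.random(n) < 0.1, 1 - am1, am1)
        ap2 = np.where(rng.random(n) < 0.1, 1 - ap1, ap1)
        c1 = (am1 + ap1).astype(np.int8)
        c2 = (am2 + ap2).astype(np.int8)
        est = estimate_rf(c1, c2, "hkxhk", "hkxhk")
        assert est.r == pytest.approx(0.1, abs=0.02)

    def test_insufficient_joint_observations_flagged(self):
        c = np.array([1, 0, 1], dtype=np.int8)
        est = estimate_rf(c, c, "lmxll", "lmxll", min_joint=20)
        assert not est.usable


class TestGrouping:
    def test_two_error_free_chromosomes_give_two_groups(self):
        run = build_pipeline(seed=13, n_chrom=2, snps_per_chrom=200,
                             error_rate=0.0, missing_rate=0.0, with_maps=False, mask=False)
        bins = run["bins"]
        seg = bins.df["seg_set"].to_numpy()
        mat = np.flatnonzero((seg == "lmxll") | (seg == "hkxhk"))
        groups, excluded, ladder = group_markers(bins.codes[mat], seg[mat])
        big = [g for g in groups if len(g) > 1]
        assert len(big) == 2
        chroms = bins.df["chrom"].to_numpy()[mat]
        for g in big:
            assert len(set(chroms[g])) == 1

    def test_missing_count_boundary_excludes_markers(self, rng):
        codes = rng.integers(0, 2, size=(4, 176)).astype(np.int8)
        codes[0, :9] = -1   # exactly 9 missing: kept
        codes[1, :10] = -1  # ten missing: excluded
        groups, excluded, _ = group_markers(codes, ["lmxll"] * 4, max_missing=9)
        assert list(excluded) == [1]

    def test_unlinked_markers_become_singletons(self, rng):
        codes = rng.integers(0, 2, size=(5, 176)).astype(np.int8)
        groups, excluded, _ = group_markers(codes, ["lmxll"] * 5, ind_lod_min=9)
        assert len(groups) == 5
        assert all(len(g) == 1 for g in groups)

    def test_ladder_reports_thresholds_two_to_thirty(self, rng):
        codes = rng.integers(0, 2, size=(4, 176)).astype(np.int8)
        _, _, ladder = group_markers(codes, ["lmxll"] * 4)
        assert list(ladder["ind_lod_min"]) == list(range(2, 31))


class TestOrdering:
    def _instance(self, rng, m=5, span=50.0):
        pos = np.sort(rng.uniform(0, span, size=m))
        d = np.abs(pos[:, None] - pos[None, :])
        r = kosambi_inverse(d)
        lod = np.full((m, m), 20.0)
        np.fill_diagonal(lod, 0.0)
        return pos, r, lod

    def test_noise_free_five_markers_recover_truth_up_to_reversal(self, rng):
        pos, r, lod = self._instance(rng)
        order, positions, warn = order_group(r, lod, min_lod=1.0)
        assert list(order) in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])
        assert not warn

    def test_two_marker_group_length_is_kosambi_distance(self):
        r = np.array([[0.0, 0.2], [0.2, 0.0]])
        lod = np.array([[0.0, 10.0], [10.0, 0.0]])
        order, positions, _ = order_group(r, lod, min_lod=1.0)
        assert positions[-1] == pytest.approx(kosambi(0.2))

    def test_heuristic_attains_bruteforce_optimum_on_noise_free_instances(self, rng):
        from .oracles import brute_force_best_order

        wins = 0
        for _ in range(30):
            pos, r, lod = self._instance(rng)
            order, _, _ = order_group(r, lod, min_lod=1.0)
            achieved = ordering_objective(list(order), kosambi(np.clip(r, 0, 0.49)), lod)
            best = brute_force_best_order(kosambi(np.clip(r, 0, 0.49)), lod, ordering_objective)
            wins += achieved <= best + 1e-9
        assert wins >= 29

    def test_simulated_group_order_matches_truth(self, small_run):
        meta = small_run["bins"].df.set_index("id")
        for g in small_run["consensus"].groups:
            phys = [meta.loc[m, "start"] for m in g.markers]
            rho = stats.spearmanr(phys, g.positions).statistic
            assert abs(rho) >= 0.95


class TestParentalAndConsensusMaps:
    def test_lm_only_simulation_leaves_paternal_map_empty(self, rng):
        cfg = fb.SimConfig(n_chrom=1, snps_per_chrom=120, chrom_len_bp=5_000_000,
                           seg_type_mix={"lmxll": 1.0, "nnxnp": 0.0, "hkxhk": 0.0},
                           error_rate=0.0, missing_rate=0.0, seed=17)
        run_pop, truth = fb.simulate_population(cfg)
        from f1binmap.segtype import SiteTable

        t = SiteTable.from_population(run_pop).classify().segregation_test()
        kept, _ = fb.filter_sites(t)
        bins = fb.make_bins(kept)
        maternal, paternal = fb.build_parental_maps(bins)
        assert len(paternal.groups) == 0
        assert sum(len(g) for g in maternal.groups) == len(bins)

    def test_error_free_group_count_matches_chromosomes(self):
        run = build_pipeline(seed=19, n_chrom=2, snps_per_chrom=250,
                             error_rate=0.0, missing_rate=0.0, mask=False)
        assert len(run["maternal"].groups) == 2
        assert len(run["paternal"].groups) == 2

    def test_hk_only_maps_share_group_membership(self):
        cfg = fb.SimConfig(n_chrom=2, snps_per_chrom=150, chrom_len_bp=5_000_000,
                           seg_type_mix={"lmxll": 0.0, "nnxnp": 0.0, "hkxhk": 1.0},
                           error_rate=0.0, missing_rate=0.0, seed=23)
        pop, _ = fb.simulate_population(cfg)
        from f1binmap.segtype import SiteTable

        t = SiteTable.from_population(pop).classify().segregation_test()
        kept, _ = fb.filter_sites(t)
        bins = fb.make_bins(kept)
        maternal, paternal = fb.build_parental_maps(bins)
        mat_sets = {frozenset(g.markers) for g in maternal.groups}
        pat_sets = {frozenset(g.markers) for g in paternal.groups}
        assert mat_sets == pat_sets

    def test_identical_parental_groups_merge_to_themselves(self):
        mg = LinkageGroup("LG1", ["a", "b", "c"], np.array([0.0, 10.0, 30.0]),
                          "maternal", np.ones(3))
        pg = LinkageGroup("LG1", ["a", "b", "c"], np.array([0.0, 10.0, 30.0]),
                          "paternal", np.ones(3))
        cons = merge_consensus(GeneticMap("maternal", [mg]), GeneticMap("paternal", [pg]))
        g = cons.groups[0]
        assert g.markers == ["a", "b", "c"]
        assert np.allclose(g.positions, [0.0, 10.0, 30.0])

    def test_bridge_projection_by_linear_interpolation(self):
        # bridges at (0,0) and (50,60); a maternal-only marker midway lands
        # at 30 on the consensus scale (longer bridge interval wins)
        mg = LinkageGroup("LG1", ["b1", "m", "b2"], np.array([0.0, 25.0, 50.0]),
                          "maternal", np.ones(3))
        pg = LinkageGroup("LG1", ["b1", "b2"], np.array([0.0, 60.0]), "paternal", np.ones(2))
        cons = merge_consensus(GeneticMap("maternal", [mg]), GeneticMap("paternal", [pg]))
        g = cons.groups[0]
        assert dict(zip(g.markers, g.positions))["m"] == pytest.approx(30.0)

    def test_no_bridges_falls_back_to_joint_regroup(self):
        run = build_pipeline(seed=29, n_chrom=1, snps_per_chrom=200)
        bins = run["bins"]
        maternal, paternal = run["maternal"], run["paternal"]
        # drop shared markers from the maternal group to force the fallback
        shared = set(maternal.groups[0].markers) & set(paternal.groups[0].markers)
        mg = maternal.groups[0]
        keep = [k for k, mk in enumerate(mg.markers) if mk not in shared]
        stripped = LinkageGroup(mg.id, [mg.markers[k] for k in keep],
                                mg.positions[keep] - mg.positions[keep[0]],
                                "maternal", mg.weights[keep])
        cons = merge_consensus(GeneticMap("maternal", [stripped]), paternal, bins)
        g = cons.groups[0]
        assert set(g.markers) == set(stripped.markers) | set(paternal.groups[0].markers)
        assert any("re-grouped union" in w for w in g.warnings)

    def test_unpaired_group_carried_with_warning(self):
        mg = LinkageGroup("LG9", ["a", "b"], np.array([0.0, 5.0]), "maternal", np.ones(2))
        cons = merge_consensus(GeneticMap("maternal", [mg]), GeneticMap("paternal", []))
        assert cons.groups[0].markers == ["a", "b"]
        assert any("no counterpart" in w for w in cons.groups[0].warnings)

    def test_consensus_contains_every_parental_marker_once(self, small_run):
        cons = small_run["consensus"]
        names = [m for g in cons.groups for m in g.markers]
        assert len(names) == len(set(names))
        parental = {m for g in small_run["maternal"].groups for m in g.markers}
        parental |= {m for g in small_run["paternal"].groups for m in g.markers}
        assert set(names) == parental


class TestMapSummary:
    def _group(self, lg, n, length):
        pos = np.linspace(0.0, length, n)
        return LinkageGroup(lg, [f"{lg}_m{i}" for i in range(n)], pos, "consensus")

    def test_published_style_interval_arithmetic(self):
        # 81 markers over 87.0 cM -> 1.09; 17 groups, 3190 markers,
        # 1358.5 cM total -> 0.43
        g6 = self._group("LG6", 81, 87.0)
        df = map_summary(GeneticMap("consensus", [g6]))
        assert df.loc[df["lg"] == "LG6", "avg_interval_cM"].iloc[0] == pytest.approx(1.0875, abs=1e-4)
        assert round(float(df.loc[df["lg"] == "LG6", "avg_interval_cM"].iloc[0]), 2) == 1.09

        per_lg = 3190 // 17
        lengths = [1358.5 / 17] * 17
        groups = [self._group(f"LG{i+1}", per_lg + (1 if i < 3190 % 17 else 0), lengths[i])
                  for i in range(17)]
        df = map_summary(GeneticMap("consensus", groups))
        avg = df.loc[df["lg"] == "Average", "avg_interval_cM"].iloc[0]
        assert round(float(avg), 2) == 0.43

    def test_two_markers_interval_is_their_distance(self):
        df = map_summary(GeneticMap("consensus", [self._group("LG1", 2, 10.0)]))
        assert df["avg_interval_cM"].iloc[0] == pytest.approx(10.0)

    def test_singleton_group_interval_undefined(self):
        g = LinkageGroup("LG1", ["a"], np.array([0.0]), "consensus")
        df = map_summary(GeneticMap("consensus", [g]))
        assert np.isnan(df["avg_interval_cM"].iloc[0])


class TestRfHeatmap:
    def test_block_structure_sits_on_the_diagonal(self, small_run):
        cons, bins = small_run["consensus"], small_run["bins"]
        sub_groups = [LinkageGroup(g.id, g.markers[:10], g.positions[:10] - g.positions[0],
                                   g.kind) for g in cons.groups]
        mat = rf_matrix(GeneticMap("consensus", sub_groups), bins)
        vals = mat.to_numpy()
        lgs = np.repeat([g.id for g in sub_groups], [len(g.markers) for g in sub_groups])
        same = vals[(lgs[:, None] == lgs[None, :]) & np.isfinite(vals) & ~np.eye(len(vals), dtype=bool)]
        diff = vals[(lgs[:, None] != lgs[None, :]) & np.isfinite(vals)]
        assert np.nanmean(same) < np.nanmean(diff)
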