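import numpy as np
import pandas as pd
import pytest

import f1binmap as fb
from f1binmap import synteny
from f1binmap.simdata import marker_scaffold_positions


def snp_row(marker, lg, scaffold, pos, cm=0.0):
    return {"marker": marker, "lg": lg, "cM": cm, "scaffold": scaffold, "scaf_pos": pos}


def bin_row(bid, lg, scaffold, start, end, cm=0.0):
    return {"id": bid, "lg": lg, "cM": cm, "scaffold": scaffold, "start": start, "end": end}


class TestSbp:
    def test_snp_inside_bin_span_pairs_within_bin(self):
        snps = pd.DataFrame([snp_row("s1", "LG1", "scf1", 1500)])
        bins = pd.DataFrame([bin_row("b1", "LG1", "scf1", 1000, 2000)])
        sbps, unpaired = synteny.find_sbps(snps, bins)
        assert sbps["relation"].iloc[0] == "within_bin"
        assert unpaired == 0

    def test_disjoint_span_on_shared_scaffold_pairs_same_scaffold(self):
        snps = pd.DataFrame([snp_row("s1", "LG1", "scf1", 5000)])
        bins = pd.DataFrame([bin_row("b1", "LG2", "scf1", 1000, 2000)])
        sbps, _ = synteny.find_sbps(snps, bins)
        assert sbps["relation"].iloc[0] == "same_scaffold"
        assert not sbps["concordant"].iloc[0]

    def test_snp_without_bins_on_scaffold_is_unpaired(self):
        snps = pd.DataFrame([snp_row("s1", "LG1", "lonely", 100)])
        bins = pd.DataFrame([bin_row("b1", "LG1", "scf1", 1000, 2000)])
        sbps, unpaired = synteny.find_sbps(snps, bins)
        assert unpaired == 1 and len(sbps) == 0

    def test_published_concordance_fraction(self):
        # 7289 concordant of 7899 SBPs -> 92.3%
        frame = pd.DataFrame({"concordant": [True] * 7289 + [False] * (7899 - 7289)})
        assert round(synteny.sbp_concordance(frame), 1) == 92.3

    def test_all_concordant_is_hundred_percent(self):
        frame = pd.DataFrame({"concordant": [True] * 10})
        assert synteny.sbp_concordance(frame) == 100.0

    def test_shuffled_group_labels_drop_to_chance(self, rng):
        n_lg = 5
        rows = []
        for i in range(1000):
            lg = f"LG{rng.integers(1, n_lg + 1)}"
            rows.append(snp_row(f"s{i}", lg, f"scf{i}", 500))
        snps = pd.DataFrame(rows)
        bins = pd.DataFrame([
            bin_row(f"b{i}", f"LG{rng.integers(1, n_lg + 1)}", f"scf{i}", 1, 1000)
            for i in range(1000)
        ])
        sbps, _ = synteny.find_sbps(snps, bins)
        pct = synteny.sbp_concordance(sbps)
        assert abs(pct - 100.0 / n_lg) < 5.0


class TestCollinearityTable:
    @pytest.mark.parametrize("co,mis,expected", [
        (23, 23, 50.0),   # published group-1 counts
        (89, 8, 91.8),    # published group-12 counts
        (1523, 383, 79.9),  # published totals
        (5, 0, 100.0),
    ])
    def test_collinearity_formula(self, co, mis, expected):
        assert round(synteny.collinearity_percent(co, mis), 1) == expected

    def test_classification_partitions_markers(self):
        map_frame = pd.DataFrame([
            {"marker": "a", "lg": "LG1", "scaffold": "s1"},
            {"marker": "b", "lg": "LG1", "scaffold": "s1"},
            {"marker": "c", "lg": "LG1", "scaffold": "s2"},
            {"marker": "d", "lg": "LG1", "scaffold": "s3"},
        ])
        ref = pd.DataFrame({"scaffold": ["s1", "s2", "s3"],
                            "chrom": ["Chr1", "Chr2", None]})
        table = synteny.classify_vs_reference(map_frame, ref)
        row = table[table["lg"] == "LG1"].iloc[0]
        assert row["co_anchored"] + row["misaligned"] + row["new_anchored"] == row["n_markers"]
        assert row["co_anchored"] == 2 and row["misaligned"] == 1 and row["new_anchored"] == 1
        assert row["pct_collinearity"] == pytest.approx(100 * 2 / 3)

    def test_correspondence_uses_majority_chromosome(self):
        rows = [{"marker": f"m{i}", "lg": "LG1", "scaffold": f"s{i}"} for i in range(5)]
        ref = pd.DataFrame({"scaffold": [f"s{i}" for i in range(5)],
                            "chrom": ["Chr7", "Chr7", "Chr7", "Chr1", "Chr1"]})
        table = synteny.classify_vs_reference(pd.DataFrame(rows), ref)
        row = table[table["lg"] == "LG1"].iloc[0]
        assert row["chrom"] == "Chr7"
        assert row["co_anchored"] == 3


class TestAnchoring:
    def _markers(self, scaffold, lg, cms, bps):
        return pd.DataFrame([
            snp_row(f"{scaffold}_m{i}", lg, scaffold, bp, cm)
            for i, (cm, bp) in enumerate(zip(cms, bps))
        ])

    def test_increasing_cm_with_bp_is_plus_orientation(self):
        mk = self._markers("scf1", "LG1", [1.0, 2.0, 3.0], [100, 200, 300])
        layout = pd.DataFrame({"scaffold": ["scf1"], "length": [1000]})
        anchors, agp = synteny.anchor_scaffolds([mk], layout)
        assert anchors["orientation"].iloc[0] == "+"

    def test_reversed_bp_order_is_minus_orientation(self):
        mk = self._markers("scf1", "LG1", [1.0, 2.0, 3.0], [300, 200, 100])
        layout = pd.DataFrame({"scaffold": ["scf1"], "length": [1000]})
        anchors, _ = synteny.anchor_scaffolds([mk], layout)
        assert anchors["orientation"].iloc[0] == "-"

    def test_single_position_gives_unknown_orientation_flagged(self):
        mk = self._markers("scf1", "LG1", [1.0], [100])
        layout = pd.DataFrame({"scaffold": ["scf1"], "length": [1000]})
        anchors, agp = synteny.anchor_scaffolds([mk], layout)
        assert anchors["orientation"].iloc[0] == "?"
        assert anchors["flag"].iloc[0] == "ambiguous orientation"
        assert agp[agp["component_type"] == "W"]["orient_or_evidence"].iloc[0] == "+"

    def test_two_marker_runs_split_scaffold_between_groups(self):
        mk = pd.concat([
            self._markers("scf1", "LG1", [1.0, 2.0], [100, 200]),
            self._markers("scf1", "LG2", [5.0, 6.0], [800, 900]),
        ], ignore_index=True)
        layout = pd.DataFrame({"scaffold": ["scf1"], "length": [1000]})
        anchors, _ = synteny.anchor_scaffolds([mk], layout)
        assert len(anchors) == 2
        assert set(anchors["lg"]) == {"LG1", "LG2"}
        assert anchors["length"].sum() == 1000

    def test_markerless_scaffold_left_unplaced(self):
        mk = self._markers("scf1", "LG1", [1.0, 2.0], [100, 200])
        layout = pd.DataFrame({"scaffold": ["scf1", "scf2"], "length": [1000, 500]})
        anchors, _ = synteny.anchor_scaffolds([mk], layout)
        empty = anchors[anchors["scaffold"] == "scf2"].iloc[0]
        assert empty["lg"] is None and empty["flag"] == "no markers"
        placed, pct = synteny.assembly_stats(anchors, 1500)
        assert placed == 1000 and pct == pytest.approx(100 * 1000 / 1500)

    def test_fragmented_simulation_recovers_placement_and_orientation(self):
        accs = []
        for seed in range(10):
            cfg = fb.SimConfig(n_chrom=5, snps_per_chrom=300, chrom_len_bp=10_000_000,
                               chrom_len_cM=80.0, error_rate=0.0, missing_rate=0.0,
                               seed=800 + seed)
            pop, truth = fb.simulate_population(cfg)
            layout, ref, _ = fb.fragment_genome(truth, 50, 0.2, min_markers_per_scaffold=3,
                                                rng=np.random.default_rng(seed))
            mk = marker_scaffold_positions(truth, layout)
            mk["lg"] = mk["chrom"].str.replace("Chr", "LG")
            anchors, _ = synteny.anchor_scaffolds(
                [mk[["marker", "lg", "cM", "scaffold", "scaf_pos"]]],
                layout[["scaffold", "length"]])
            accs.append(synteny.anchoring_accuracy(anchors, layout))
        assert np.mean(accs) >= 0.95

    def test_second_map_only_increases_anchored_fraction(self):
        cfg = fb.SimConfig(n_chrom=3, snps_per_chrom=150, chrom_len_bp=10_000_000,
                           error_rate=0.0, missing_rate=0.0, seed=900)
        pop, truth = fb.simulate_population(cfg)
        layout, _, _ = fb.fragment_genome(truth, 30, 0.0, min_markers_per_scaffold=3)
        mk = marker_scaffold_positions(truth, layout)
        mk["lg"] = mk["chrom"].str.replace("Chr", "LG")
        half_a = mk[mk["scaffold"].isin(sorted(mk["scaffold"].unique())[:15])]
        half_b = mk[~mk["scaffold"].isin(half_a["scaffold"])]
        cols = ["marker", "lg", "cM", "scaffold", "scaf_pos"]
        one, _ = synteny.anchor_scaffolds([half_a[cols]], layout[["scaffold", "length"]])
        both, _ = synteny.anchor_scaffolds([half_a[cols], half_b[cols]],
                                           layout[["scaffold", "length"]])
        g = int(layout["length"].sum())
        assert synteny.assembly_stats(both, g)[1] > synteny.assembly_stats(one, g)[1]


class TestAgp:
    def _components(self):
        return [("Chr1", "scfA", 1000, "+"), ("Chr1", "scfB", 500, "-"),
                ("Chr2", "scfC", 800, "+")]

    def test_round_trip_is_lossless_and_valid(self, tmp_path):
        frame = synteny.build_agp_frame(self._components())
        synteny.validate_agp(frame)
        path = tmp_path / "test.agp"
        synteny.write_agp(frame, path, comment="round trip")
        back = synteny.read_agp(path)
        assert synteny.agp_components(back) == synteny.agp_components(frame)
        pd.testing.assert_frame_equal(
            back.astype(str).reset_index(drop=True), frame.astype(str))

    def test_gap_rows_alternate_with_fixed_length(self):
        frame = synteny.build_agp_frame(self._components())
        chr1 = frame[frame["object"] == "Chr1"]
        assert list(chr1["component_type"]) == ["W", "N", "W"]
        gap = chr1[chr1["component_type"] == "N"].iloc[0]
        assert (gap["id_or_length"], gap["beg_or_type"], gap["orient_or_evidence"]) == \
            (100, "scaffold", "map")

    def test_validation_rejects_noncontiguous_spans(self):
        frame = synteny.build_agp_frame(self._components())
        frame.loc[0, "object_end"] = 999
        with pytest.raises(ValueError):
            synteny.validate_agp(frame)

    def test_matching_up_to_whole_object_reversal(self):
        a = synteny.build_agp_frame([("Chr1", "x", 10, "+"), ("Chr1", "y", 20, "-")])
        b = synteny.build_agp_frame([("Chr1", "y", 20, "+"), ("Chr1", "x", 10, "-")])
        c = synteny.build_agp_frame([("Chr1", "y", 20, "-"), ("Chr1", "x", 10, "+")])
        assert synteny.agp_matches(a, b)
        assert not synteny.agp_matches(a, b, allow_reversal=False)
        assert not synteny.agp_matches(a, c)

    def test_error_free_anchoring_reproduces_true_agp(self):
        cfg = fb.SimConfig(n_chrom=3, snps_per_chrom=200, chrom_len_bp=10_000_000,
                           error_rate=0.0, missing_rate=0.0, seed=11)
        pop, truth = fb.simulate_population(cfg)
        layout, ref, true_agp = fb.fragment_genome(truth, 12, 0.0, min_markers_per_scaffold=3)
        mk = marker_scaffold_positions(truth, layout)
        mk["lg"] = mk["chrom"].str.replace("Chr", "LG")
        _, agp = synteny.anchor_scaffolds(
            [mk[["marker", "lg", "cM", "scaffold", "scaf_pos"]]],
            layout[["scaffold", "length"]])
        assert synteny.agp_matches(agp, true_agp)
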