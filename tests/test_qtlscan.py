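import numpy as np
import pandas as pd
import pytest
from scipy import stats

import f1binmap as fb
from f1binmap.binning import BinSet
from f1binmap.linkage import GeneticMap, LinkageGroup, kosambi_inverse
from f1binmap import qtlscan


def make_bins(codes, seg="lmxll", chrom="Chr1", starts=None):
    codes = np.asarray(codes, dtype=np.int8)
    m = len(codes)
    starts = starts if starts is not None else np.arange(m) * 1000 + 1
    df = pd.DataFrame({
        "id": [f"m{i}" for i in range(m)],
        "seg_set": [seg] * m if isinstance(seg, str) else list(seg),
        "chrom": [chrom] * m,
        "start": starts,
        "end": np.asarray(starts) + 500,
        "snp_count": np.ones(m, dtype=int),
        "family": np.zeros(m, dtype=int),
    })
    return BinSet(df=df, codes=codes, progeny_names=[f"F{j}" for j in range(codes.shape[1])])


class TestTraitStats:
    def test_adjusted_moments_on_small_sample(self):
        t = fb.trait_stats([1, 2, 3, 4, 5], name="toy")
        assert t.skewness == pytest.approx(0.0, abs=1e-12)
        assert t.kurtosis == pytest.approx(-1.2, abs=1e-9)

    def test_self_correlation_is_one(self):
        x = np.arange(10.0)
        t = fb.trait_stats(x, paired=x)
        assert t.pearson_r == pytest.approx(1.0)

    def test_identical_groups_give_zero_anova_f(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = fb.trait_stats(x, paired=x.copy())
        assert t.anova_f == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_flags_shapiro_undefined(self):
        t = fb.trait_stats([2.0, 2.0, 2.0, 2.0])
        assert np.isnan(t.shapiro_w)
        assert any("constant" in f for f in t.flags)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fb.trait_stats([1.0, np.nan, np.nan])


class TestTransform:
    def test_cubic_root(self):
        out, info = fb.transform_trait(np.array([8.0, 27.0]), "curt")
        assert out == pytest.approx([2.0, 3.0])

    def test_natural_log(self):
        out, info = fb.transform_trait(np.array([1.0, np.e, np.e ** 2]), "ln")
        assert out == pytest.approx([0.0, 1.0, 2.0])
        assert info["shift"] == 0.0

    def test_nonpositive_support_shifts_and_records(self):
        out, info = fb.transform_trait(np.array([-1.0, 0.0, 3.0]), "ln")
        assert info["shift"] > 0
        assert np.all(np.isfinite(out))

    def test_tukey_picks_log_for_lognormal(self, rng):
        picks = 0
        for _ in range(50):
            x = np.exp(rng.normal(size=120))
            _, info = fb.transform_trait(x, "tukey")
            picks += info["lambda"] == 0.0
        assert picks >= 45

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fb.transform_trait(np.array([1.0, 2.0, 3.0]), "boxcox")


class TestTransmissionProbs:
    def _map_and_bins(self, codes, seg, positions):
        bins = make_bins(codes, seg=seg)
        g = LinkageGroup("LG1", [f"m{i}" for i in range(len(codes))],
                         np.asarray(positions, dtype=float), "consensus")
        return GeneticMap("consensus", [g]), bins

    def test_fully_informative_marker_pins_the_class(self, rng):
        n = 60
        am = rng.integers(0, 2, size=n)
        ap = rng.integers(0, 2, size=n)
        codes = np.vstack([(am + ap), (am + ap)]).astype(np.int8)
        gmap, bins = self._map_and_bins(codes, "hkxhk", [0.0, 5.0])
        grids = qtlscan.transmission_probs(gmap, bins, eps=0.0)
        g = grids[0]
        k = int(np.argmin(np.abs(g.grid - 0.0)))
        hh = codes[0] == 0
        kk = codes[0] == 2
        # hh progeny: both transmitted alleles fixed -> one class carries mass 1
        assert np.allclose(g.probs[hh, k].max(axis=1), 1.0, atol=1e-6)
        assert np.allclose(g.probs[kk, k].max(axis=1), 1.0, atol=1e-6)

    def test_midpoint_two_point_conditional_probability(self):
        # two concordant fully informative maternal markers 20 cM apart:
        # P(same maternal state at the midpoint) =
        # (1-r)^2 / ((1-r)^2 + r^2) with r = inverse-Kosambi(10)
        n = 40
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, size=n).astype(np.int8)
        flip = rng.random(n) < 0.15  # some recombinants so phasing has signal
        codes = np.vstack([base, np.where(flip, 1 - base, base)]).astype(np.int8)
        gmap, bins = self._map_and_bins(codes, "lmxll", [0.0, 20.0])
        grids = qtlscan.transmission_probs(gmap, bins, eps=0.0, min_joint=10)
        g = grids[0]
        k = int(np.argmin(np.abs(g.grid - 10.0)))
        r = kosambi_inverse(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        concordant = codes[0] == codes[1]
        p_m = g.probs[:, k, 2] + g.probs[:, k, 3]  # P(maternal state B)
        observed = np.where(codes[0][concordant] == 1, p_m[concordant],
                            1 - p_m[concordant])
        assert np.allclose(observed, expected, atol=1e-6)

    def test_uninformative_paternal_meiosis_is_uniform(self, rng):
        codes = rng.integers(0, 2, size=(3, 50)).astype(np.int8)
        gmap, bins = self._map_and_bins(codes, "lmxll", [0.0, 10.0, 20.0])
        grids = qtlscan.transmission_probs(gmap, bins)
        g = grids[0]
        p_pat = g.probs[..., 1] + g.probs[..., 3]  # P(paternal state D)
        assert np.allclose(p_pat, 0.5, atol=1e-9)

    def test_probabilities_sum_to_one_everywhere(self, small_grids):
        for g in small_grids:
            assert np.allclose(g.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_unknown_marker_raises(self, rng):
        codes = rng.integers(0, 2, size=(2, 30)).astype(np.int8)
        bins = make_bins(codes)
        g = LinkageGroup("LG1", ["m0", "ghost"], np.array([0.0, 5.0]), "consensus")
        with pytest.raises(ValueError, match="absent"):
            qtlscan.transmission_probs(GeneticMap("consensus", [g]), bins)


class TestIntervalMapping:
    def test_deterministic_class_trait_peaks_at_marker_with_full_pve(self, rng):
        n = 176
        am = rng.integers(0, 2, size=n)
        ap = rng.integers(0, 2, size=n)
        m = 9
        codes = np.vstack([(am + ap)] * m).astype(np.int8)
        gmap, bins = (TestTransmissionProbs()._map_and_bins(codes, "hkxhk",
                                                            np.arange(m) * 5.0))
        grids = qtlscan.transmission_probs(gmap, bins, eps=0.0)
        # additive class function: hk-coded progeny (AD/BC ambiguous) share
        # the same trait value, so the association is fully capturable
        trait = (am + ap).astype(float)
        res = qtlscan.interval_mapping(trait, grids)
        assert res.peaks
        top = res.peaks[0]
        assert top.pve > 99.0
        assert top.interval_1lod[0] <= top.cM <= top.interval_1lod[1]

    def test_lod_invariant_to_affine_trait_transform(self, small_grids, rng):
        y = rng.normal(size=176)
        a = qtlscan.interval_mapping(y, small_grids).frame["lod"]
        b = qtlscan.interval_mapping(3.5 * y - 7.0, small_grids).frame["lod"]
        assert np.allclose(a, b, atol=1e-8)

    def test_support_intervals_nest_and_contain_peak(self, small_run, small_grids, rng):
        truth = small_run["truth"]
        vals, _ = fb.simulate_traits(truth, [(0, 40.0, [0, 0, 1, 1], 0.3)], rng=rng)
        res = qtlscan.interval_mapping(vals, small_grids)
        assert res.peaks
        for p in res.peaks:
            lo1, hi1 = p.interval_1lod
            lo2, hi2 = p.interval_2lod
            assert lo2 <= lo1 <= p.cM <= hi1 <= hi2

    def test_kw_and_interval_mapping_agree_on_strong_effect(self, small_run, small_grids, rng):
        truth, bins = small_run["truth"], small_run["bins"]
        vals, _ = fb.simulate_traits(truth, [(1, 40.0, [0, 0, 1, 1], 0.5)], rng=rng)
        res = qtlscan.interval_mapping(vals, small_grids)
        kw = qtlscan.kw_scan(vals, bins)
        top_peak = res.peaks[0]
        top_kw = kw.sort_values("pvalue").iloc[0]["marker"]
        lg, pos = small_run["consensus"].marker_positions()[top_kw]
        assert lg == top_peak.lg
        assert abs(pos - top_peak.cM) <= 10.0

    def test_constant_trait_rejected(self, small_grids):
        with pytest.raises(ValueError, match="constant"):
            qtlscan.interval_mapping(np.ones(176), small_grids)


class TestKwScan:
    def test_hand_computed_two_group_statistic(self):
        codes = np.array([[0, 0, 0, 1, 1, 1]], dtype=np.int8)
        bins = make_bins(codes)
        kw = qtlscan.kw_scan(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), bins)
        assert kw["H"].iloc[0] == pytest.approx(3.857, abs=1e-3)
        assert kw["df"].iloc[0] == 1

    def test_all_equal_values_guarded_to_zero(self):
        codes = np.array([[0, 0, 1, 1]], dtype=np.int8)
        bins = make_bins(codes)
        kw = qtlscan.kw_scan(np.array([2.0, 2.0, 2.0, 2.0]), bins)
        assert kw["H"].iloc[0] == 0.0
        assert kw["pvalue"].iloc[0] == 1.0

    def test_single_class_marker_skipped(self):
        codes = np.array([[1, 1, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        bins = make_bins(codes)
        kw = qtlscan.kw_scan(np.array([1.0, 2.0, 3.0, 4.0]), bins)
        assert list(kw["marker"]) == ["m1"]


class TestHeritability:
    def test_noise_free_genetic_trait_estimates_near_one(self, small_run, rng):
        vals, _ = fb.simulate_traits(small_run["truth"], [], h2_polygenic=1.0, rng=rng)
        est = fb.heritability(small_run["bins"], vals)
        assert est.h2 >= 0.95
        assert est.h2 == pytest.approx(est.sigma_g2 / (est.sigma_g2 + est.sigma_e2), abs=1e-9)

    def test_pure_noise_estimates_near_zero(self, small_run, rng):
        vals = rng.normal(size=176)
        est = fb.heritability(small_run["bins"], vals)
        assert est.h2 <= 0.1

    def test_requires_enough_progeny_and_markers(self, small_run):
        with pytest.raises(ValueError):
            fb.heritability(small_run["bins"], np.ones(176) * np.nan)


class TestStabilityAndPhysical:
    def _peak(self, lg, cm):
        return qtlscan.QtlPeak(lg=lg, cM=cm, lod=4.0, pve=10.0,
                               interval_1lod=(cm - 2, cm + 2), interval_2lod=(cm - 4, cm + 4))

    def _result(self, peaks):
        return qtlscan.QtlScanResult(frame=pd.DataFrame(), peaks=peaks)

    def test_same_position_matches_at_zero_delta(self):
        m = qtlscan.qtl_stability(self._result([self._peak("LG1", 20.0)]),
                                  self._result([self._peak("LG1", 20.0)]))
        assert len(m) == 1 and m[0][2] == 0.0

    def test_strict_ten_centimorgan_boundary(self):
        near = qtlscan.qtl_stability(self._result([self._peak("LG1", 10.0)]),
                                     self._result([self._peak("LG1", 19.9)]))
        far = qtlscan.qtl_stability(self._result([self._peak("LG1", 10.0)]),
                                    self._result([self._peak("LG1", 20.0)]))
        assert len(near) == 1 and len(far) == 0

    def test_different_groups_never_match(self):
        m = qtlscan.qtl_stability(self._result([self._peak("LG1", 10.0)]),
                                  self._result([self._peak("LG2", 10.0)]))
        assert m == []

    def test_overlapping_bin_spans_merge(self, rng):
        codes = rng.integers(0, 2, size=(2, 30)).astype(np.int8)
        bins = make_bins(codes, starts=[100_000, 150_000])
        bins.df.loc[0, "end"] = 200_000
        bins.df.loc[1, "end"] = 300_000
        g = LinkageGroup("LG1", ["m0", "m1"], np.array([0.0, 1.0]), "consensus")
        gmap = GeneticMap("consensus", [g])
        res = self._result([qtlscan.QtlPeak("LG1", 0.5, 5.0, 12.0, (0.0, 1.0), (0.0, 1.0))])
        out = qtlscan.qtl_to_physical(res, gmap, bins, drop=1)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (100_000, 300_000)

    def test_genes_intersecting_interval_reported(self, rng):
        codes = rng.integers(0, 2, size=(1, 30)).astype(np.int8)
        bins = make_bins(codes, starts=[100_000])
        bins.df.loc[0, "end"] = 200_000
        g = LinkageGroup("LG1", ["m0"], np.array([0.0]), "consensus")
        annotation = pd.DataFrame({
            "chrom": ["Chr1", "Chr1", "Chr2"],
            "start": [150_000, 500_000, 150_000],
            "end": [160_000, 510_000, 160_000],
            "gene_id": ["inQtl", "farAway", "wrongChrom"],
        })
        res = self._result([qtlscan.QtlPeak("LG1", 0.0, 5.0, 12.0, (0.0, 0.0), (0.0, 0.0))])
        out = qtlscan.qtl_to_physical(res, GeneticMap("consensus", [g]), bins,
                                      annotation=annotation)
        assert out["genes"].iloc[0] == "inQtl"

    def test_empty_interval_gives_empty_output(self):
        res = self._result([])
        out = qtlscan.qtl_to_physical(res, GeneticMap("consensus", []),
                                      make_bins(np.zeros((1, 4))))
        assert len(out) == 0
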