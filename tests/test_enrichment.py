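"""Colocalization statistics against per-base brute-force scans."""

import numpy as np
import pytest

from retromap import simulate as sim
from retromap.enrichment import (
    ChIPFeatureSet,
    categorize_by_tss,
    colocalize,
    enrichment_test,
    genome_fraction,
    midpoint_distance_profile,
    reduce_integration_set,
    sample_matched_random_features,
)
from retromap.intervals import merge_intervals, pad_intervals


class TestCategorizeByTSS:
    def test_boundary_conventions(self):
        # distances 0 and 868 immediate; 3,000 and 10,000 intermediate;
        # 10,001 distal
        tss = {"chr1": np.array([100_000])}
        ints = {"chr1": np.array([100_000, 100_868, 103_000, 110_000, 110_001])}
        part = categorize_by_tss(ints, tss)
        labels = part.categories["chr1"].tolist()
        assert labels == ["immediate", "immediate", "intermediate",
                          "intermediate", "distal"]
        assert sum(part.counts.values()) == 5

    def test_partition_property_random(self, rng):
        for _ in range(50):
            ints = {"chr1": rng.integers(0, 1_000_000, size=rng.integers(1, 50))}
            tss = {"chr1": rng.integers(0, 1_000_000, size=rng.integers(1, 20))}
            part = categorize_by_tss(ints, tss)
            assert sum(part.counts.values()) == len(ints["chr1"])

    def test_chromosome_without_tss_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no TSS"):
            part = categorize_by_tss({"chrZ": np.array([1, 2])}, {"chr1": np.array([5])})
        assert part.n_dropped == 2 and sum(part.counts.values()) == 0

    def test_category_medians_within_bounds(self, rng):
        ints = {"chr1": rng.integers(0, 500_000, size=200)}
        tss = {"chr1": rng.integers(0, 500_000, size=10)}
        part = categorize_by_tss(ints, tss)
        if part.counts["immediate"]:
            assert part.medians["immediate"] < 3_000
        if part.counts["intermediate"]:
            assert 3_000 <= part.medians["intermediate"] <= 10_000
        if part.counts["distal"]:
            assert part.medians["distal"] > 10_000


class TestColocalize:
    def test_half_open_extension_arithmetic(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(10_000, 10_500)]})
        # extended territory [8,750, 11,750)
        count, frac, _ = colocalize({"chr1": np.array([11_749, 11_750])}, fs, pad=1_250)
        assert count == 1

    def test_midpoint_always_inside(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(500, 900)]})
        for pad in (0, 10, 1_250):
            count, _, _ = colocalize({"chr1": np.array([700])}, fs, pad=pad)
            assert count == 1

    def test_matches_per_base_scan_random(self, rng):
        for _ in range(100):
            n_peaks = int(rng.integers(1, 10))
            peaks = []
            for _ in range(n_peaks):
                s = int(rng.integers(0, 9_000))
                peaks.append((s, s + int(rng.integers(50, 800))))
            fs = ChIPFeatureSet("m", "t", {"chr1": peaks})
            pad = int(rng.integers(0, 500))
            pos = rng.integers(0, 10_000, size=30)
            count, _, flags = colocalize({"chr1": pos}, fs, pad=pad)
            territory = pad_intervals(peaks, pad)
            brute = [any(s <= p < e for s, e in territory) for p in pos]
            assert flags["chr1"].tolist() == brute
            assert count == sum(brute)

    def test_fraction_monotone_in_pad(self, rng):
        peaks = [(1_000, 1_400), (5_000, 5_600)]
        fs = ChIPFeatureSet("m", "t", {"chr1": peaks})
        pos = rng.integers(0, 10_000, size=200)
        fracs = [colocalize({"chr1": pos}, fs, pad=p)[1] for p in (0, 500, 1_250, 5_000)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestMatchedRandomFeatures:
    def test_count_and_length_matching(self):
        # 200 peaks of 500 bp -> total 100,000 bp, median 500 -> 200 intervals
        peaks = [(i * 1_000, i * 1_000 + 500) for i in range(200)]
        fs = ChIPFeatureSet("m", "t", {"chr1": peaks})
        rand = sample_matched_random_features(fs, {"chr1": [(0, 2_000_000)]}, rng=3)
        lengths = rand.lengths()
        assert rand.n_peaks() == 200
        assert set(lengths.tolist()) == {500}

    def test_deterministic_given_seed(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(0, 400), (10_000, 10_600)]})
        mask = {"chr1": [(0, 100_000)]}
        a = sample_matched_random_features(fs, mask, rng=11)
        b = sample_matched_random_features(fs, mask, rng=11)
        assert a.peaks == b.peaks

    def test_disjoint_and_inside_mask_scan(self, rng):
        fs = ChIPFeatureSet(
            "m", "t", {"chr1": [(i * 2_000, i * 2_000 + 700) for i in range(30)]}
        )
        mask = {"chr1": [(5_000, 150_000), (200_000, 260_000)]}
        rand = sample_matched_random_features(fs, mask, rng=5)
        ivs = sorted(rand.peaks["chr1"])
        merged_mask = merge_intervals(mask["chr1"])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        for s, e in ivs:
            assert any(ms <= s and e <= me for ms, me in merged_mask)

    def test_impossible_placement_raises(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(0, 900)]})
        with pytest.raises(ValueError, match="smaller"):
            sample_matched_random_features(fs, {"chr1": [(0, 500)]}, rng=0)


class TestEnrichmentTest:
    def test_saturated_features_fold_one_p_one(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(0, 100_000)]})
        ints = {"chr1": np.array([10, 500, 99_999])}
        res = enrichment_test(ints, fs, {"chr1": [(0, 100_000)]}, pad=0,
                              n_iter=50, seed=1)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_scenario_binomial_null(self):
        """Territory q = 0.10 of the mask with every integration inside:
        null counts ~ Binomial(n, ~q), fold near 1/q, p at the floor."""
        mask_len = 1_000_000
        peaks = [(i * 10_000, i * 10_000 + 1_000) for i in range(100)]
        fs = ChIPFeatureSet("m", "t", {"chr1": peaks})
        rng = np.random.default_rng(0)
        inside = np.concatenate([
            rng.integers(s, e, size=1) for s, e in peaks
        ])
        ints = {"chr1": np.sort(inside)}  # 100 integrations, all in peaks
        res = enrichment_test(ints, fs, {"chr1": [(0, mask_len)]}, pad=0,
                              n_iter=200, seed=2)
        n, q = 100, 0.10
        assert res.observed == 100
        assert abs(res.null_mean - n * q) < 3 * (n * q * (1 - q)) ** 0.5
        assert res.p_value == pytest.approx(1 / 201)
        assert abs(res.fold - 1 / q) / (1 / q) < 0.2

    def test_minimum_reportable_p_below_paper_floor(self):
        # with n_iter = 1,000 the add-one estimator can reach 1/1001 < 0.001
        assert 1 / (1_000 + 1) < 0.001


class TestGenomeFraction:
    def test_no_features_zero(self):
        fs = ChIPFeatureSet("m", "t", {})
        out = genome_fraction(fs, [0, 1_250], {"chr1": [(0, 10_000)]})
        assert out == {0: 0.0, 1_250: 0.0}

    def test_two_peak_merge_arithmetic(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(0, 100), (150, 250)]})
        out = genome_fraction(fs, [50], {"chr1": [(0, 1_000)]})
        # extended: [0,150) and [100,300) merge to [0,300)
        assert out[50] == pytest.approx(300 / 1_000)

    def test_monotone_over_default_grid(self, rng):
        peaks = [(int(s), int(s) + 200) for s in rng.integers(0, 90_000, size=8)]
        fs = ChIPFeatureSet("m", "t", {"chr1": merge_intervals(peaks)})
        out = genome_fraction(fs, [0, 1_250, 2_500, 5_000], {"chr1": [(0, 100_000)]})
        vals = [out[p] for p in (0, 1_250, 2_500, 5_000)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestMidpointProfile:
    def test_integration_at_midpoint_in_first_bin(self):
        fs = ChIPFeatureSet("m", "t", {"chr1": [(1_000, 1_400)]})
        edges, counts, beyond = midpoint_distance_profile({"chr1": np.array([1_200])}, fs)
        assert counts[0] == 1 and beyond == 0

    def test_matches_brute_force_scan_random(self, rng):
        for _ in range(100):
            peaks = sorted(
                (int(s), int(s) + int(rng.integers(100, 500)))
                for s in rng.integers(0, 50_000, size=rng.integers(1, 8))
            )
            fs = ChIPFeatureSet("m", "t", {"chr1": peaks})
            pos = rng.integers(0, 60_000, size=20)
            edges, counts, beyond = midpoint_distance_profile(
                {"chr1": pos}, fs, bin_size=200, max_range=10_000
            )
            mids = [(s + e) // 2 for s, e in peaks]
            brute = [min(abs(int(p) - m) for m in mids) for p in pos]
            bcounts, _ = np.histogram(
                [d for d in brute if d <= 10_000], bins=edges
            )
            assert counts.tolist() == bcounts.tolist()
            assert beyond == sum(d > 10_000 for d in brute)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            midpoint_distance_profile({"chr1": np.array([1])},
                                      ChIPFeatureSet("m", "t", {}))


class TestReduceIntegrationSet:
    def test_singletons_unchanged(self):
        ints = {"chr1": np.array([1_000, 4_000, 9_000])}
        red = reduce_integration_set(ints)
        assert red.coordinates["chr1"].tolist() == [1_000, 4_000, 9_000]
        assert red.singleton_fraction == 1.0

    def test_two_sites_emit_midpoint(self):
        red = reduce_integration_set({"chr1": np.array([1_000, 2_000])})
        assert red.coordinates["chr1"].tolist() == [1_500]
        assert red.multiplicity["chr1"].tolist() == [2]

    def test_three_sites_excluded(self):
        red = reduce_integration_set({"chr1": np.array([100, 900, 2_200])})
        assert red.coordinates["chr1"].size == 0
        assert red.n_excluded_clusters == 1

    def test_invariants_and_idempotence_random(self, rng):
        for _ in range(1_000):
            pos = rng.integers(0, 100_000, size=rng.integers(1, 40))
            red = reduce_integration_set({"chr1": pos})
            # output count = singleton bins + two-site bins
            assert red.n_coordinates() == red.n_singletons + red.n_pairs
            # no output bin holds two coordinates
            bins = red.coordinates["chr1"] // 2_500
            assert len(np.unique(bins)) == len(bins)
            again = reduce_integration_set(red.coordinates)
            assert again.coordinates["chr1"].tolist() == \
                red.coordinates["chr1"].tolist()
            assert again.n_excluded_clusters == 0
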