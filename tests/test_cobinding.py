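import math

import numpy as np
import pytest

from cobindclock.cobinding import (
    CobindConfig, DistanceSet, cistrome_overlap, cobinding_ratio,
    distance_histogram, extract_cobound_pairs, filter_by_fe,
    nearest_summit_distances, pool_cistromes)
from cobindclock.peak_io import Cistrome, GenomicPeak

from conftest import brute_force_nearest, make_cistrome, random_cistrome


class TestFilterByFe:
    def test_inclusive_cutoff(self):
        c = make_cistrome("GR", [100, 500, 900], fe=[5.0, 30.0, 31.0])
        kept = filter_by_fe(c, 30)
        assert [p.fold_enrichment for p in kept] == [30.0, 31.0]

    def test_cutoff_zero_is_identity(self):
        c = make_cistrome("GR", [100, 500], fe=[5.0, 30.0])
        assert filter_by_fe(c, 0).peaks == c.peaks

    def test_all_below_cutoff_gives_empty(self):
        c = make_cistrome("GR", [100], fe=[5.0])
        assert len(filter_by_fe(c, 100)) == 0

    def test_missing_fe_errors_with_peak_names(self):
        c = make_cistrome("GR", [100, 500], fe=[5.0, None])
        with pytest.raises(ValueError, match="GR_1"):
            filter_by_fe(c, 10)


class TestPooling:
    def test_multiset_union_retains_duplicates(self):
        a = make_cistrome("t1", [100, 200, 300])
        b = make_cistrome("t2", [100, 400, 500, 600])
        pooled = pool_cistromes([a, b], "pool")
        assert len(pooled) == 7

    def test_single_input_relabelled(self):
        a = make_cistrome("t1", [100, 200])
        pooled = pool_cistromes([a], "pool")
        assert pooled.factor_label == "pool"
        assert pooled.peaks == a.peaks

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_cistromes([], "pool")

    def test_pooled_distance_is_elementwise_minimum(self):
        rng = np.random.default_rng(3)
        query = random_cistrome(rng, "q", 50)
        r1 = random_cistrome(rng, "r1", 50)
        r2 = random_cistrome(rng, "r2", 50)
        pooled = pool_cistromes([r1, r2], "pool")
        d1 = nearest_summit_distances(query, r1).distances
        d2 = nearest_summit_distances(query, r2).distances
        dp = nearest_summit_distances(query, pooled).distances
        assert np.array_equal(dp, np.minimum(d1, d2))


class TestNearestDistances:
    def test_forced_example(self):
        q = make_cistrome("q", [100, 500])
        r = make_cistrome("r", [120, 1000])
        d = nearest_summit_distances(q, r)
        assert sorted(d.distances.tolist()) == [20, 380]
        assert d.n_orphans == 0

    def test_orphan_chromosome_counted_separately(self):
        q = Cistrome("q", [GenomicPeak("chr2", 0, 300, 100, "a"),
                           GenomicPeak("chr1", 0, 300, 100, "b")])
        r = make_cistrome("r", [150], chrom="chr1")
        d = nearest_summit_distances(q, r)
        assert d.n_orphans == 1
        assert d.distances.tolist() == [50]

    def test_empty_reference_rejected(self):
        q = make_cistrome("q", [100])
        with pytest.raises(ValueError):
            nearest_summit_distances(q, Cistrome("r", []))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = random_cistrome(rng, "q", 300)
        r = random_cistrome(rng, "r", 300)
        d = nearest_summit_distances(q, r)
        expect, orphans = brute_force_nearest(q, r)
        assert d.distances.tolist() == expect
        assert d.n_orphans == orphans

    def test_self_comparison_excludes_only_same_name(self):
        c = make_cistrome("q", [1000, 1000 + 320, 5000])
        d = nearest_summit_distances(c, c)
        expect, _ = brute_force_nearest(c, c, self_mode=True)
        assert d.distances.tolist() == expect
        assert 0 not in d.distances

    def test_duplicate_summits_across_cistromes_give_zero(self):
        q = make_cistrome("q", [1000])
        r = make_cistrome("r", [1000])
        assert nearest_summit_distances(q, r).distances.tolist() == [0]


class TestCobindingRatio:
    def test_counting_rule(self):
        d = DistanceSet("q", "r", np.array([20, 50, 119, 121, 400]))
        s = cobinding_ratio(d, CobindConfig())
        assert (s.n_proximal, s.n_nonproximal) == (3, 2)
        assert s.ratio == pytest.approx(1.5)
        assert s.median_proximal_bp == 50
        assert s.median_all_bp == 119

    def test_tie_at_threshold_is_nonproximal(self):
        d = DistanceSet("q", "r", np.array([119, 120]))
        s = cobinding_ratio(d, CobindConfig(proximal_threshold_bp=120))
        assert (s.n_proximal, s.n_nonproximal) == (1, 1)

    def test_all_proximal_gives_infinite_sentinel(self):
        d = DistanceSet("q", "r", np.array([5, 10]))
        s = cobinding_ratio(d)
        assert math.isinf(s.ratio)
        assert s.median_proximal_bp == 7.5

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2000, size=400)
        for c in (2, 7):
            s1 = cobinding_ratio(DistanceSet("q", "r", base),
                                 CobindConfig(proximal_threshold_bp=120))
            s2 = cobinding_ratio(DistanceSet("q", "r", base * c),
                                 CobindConfig(proximal_threshold_bp=120 * c))
            assert (s1.n_proximal, s1.n_nonproximal) == \
                (s2.n_proximal, s2.n_nonproximal)

    def test_empty_distance_set_rejected(self):
        with pytest.raises(ValueError):
            cobinding_ratio(DistanceSet("q", "r", np.array([], dtype=int)))


class TestHistogram:
    def test_bins_and_overflow(self):
        d = DistanceSet("q", "r", np.array([10, 25, 250]))
        h = distance_histogram(d, CobindConfig(histogram_bin_bp=20,
                                               histogram_max_bp=40))
        assert h.counts.tolist() == [1, 1]
        assert h.overflow == 1

    def test_empty_set_gives_all_zero(self):
        d = DistanceSet("q", "r", np.array([], dtype=int))
        h = distance_histogram(d)
        assert h.counts.sum() == 0 and h.overflow == 0

    def test_counts_conserved_on_random_draws(self):
        rng = np.random.default_rng(9)
        d = DistanceSet("q", "r", rng.integers(0, 5000, size=1000))
        h = distance_histogram(d)
        assert h.counts.sum() + h.overflow == len(d)
        assert h.bin_edges[-1] == 3000 and h.bin_edges[1] == 20


class TestCoboundPairs:
    def test_single_pair_example(self):
        q = make_cistrome("q", [100, 500])
        r = make_cistrome("r", [120, 1000])
        (pair,) = extract_cobound_pairs(q, r)
        assert pair.query_peak.summit == 100
        assert pair.ref_peak.summit == 120
        assert pair.distance_bp == 20

    def test_tiny_threshold_gives_empty(self):
        q = make_cistrome("q", [100])
        r = make_cistrome("r", [105])
        assert extract_cobound_pairs(
            q, r, CobindConfig(proximal_threshold_bp=1)) == []

    def test_pair_count_matches_proximal_count(self):
        rng = np.random.default_rng(13)
        q = random_cistrome(rng, "q", 200, span=100_000)
        r = random_cistrome(rng, "r", 200, span=100_000)
        config = CobindConfig()
        pairs = extract_cobound_pairs(q, r, config)
        summary = cobinding_ratio(nearest_summit_distances(q, r), config)
        assert len(pairs) == summary.n_proximal

    def test_sorted_by_chrom_then_start(self):
        rng = np.random.default_rng(17)
        q = random_cistrome(rng, "q", 100, span=50_000)
        r = random_cistrome(rng, "r", 100, span=50_000)
        pairs = extract_cobound_pairs(q, r)
        keys = [(p.query_peak.chrom, p.query_peak.start) for p in pairs]
        assert keys == sorted(keys)


class TestCistromeOverlap:
    def test_simple_shared(self):
        a = Cistrome("a", [GenomicPeak("chr1", 100, 200, 150, "a0")])
        b = Cistrome("b", [GenomicPeak("chr1", 150, 250, 200, "b0")])
        s = cistrome_overlap(a, b)
        assert (s.shared_a, s.shared_b, s.a_only, s.b_only) == (1, 1, 0, 0)

    def test_disjoint(self):
        a = make_cistrome("a", [1000, 2000])
        b = make_cistrome("b", [500_000])
        s = cistrome_overlap(a, b)
        assert (s.a_only, s.b_only, s.shared_a, s.shared_b) == (2, 1, 0, 0)

    def test_one_spanning_two_is_asymmetric(self):
        a = Cistrome("a", [GenomicPeak("chr1", 100, 1000, 500, "a0")])
        b = Cistrome("b", [GenomicPeak("chr1", 150, 250, 200, "b0"),
                           GenomicPeak("chr1", 700, 800, 750, "b1")])
        s = cistrome_overlap(a, b)
        assert (s.shared_a, s.shared_b) == (1, 2)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"proximal_threshold_bp": 0},
        {"fe_stringencies": (30, 10)},
        {"fe_stringencies": (-1, 10)},
        {"histogram_bin_bp": 7, "histogram_max_bp": 3000},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CobindConfig(**kwargs)
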