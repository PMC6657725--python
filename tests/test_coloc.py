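import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandcoloc import (
    coloc_percent,
    match_bands,
    permutation_test,
    summarize_larvae,
)
from _reference import brute_match_count, brute_two_sided_p


class TestMatchBands:
    def test_identical_sets_fully_matched(self, band_factory):
        a = band_factory([1.0, 2.0, 3.0])
        b = band_factory([1.0, 2.0, 3.0], channel="channel_b")
        assert len(match_bands(a, b)) == 3

    def test_single_pair_within_tolerance(self, band_factory):
        a = band_factory([1.0])
        b = band_factory([1.5], channel="channel_b")
        (pair,) = match_bands(a, b, tolerance_um=0.6)
        assert pair.distance == pytest.approx(0.5)

    def test_nearest_pair_wins(self, band_factory):
        # B at 1.55 is 0.45 from A at 2.0 and 0.55 from A at 1.0
        a = band_factory([1.0, 2.0])
        b = band_factory([1.55], channel="channel_b")
        (pair,) = match_bands(a, b)
        assert pair.position_a == pytest.approx(2.0)

    def test_one_to_one_no_double_counting(self, band_factory):
        a = band_factory([1.0])
        b = band_factory([0.8, 1.2], channel="channel_b")
        matched = match_bands(a, b)
        assert len(matched) == 1

    def test_empty_sets_match_empty(self, band_factory):
        assert match_bands(band_factory([]), band_factory([])) == []

    @given(st.integers(0, 5000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_reference_greedy_assignment(self, seed):
        from conftest import make_bands

        rng = np.random.default_rng(seed)
        pos_a = np.sort(rng.uniform(0, 20, rng.integers(0, 12)))
        pos_b = np.sort(rng.uniform(0, 20, rng.integers(0, 12)))
        got = match_bands(make_bands(pos_a), make_bands(pos_b))
        expected = brute_match_count(pos_a, pos_b, 0.6)
        assert len(got) == len(expected)
        assert sorted((m.position_a, m.position_b) for m in got) == sorted(expected)


class TestColocPercent:
    def test_identical_sets_give_100(self, band_factory):
        a = band_factory([1.0, 2.0, 3.0])
        b = band_factory([1.0, 2.0, 3.0], channel="channel_b")
        assert coloc_percent(a, b).percent_coloc == 100.0

    def test_disjoint_sets_give_0(self, band_factory):
        a = band_factory([1.0, 3.0, 5.0])
        b = band_factory([10.0, 12.0, 14.0], channel="channel_b")
        assert coloc_percent(a, b).percent_coloc == 0.0

    def test_partial_match_formula(self, band_factory):
        # 5 + 5 bands, 2 matched pairs -> 100 * 4 / 10 = 40%
        a = band_factory([1.0, 3.0, 5.0, 7.0, 9.0])
        b = band_factory([1.1, 3.1, 20.0, 22.0, 24.0], channel="channel_b")
        seg = coloc_percent(a, b)
        assert seg.n_matched_pairs == 2
        assert seg.percent_coloc == pytest.approx(40.0)

    def test_both_empty_is_undefined(self, band_factory):
        seg = coloc_percent(band_factory([]), band_factory([]))
        assert not seg.defined and math.isnan(seg.percent_coloc)

    def test_pairs_never_exceed_smaller_set(self, band_factory):
        seg = coloc_percent(band_factory([1.0, 1.4]),
                            band_factory([1.2], channel="channel_b"))
        assert seg.n_matched_pairs <= min(seg.n_bands_a, seg.n_bands_b)


class TestSummarizeLarvae:
    def test_mean_of_three_segments(self, band_factory):
        segments = [
            coloc_percent(band_factory([1.0], larva_id="L1", segment_id=f"s{k}"),
                          band_factory(pos, larva_id="L1", segment_id=f"s{k}",
                                       channel="channel_b"))
            for k, pos in enumerate([[1.0], [9.0], [1.0]])
        ]
        # percentages 100, 0, 100 -> larva mean 200/3
        data = summarize_larvae(segments, condition="c")
        assert data.larva_means["L1"] == pytest.approx(200.0 / 3.0)

    def test_undefined_segments_excluded_from_mean(self, band_factory):
        seg_def = coloc_percent(band_factory([1.0], larva_id="L1"),
                                band_factory([1.0], larva_id="L1", channel="channel_b"))
        seg_undef = coloc_percent(band_factory([], larva_id="L1"),
                                  band_factory([], larva_id="L1", channel="channel_b"))
        data = summarize_larvae([seg_def, seg_undef], condition="c")
        assert data.larva_means["L1"] == 100.0

    def test_larva_without_defined_segments_dropped_with_warning(self, band_factory):
        seg = coloc_percent(band_factory([], larva_id="L1"),
                            band_factory([], larva_id="L1", channel="channel_b"))
        with pytest.warns(UserWarning, match="no defined segments"):
            data = summarize_larvae([seg], condition="c")
        assert data.n_larvae == 0


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        res = permutation_test([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_three_vs_three_exhaustive_exact(self):
        res = permutation_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.mode == "exhaustive"
        assert res.n_permutations == 20
        assert res.n_as_or_more_extreme == 2
        assert res.p_value == pytest.approx(0.1)

    @given(st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exhaustive_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, rng.integers(2, 6)).astype(float)
        b = rng.integers(0, 5, rng.integers(2, 6)).astype(float)
        if np.all(np.concatenate([a, b]) == a[0]):
            return
        res = permutation_test(a, b)
        expected_p, _, total = brute_two_sided_p(a, b)
        assert res.mode == "exhaustive"
        assert res.n_permutations == total
        assert res.p_value == pytest.approx(expected_p)

    @given(st.integers(0, 5000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_two_sided_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(50, 10, 5)
        b = rng.normal(55, 10, 5)
        r1 = permutation_test(a, b, n_permutations=500, seed=seed)
        r2 = permutation_test(b, a, n_permutations=500, seed=seed)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_sampled_mode_uses_add_one_correction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(90, 1, 8)
        b = rng.normal(10, 1, 8)  # C(16,8) = 12870 > 200 -> sampled
        res = permutation_test(a, b, n_permutations=200, seed=1)
        assert res.mode == "sampled"
        assert res.p_value == pytest.approx((res.n_as_or_more_extreme + 1) / 201)
        assert res.p_value > 0.0

    def test_sampled_mode_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(50, 10, 9), rng.normal(60, 10, 9)
        r1 = permutation_test(a, b, n_permutations=400, seed=7)
        r2 = permutation_test(a, b, n_permutations=400, seed=7)
        assert r1 == r2

    def test_degenerate_identical_values_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = permutation_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_too_few_larvae_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test([1.0], [2.0, 3.0])
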