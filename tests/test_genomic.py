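import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from bandcoloc import (
    CoverageTrack,
    PeakSet,
    centered_matrix,
    composite_profile,
    overlap_stats,
    read_bed,
    read_bedgraph,
    sort_rows_by_signal,
    write_bed,
    write_bedgraph,
)
from bandcoloc.genomic import BedParseError
from _reference import brute_overlap_counts


def peak_set(triples, label="X", merge=True):
    return PeakSet(pd.DataFrame(triples, columns=["chrom", "start", "end"]),
                   label=label, merge=merge)


def random_peak_set(rng, n, span=2000, width_max=60):
    rows = []
    for _ in range(n):
        chrom = rng.choice(["chr2L", "chr3R"])
        start = int(rng.integers(0, span))
        rows.append((chrom, start, start + int(rng.integers(1, width_max))))
    return peak_set(rows)


class TestBedIO:
    def test_read_bed_basic_and_sorted(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr2R\t500\t600\nchr2R\t100\t200\nchr2L\t10\t20\n")
        peaks = read_bed(path)
        assert list(peaks.intervals["chrom"]) == ["chr2L", "chr2R", "chr2R"]
        assert peaks.intervals.iloc[1]["start"] == 100

    def test_overlapping_intervals_merged_on_load(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr2R\t100\t200\nchr2R\t150\t250\nchr2R\t400\t500\n")
        peaks = read_bed(path)
        assert len(peaks) == 2
        assert peaks.intervals.iloc[0]["end"] == 250

    @pytest.mark.parametrize(
        "line", ["chr2R\t200\t100", "chr2R\t-5\t100", "chr2R\t100"],
        ids=["end<start", "negative", "too-few-fields"],
    )
    def test_malformed_bed_names_line(self, tmp_path, line):
        path = tmp_path / "bad.bed"
        path.write_text("chr2R\t1\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match="bad.bed:2"):
            read_bed(path)

    def test_bed_roundtrip(self, tmp_path):
        peaks = peak_set([("chr2L", 5, 50), ("chr2R", 10, 30)])
        restored = read_bed(write_bed(peaks, tmp_path / "y.bed"))
        assert restored.intervals.equals(peaks.intervals)

    def test_bedgraph_roundtrip_and_gap_is_zero(self, tmp_path):
        track = CoverageTrack({"chr2L": ([0, 100], [50, 150], [2.0, 5.0])})
        restored = read_bedgraph(write_bedgraph(track, tmp_path / "t.bedGraph"))
        window = restored.window("chr2L", 40, 110)
        assert (window[:10] == 2.0).all()
        assert (window[10:60] == 0.0).all()   # gap [50,100)
        assert (window[60:] == 5.0).all()

    def test_bedgraph_rejects_overlapping_intervals(self, tmp_path):
        path = tmp_path / "bad.bedGraph"
        path.write_text("chr2L\t0\t100\t1.0\nchr2L\t50\t150\t2.0\n")
        with pytest.raises(BedParseError, match="overlapping"):
            read_bedgraph(path)


class TestOverlapStats:
    def test_mutual_overlap(self):
        stats = overlap_stats(peak_set([("chr2R", 100, 200)]),
                              peak_set([("chr2R", 150, 250)]))
        assert stats.pct_a_in_b == 100.0 and stats.pct_b_in_a == 100.0

    def test_half_open_adjacency_is_not_overlap(self):
        stats = overlap_stats(peak_set([("chr2R", 100, 200)]),
                              peak_set([("chr2R", 200, 300)]))
        assert stats.n_a_hit == 0 and stats.n_b_hit == 0

    def test_empty_set_percentage_undefined(self):
        stats = overlap_stats(peak_set([]), peak_set([("chr2R", 1, 2)]))
        assert stats.pct_a_in_b is None
        assert stats.n_b_hit == 0

    def test_chromosomes_kept_separate(self):
        stats = overlap_stats(peak_set([("chr2L", 100, 200)]),
                              peak_set([("chr2R", 100, 200)]))
        assert stats.n_a_hit == 0

    def test_min_overlap_bp_parameter(self):
        a = peak_set([("chr2R", 100, 200)])
        b = peak_set([("chr2R", 195, 300)])
        assert overlap_stats(a, b, min_overlap_bp=5).n_a_hit == 1
        assert overlap_stats(a, b, min_overlap_bp=6).n_a_hit == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_sweep_equals_brute_force_and_intervaltree(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peak_set(rng, int(rng.integers(0, 50)))
        b = random_peak_set(rng, int(rng.integers(0, 50)))
        stats = overlap_stats(a, b)
        ta = list(a.intervals.itertuples(index=False, name=None))
        tb = list(b.intervals.itertuples(index=False, name=None))
        n_a_hit, n_b_hit = brute_overlap_counts(ta, tb)
        assert (stats.n_a_hit, stats.n_b_hit) == (n_a_hit, n_b_hit)
        # second independent route: intervaltree containment queries
        trees = {}
        for chrom, start, end in tb:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        tree_hits = sum(
            1 for chrom, start, end in ta
            if chrom in trees and trees[chrom].overlap(start, end)
        )
        assert stats.n_a_hit == tree_hits

    def test_halving_coordinates_preserves_hits(self):
        rng = np.random.default_rng(99)
        rows = [("chr2L", int(s), int(s) + 2 * int(w))
                for s, w in zip(rng.integers(0, 4000, 40) * 2,
                                rng.integers(1, 30, 40))]
        a = peak_set(rows[:20])
        b = peak_set(rows[20:])
        halved_a = peak_set([(c, s // 2, e // 2) for c, s, e in
                             a.intervals.itertuples(index=False, name=None)])
        halved_b = peak_set([(c, s // 2, e // 2) for c, s, e in
                             b.intervals.itertuples(index=False, name=None)])
        full = overlap_stats(a, b)
        half = overlap_stats(halved_a, halved_b)
        assert (full.n_a_hit, full.n_b_hit) == (half.n_a_hit, half.n_b_hit)


class TestCenteredMatrix:
    def test_zero_coverage_gives_zero_rows(self):
        track = CoverageTrack({"chr2L": ([0], [10_000], [0.0])})
        peaks = peak_set([("chr2L", 4000, 4400)])
        m = centered_matrix(track, peaks, window_bp=200)
        assert (m.values == 0.0).all()  # log2(0 + 1) = 0

    def test_delta_at_midpoint_maps_to_center_column(self):
        # coverage 3 on exactly one bp at the peak midpoint: log2(4) = 2
        track = CoverageTrack({"chr2L": ([4200], [4201], [3.0])})
        peaks = peak_set([("chr2L", 4000, 4400)])
        m = centered_matrix(track, peaks, window_bp=200)
        center = m.window_bp // 2
        assert m.values[0, center] == pytest.approx(2.0)
        assert np.count_nonzero(m.values) == 1

    def test_doubling_track_shifts_log2_where_covered(self):
        track1 = CoverageTrack({"chr2L": ([100], [900], [4.0])})
        track2 = CoverageTrack({"chr2L": ([100], [900], [8.0])})
        peaks = peak_set([("chr2L", 400, 600)])
        m1 = centered_matrix(track1, peaks, window_bp=200, pseudocount=1e-9)
        m2 = centered_matrix(track2, peaks, window_bp=200, pseudocount=1e-9)
        np.testing.assert_allclose(m2.values - m1.values, 1.0, rtol=1e-6)

    def test_out_of_chromosome_positions_fill_zero(self):
        track = CoverageTrack({"chr2L": ([0], [100], [5.0])})
        peaks = peak_set([("chr2L", 0, 20)])  # window extends below position 0
        m = centered_matrix(track, peaks, window_bp=100)
        left = m.values[0, :40]   # offsets -50..-11 map to negative coordinates
        assert (left == 0.0).all()

    def test_missing_chromosome_warns_background_row(self):
        track = CoverageTrack({"chr2L": ([0], [100], [5.0])})
        peaks = peak_set([("chrX", 500, 600)])
        with pytest.warns(UserWarning, match="chrX"):
            m = centered_matrix(track, peaks, window_bp=100)
        assert (m.values == 0.0).all()

    def test_odd_window_rejected(self):
        track = CoverageTrack({"chr2L": ([0], [100], [1.0])})
        with pytest.raises(ValueError, match="even"):
            centered_matrix(track, peak_set([("chr2L", 10, 20)]), window_bp=101)

    def test_signal_conservation_identity(self):
        rng = np.random.default_rng(5)
        starts = np.arange(0, 5000, 100)
        track = CoverageTrack(
            {"chr2L": (starts, starts + 100, rng.uniform(0, 10, starts.size))}
        )
        peaks = peak_set([("chr2L", 2000, 2400), ("chr2L", 3000, 3100)])
        m = centered_matrix(track, peaks, window_bp=400, pseudocount=1.0)
        for row, (_, mid) in zip(m.values, peaks.midpoints.itertuples(index=False)):
            window_total = track.window("chr2L", mid - 200, mid + 200).sum()
            assert np.sum(2.0 ** row - 1.0) == pytest.approx(window_total, rel=1e-12)


class TestSortAndComposite:
    def test_sort_by_reference_means(self):
        m = _matrix_with(np.zeros((3, 4)))
        ref = _matrix_with(np.array([[3.0] * 4, [1.0] * 4, [2.0] * 4]))
        np.testing.assert_array_equal(sort_rows_by_signal(m, ref), [0, 2, 1])

    def test_all_equal_means_keep_original_order(self):
        m = _matrix_with(np.ones((4, 4)))
        np.testing.assert_array_equal(sort_rows_by_signal(m, m), [0, 1, 2, 3])

    def test_random_order_equals_argsort_oracle(self):
        rng = np.random.default_rng(8)
        ref = _matrix_with(rng.uniform(0, 5, (20, 10)))
        order = sort_rows_by_signal(ref, ref)
        expected = np.argsort(-ref.values.mean(axis=1), kind="stable")
        np.testing.assert_array_equal(order, expected)

    def test_mismatched_peaks_rejected(self):
        m1 = _matrix_with(np.ones((2, 4)))
        m2 = _matrix_with(np.ones((3, 4)))
        with pytest.raises(ValueError, match="different peak lists"):
            sort_rows_by_signal(m1, m2)

    def test_composite_single_row_is_that_row(self):
        m = _matrix_with(np.array([[1.0, 2.0, 3.0, 4.0]]))
        np.testing.assert_array_equal(composite_profile(m), m.values[0])

    def test_composite_equals_column_mean_oracle(self):
        rng = np.random.default_rng(3)
        m = _matrix_with(rng.uniform(0, 4, (20, 100)))
        expected = np.array([m.values[:, j].sum() / 20 for j in range(100)])
        np.testing.assert_allclose(composite_profile(m), expected, rtol=1e-12)

    def test_empty_matrix_rejected(self):
        m = _matrix_with(np.zeros((1, 4)))
        m.values = m.values[:0]
        with pytest.raises(ValueError):
            composite_profile(m)


def _matrix_with(values, peaks=None):
    """Build a CoverageMatrix carrying arbitrary row values for sort/composite tests."""
    from bandcoloc import CoverageMatrix

    values = np.asarray(values, float)
    if peaks is None:
        peaks = peak_set(
            [("chr2L", 100 * (i + 1), 100 * (i + 1) + 10)
             for i in range(values.shape[0])]
        )
    return CoverageMatrix(values=values, peaks=peaks, window_bp=values.shape[1],
                          pseudocount=1.0)
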