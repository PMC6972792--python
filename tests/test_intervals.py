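"""Interval arithmetic against per-base boolean oracles and worked cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pioneerscan.intervals import GenomicInterval, IntervalSet
from pioneerscan.regions import (
    annotate_window_signal,
    filter_by_track,
    frip,
    intersect_intervals,
    merge_intervals,
    refine_atac_regions,
    resize_intervals,
    subtract_blacklist,
)
from pioneerscan.tracks import SignalTrack

from conftest import coverage, random_interval_set


def iset(*triples):
    return IntervalSet.from_records(list(triples))


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_overlap_is_half_open(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))


class TestMerge:
    def test_overlapping_union(self):
        out = iset(("chrA", 10, 20), ("chrA", 15, 30)).merge(0)
        assert out.df[["start", "end"]].values.tolist() == [[10, 30]]

    def test_min_gap_bridges_small_gaps(self):
        out = iset(("chrA", 10, 20), ("chrA", 25, 30)).merge(10)
        assert out.df[["start", "end"]].values.tolist() == [[10, 30]]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            iset(("chrA", 0, 5)).merge(-1)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            s = random_interval_set(rng)
            merged = s.merge(0)
            cm, cs = coverage(merged), coverage(s)
            assert all((cm[c] == cs[c]).all() for c in cm)
            # merged set is sorted and non-overlapping per chrom
            for _, g in merged.df.groupby("chrom"):
                assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


intervals_strategy = st.lists(
    st.tuples(
        st.sampled_from(["chrA", "chrB"]),
        st.integers(min_value=0, max_value=9000),
        st.integers(min_value=1, max_value=500),
    ).map(lambda t: (t[0], t[1], t[1] + t[2])),
    min_size=1,
    max_size=30,
)


class TestMergeProperties:
    @settings(max_examples=50, derandomize=True)
    @given(rows=intervals_strategy, gap=st.integers(min_value=0, max_value=100))
    def test_merge_idempotent_and_coverage_preserving(self, rows, gap):
        s = IntervalSet.from_records(rows)
        merged = s.merge(gap)
        # covered bases are conserved or grown, never lost
        cs, cm = coverage(s), coverage(merged)
        for c in cs:
            assert not (cs[c] & ~cm[c]).any()
        # a second merge is the identity
        again = merged.merge(gap)
        assert again.df.equals(merged.df)

    @settings(max_examples=50, derandomize=True)
    @given(rows=intervals_strategy, delta=st.integers(min_value=-200, max_value=200))
    def test_resize_widths(self, rows, delta):
        s = IntervalSet.from_records(rows)
        out = s.resize(delta)
        widths = (out.df["end"] - out.df["start"]).to_numpy()
        assert (widths > 0).all()
        if delta >= 0:
            assert len(out) == len(s)


class TestIntersect:
    def test_clipped_regions(self):
        out = intersect_intervals(iset(("chrA", 0, 10)), iset(("chrA", 5, 20)))
        assert out.df[["start", "end"]].values.tolist() == [[5, 10]]

    def test_half_open_boundary_is_empty(self):
        out = intersect_intervals(iset(("chrA", 0, 10)), iset(("chrA", 10, 20)))
        assert len(out) == 0

    def test_any_overlap_keeps_original_rows(self):
        a = IntervalSet(
            pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [10], "name": ["x"]})
        )
        out = intersect_intervals(a, iset(("chrA", 9, 30)), mode="a_with_any_overlap")
        assert out.df["name"].tolist() == ["x"]
        assert out.df["end"].tolist() == [10]

    def test_matches_boolean_and_oracle(self, rng):
        for _ in range(50):
            a, b = random_interval_set(rng), random_interval_set(rng)
            out = intersect_intervals(a, b)
            ca, cb, co = coverage(a), coverage(b), coverage(out)
            for c in ca:
                assert (co[c] == (ca[c] & cb[c])).all()


class TestSubtract:
    def test_overlapping_interval_removed(self):
        assert len(subtract_blacklist(iset(("chrA", 100, 300)), iset(("chrA", 250, 400)))) == 0

    def test_touching_interval_kept(self):
        out = subtract_blacklist(iset(("chrA", 100, 200)), iset(("chrA", 200, 400)))
        assert len(out) == 1

    def test_empty_blacklist_is_identity(self):
        a = iset(("chrA", 1, 5), ("chrB", 7, 9))
        assert subtract_blacklist(a, IntervalSet.empty()).df.equals(a.df)

    def test_matches_oracle(self, rng):
        for _ in range(30):
            a, b = random_interval_set(rng), random_interval_set(rng)
            out = subtract_blacklist(a, b)
            cb = coverage(b)
            expected = [
                row
                for row in a.df.itertuples(index=False)
                if not cb[row.chrom][row.start : row.end].any()
            ]
            assert len(out) == len(expected)


class TestResize:
    def test_extension_by_48(self):
        out = resize_intervals(iset(("chrA", 100, 112)), 48)
        assert out.df[["start", "end"]].values.tolist() == [[52, 160]]

    def test_reduction_by_24(self):
        out = resize_intervals(iset(("chrA", 52, 160)), -24)
        assert out.df[["start", "end"]].values.tolist() == [[76, 136]]

    def test_degenerate_intervals_dropped(self):
        assert len(resize_intervals(iset(("chrA", 10, 20)), -6)) == 0

    def test_clipped_at_chromosome_ends(self):
        out = resize_intervals(iset(("chrA", 10, 90)), 50, chrom_sizes={"chrA": 100})
        assert out.df[["start", "end"]].values.tolist() == [[0, 100]]


class TestRefineAtacRegions:
    def test_single_small_peak(self):
        out = refine_atac_regions(iset(("chrA", 100, 112)), iset(("chrA", 90, 200)))
        assert out.df[["start", "end"]].values.tolist() == [[76, 136]]

    def test_two_small_peaks_merge_through_extension(self):
        out = refine_atac_regions(
            iset(("chrA", 100, 112), ("chrA", 150, 162)), iset(("chrA", 90, 200))
        )
        assert out.df[["start", "end"]].values.tolist() == [[76, 186]]

    def test_empty_input(self):
        assert len(refine_atac_regions(IntervalSet.empty(), iset(("chrA", 0, 100)))) == 0

    def test_result_within_grown_regions(self, rng):
        small = random_interval_set(rng, n=30)
        regions = random_interval_set(rng, n=10)
        out = refine_atac_regions(small, regions)
        grown = coverage(regions.resize(24))
        for c, cov in coverage(out).items():
            assert not (cov & ~grown[c]).any()


class TestFilterByTrack:
    def test_boundary_mean_is_kept(self):
        track = SignalTrack({"chrA": np.full(100, 0.8)})
        out = filter_by_track(iset(("chrA", 10, 20)), track, threshold=0.8, keep="ge")
        assert len(out) == 1

    def test_constant_one_track_keeps_everything(self, flat_track, rng):
        s = random_interval_set(rng)
        assert len(filter_by_track(s, flat_track, threshold=1.0, keep="ge")) == len(s)

    def test_low_mean_removed(self):
        arr = np.zeros(100)
        arr[10:15] = 1.0  # mean over [10, 20) = 0.5
        track = SignalTrack({"chrA": arr})
        assert len(filter_by_track(iset(("chrA", 10, 20)), track, threshold=0.8)) == 0

    def test_missing_chromosome_is_an_error(self, flat_track):
        with pytest.raises(KeyError, match="chrZ"):
            filter_by_track(iset(("chrZ", 0, 5)), flat_track, threshold=0.5)


class TestAnnotateWindowSignal:
    def test_uniform_track_four_bins(self, flat_track):
        mat = annotate_window_signal(iset(("chrA", 4000, 4200)), flat_track, 100, 25)
        assert mat.shape == (1, 4)
        np.testing.assert_allclose(mat, 25.0)

    def test_center_spike(self):
        arr = np.zeros(1000)
        arr[500] = 7
        track = SignalTrack({"chrA": arr})  # ratio track: no normalization
        mat = annotate_window_signal(iset(("chrA", 490, 510)), track, 50, 1)
        assert mat[0, 25] == 7
        assert mat.sum() == 7

    def test_row_sums_match_windowed_totals(self, rng):
        arr = rng.poisson(2.0, size=10_000).astype(float)
        track = SignalTrack({"chrA": arr, "chrB": np.zeros(10_000)},
                            library_size=arr.sum())
        s = random_interval_set(rng, n=20)
        mat = annotate_window_signal(s, track, 200, 25)
        centers = s.centers()
        for i, (chrom, c) in enumerate(zip(s.df["chrom"], centers)):
            expected = track.window_sums(chrom, np.array([c]), 200)[0] * track.norm_scale
            assert mat[i].sum() == pytest.approx(expected, rel=1e-9)

    def test_bin_must_divide_window(self, flat_track):
        with pytest.raises(ValueError):
            annotate_window_signal(iset(("chrA", 0, 10)), flat_track, 100, 30)


class TestFrip:
    def test_all_tags_in_peaks(self):
        arr = np.zeros(1000)
        arr[100:200] = 2
        track = SignalTrack({"chrA": arr}, library_size=arr.sum())
        assert frip(track, iset(("chrA", 50, 300))) == 1.0

    def test_no_peaks_is_zero(self):
        track = SignalTrack({"chrA": np.ones(100)}, library_size=100)
        assert frip(track, IntervalSet.empty()) == 0.0

    def test_fraction_counts(self):
        arr = np.zeros(1200)
        arr[0:30] = 1.0   # 30 tags inside
        arr[500:590] = 1.0  # 90 tags outside
        track = SignalTrack({"chrA": arr}, library_size=120)
        assert frip(track, iset(("chrA", 0, 30))) == pytest.approx(0.25)

    def test_invariant_to_uniform_scaling(self, rng):
        arr = rng.poisson(1.0, 2000).astype(float)
        peaks = iset(("chrA", 100, 400), ("chrA", 900, 1500))
        t1 = SignalTrack({"chrA": arr}, library_size=arr.sum())
        t2 = SignalTrack({"chrA": arr * 5}, library_size=arr.sum() * 5)
        assert frip(t1, peaks) == pytest.approx(frip(t2, peaks))

    def test_zero_library_is_an_error(self):
        track = SignalTrack({"chrA": np.zeros(10)})
        with pytest.raises(ValueError):
            frip(track, iset(("chrA", 0, 5)))
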