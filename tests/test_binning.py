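import numpy as np
import pytest
from hypothesis import given, strategies as st

import venomprint as vp
from venomprint.binning import cluster_replicate_peaks, merge_bin_sets

from oracles import brute_force_single_linkage


def cluster_times(clusters):
    return [tuple(t for _, t in c) for c in clusters]


class TestClustering:
    def test_two_replicates_one_marker(self):
        clusters = cluster_replicate_peaks([[40.4], [40.6]], gap=0.5)
        assert cluster_times(clusters) == [(40.4, 40.6)]

    def test_two_replicates_two_markers(self):
        clusters = cluster_replicate_peaks([[40.4], [42.0]], gap=0.5)
        assert cluster_times(clusters) == [(40.4,), (42.0,)]

    def test_matches_single_linkage_oracle(self):
        times = [10.0, 10.3, 10.5, 12.0]
        clusters = cluster_replicate_peaks([[t] for t in times], gap=0.6)
        assert cluster_times(clusters) == brute_force_single_linkage(times, 0.6)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_on_random_times(self, seed):
        rng = np.random.default_rng(seed)
        times = np.round(np.sort(rng.uniform(0, 30, 25)), 3)
        # one peak per replicate so the conflict-split rule never fires
        clusters = cluster_replicate_peaks([[t] for t in times], gap=0.4)
        assert cluster_times(clusters) == brute_force_single_linkage(times, 0.4)

    def test_replicate_conflict_split(self):
        # replicate 0 contributes two peaks chained into one cluster:
        # split must fall at the largest internal gap (between 10.5 and 10.9)
        clusters = cluster_replicate_peaks([[10.0, 10.9], [10.3, 11.0]], gap=0.5)
        assert cluster_times(clusters) == [(10.0, 10.3), (10.9, 11.0)]
        for c in clusters:
            reps = [r for r, _ in c]
            assert len(reps) == len(set(reps))


class TestBuildBins:
    def test_hand_computed_bin(self):
        bins = vp.build_bins([[(0, 40.4), (1, 40.6)]])
        b = bins.bins[0]
        assert b.label == "P40.5"
        assert b.center == pytest.approx(40.5)
        assert b.sd == pytest.approx(np.std([40.4, 40.6], ddof=1))
        assert b.half_width == pytest.approx(max(3 * b.sd, 0.15))

    def test_degenerate_sd_floor(self):
        bins = vp.build_bins([[(0, 30.0), (1, 30.0)]])
        b = bins.bins[0]
        assert b.sd == 0.0
        assert b.half_width == pytest.approx(0.15)

    def test_min_support_discards(self):
        bins = vp.build_bins([[(0, 25.0)]], min_support=2)
        assert len(bins) == 0

    def test_width_cap(self):
        # wildly spread cluster cannot produce a bin wider than the cap
        bins = vp.build_bins([[(0, 30.0), (1, 31.0)]], max_half_width=0.5)
        assert bins.bins[0].half_width == pytest.approx(0.5)

    def test_label_collision_suffixes(self):
        bins = vp.build_bins(
            [[(0, 40.50), (1, 40.50)], [(0, 40.54), (1, 40.54)]],
            min_half_width=0.01,
        )
        assert bins.labels == ["P40.5", "P40.5a"]


class TestMergeBinSets:
    def _binset(self, *centers, hw=0.4):
        clusters = [[(0, c - 0.01), (1, c + 0.01)] for c in centers]
        return vp.build_bins(clusters, min_half_width=hw)

    def test_disjoint_sets_concatenate(self):
        merged = merge_bin_sets([self._binset(20.0), self._binset(30.0)])
        assert [b.center for b in merged] == [20.0, 30.0]

    def test_overlapping_bins_union(self):
        a = vp.build_bins([[(0, 40.1), (1, 40.9)]], max_half_width=None)
        # bin spans [39.3, 41.7]; second set overlaps it
        b = vp.build_bins([[(0, 41.5), (1, 42.1)]], max_half_width=None)
        merged = merge_bin_sets([a, b])
        assert len(merged) == 1
        assert merged.bins[0].lo == pytest.approx(min(a.bins[0].lo, b.bins[0].lo))
        assert merged.bins[0].hi == pytest.approx(max(a.bins[0].hi, b.bins[0].hi))

    def test_idempotent_on_disjoint(self):
        s = self._binset(20.0, 25.0, 30.0)
        merged = merge_bin_sets([s])
        assert [b.lo for b in merged] == pytest.approx([b.lo for b in s])
        assert [b.hi for b in merged] == pytest.approx([b.hi for b in s])

    @pytest.mark.parametrize("seed", range(5))
    def test_result_pairwise_disjoint_and_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for _ in range(4):
            centers = np.sort(rng.uniform(10, 50, 12))
            clusters = [[(0, c - 0.1), (1, c + 0.1)] for c in centers]
            sets.append(vp.build_bins(clusters))
        merged = merge_bin_sets(sets)
        for b1, b2 in zip(merged.bins, merged.bins[1:]):
            assert b1.hi < b2.lo
        perm = [sets[i] for i in rng.permutation(len(sets))]
        merged2 = merge_bin_sets(perm)
        assert [b.lo for b in merged2] == pytest.approx([b.lo for b in merged])
        assert [b.hi for b in merged2] == pytest.approx([b.hi for b in merged])


class TestScoreProfile:
    def _bins(self):
        return vp.build_bins(
            [[(0, 40.4), (1, 40.6)], [(0, 42.0), (1, 42.2)]]
        )

    def test_no_peaks(self):
        row, unassigned = vp.score_profile([], self._bins())
        assert all(v == 0 for v in row.values())
        assert unassigned == []

    def test_peak_at_center(self):
        bins = self._bins()
        peak = vp.PeakCall(time=40.5, height=50, prominence=50)
        row, unassigned = vp.score_profile([peak], bins)
        assert row["P40.5"] == 1 and row["P42.1"] == 0
        assert unassigned == []

    def test_unassigned_peak(self):
        bins = self._bins()
        peaks = [
            vp.PeakCall(time=40.5, height=50, prominence=50),
            vp.PeakCall(time=55.0, height=50, prominence=50),
        ]
        row, unassigned = vp.score_profile(peaks, bins)
        assert sum(row.values()) == 1
        assert [p.time for p in unassigned] == [55.0]

    def test_overlapping_bins_nearest_center(self):
        a = vp.MarkerBin("A", center=40.0, lo=39.5, hi=40.6, sd=0.1, support=2)
        b = vp.MarkerBin("B", center=41.0, lo=40.4, hi=41.5, sd=0.1, support=2)
        bins = vp.BinSet(bins=(a, b))
        row, _ = vp.score_profile([vp.PeakCall(time=40.45, height=50, prominence=50)], bins)
        assert row == {"A": 1, "B": 0}


class TestExtendBins:
    def _bins(self):
        return vp.build_bins([[(0, 40.4), (1, 40.6)]])

    def test_new_bin_created(self):
        extended = vp.extend_bins(self._bins(), vp.PeakCall(55.0, 50, 50))
        assert "P55.0" in extended.labels
        assert len(extended) == 2

    def test_adjacent_bin_merges(self):
        bins = self._bins()
        edge = bins.bins[0].hi + 0.1
        extended = vp.extend_bins(bins, vp.PeakCall(edge, 50, 50), min_half_width=0.15)
        assert len(extended) == 1  # new bin touches the old one and merges in
        assert extended.bins[0].hi >= edge

    def test_peak_inside_bin_noop(self):
        bins = self._bins()
        extended = vp.extend_bins(bins, vp.PeakCall(40.5, 50, 50))
        assert extended.labels == bins.labels


@given(
    st.lists(
        st.floats(10, 50).map(lambda x: round(x, 2)),
        min_size=2,
        max_size=20,
        unique=True,
    )
)
def test_clustering_conserves_peaks(times):
    """Every input peak lands in exactly one cluster."""
    clusters = cluster_replicate_peaks([[t] for t in sorted(times)], gap=0.3)
    flat = sorted(t for c in clusters for _, t in c)
    assert flat == sorted(times)
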