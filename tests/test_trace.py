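import numpy as np
import pytest
from hypothesis import given, strategies as st

import venomprint as vp
from venomprint.exceptions import StandardsNotFoundError
from venomprint.trace import default_windows, size_peak

from conftest import make_gaussian_trace
from oracles import brute_force_peaks


class TestLocateStandards:
    def test_unique_maxima(self):
        trace = make_gaussian_trace([15.0, 44.9], [150, 150])
        sp = vp.locate_internal_standards(trace, (10, 20), (40, 50))
        assert sp.lower_time == pytest.approx(15.0, abs=0.02)
        assert sp.upper_time == pytest.approx(44.9, abs=0.02)

    def test_flat_trace(self):
        trace = vp.Trace("flat", np.arange(0, 60, 0.1), np.zeros(600))
        with pytest.raises(StandardsNotFoundError):
            vp.locate_internal_standards(trace, (10, 20), (40, 50))

    def test_tallest_wins(self):
        # two candidates in the lower window; exhaustive scan agrees the
        # 150 FU apex at 15.1 beats the 80 FU apex at 14.8
        trace = make_gaussian_trace([14.8, 15.1, 44.9], [80, 150, 150])
        sp = vp.locate_internal_standards(trace, (10, 20), (40, 50))
        assert sp.lower_time == pytest.approx(15.1, abs=0.02)
        window = (trace.times >= 10) & (trace.times <= 20)
        assert sp.lower_time == pytest.approx(
            trace.times[window][np.argmax(trace.fluorescence[window])], abs=1e-9
        )

    def test_default_windows_cover_span_ends(self):
        trace = make_gaussian_trace([15.0, 44.9], [150, 150], start=10, stop=50)
        (lo0, lo1), (hi0, hi1) = default_windows(trace)
        assert lo0 == pytest.approx(10.0) and hi1 == pytest.approx(trace.times[-1])
        assert lo1 < hi0


class TestAlignment:
    def test_identity_map(self):
        trace = make_gaussian_trace([15, 30, 45], [150, 90, 150])
        sp = vp.StandardPair(15.0, 45.0)
        aligned = vp.align_to_reference(trace, sp, sp)
        np.testing.assert_allclose(aligned.times, trace.times)

    def test_hand_computed_affine(self):
        # own (10, 40) onto reference (15, 45): a = 1, b = 5
        trace = make_gaussian_trace([20.0], [100], start=5, stop=45)
        aligned = vp.align_to_reference(
            trace, vp.StandardPair(10.0, 40.0), vp.StandardPair(15.0, 45.0)
        )
        peak = aligned.times[np.argmax(aligned.fluorescence)]
        assert peak == pytest.approx(25.0, abs=0.02)
        assert aligned.standards.lower_time == pytest.approx(15.0, abs=1e-9)
        assert aligned.standards.upper_time == pytest.approx(45.0, abs=1e-9)

    def test_simulated_warp_recovery(self):
        # observed time = 1.02 t + 0.8; aligning on the warped standards
        # composes to the identity
        warp = lambda t: 1.02 * t + 0.8  # noqa: E731
        true_times = np.linspace(16, 44, 15)
        trace = vp.Trace("w", warp(np.linspace(10, 50, 2001)), np.zeros(2001))
        own = vp.StandardPair(warp(15.0), warp(45.0))
        ref = vp.StandardPair(15.0, 45.0)
        aligned = vp.align_to_reference(trace, own, ref)
        np.testing.assert_allclose(aligned.times, np.linspace(10, 50, 2001), atol=1e-6)
        del true_times

    def test_alignment_idempotent(self):
        trace = make_gaussian_trace([15, 30, 45], [150, 90, 150])
        own = vp.StandardPair(15.0, 45.0)
        ref = vp.StandardPair(14.0, 46.0)
        once = vp.align_to_reference(trace, own, ref)
        twice = vp.align_to_reference(once, once.standards, ref)
        np.testing.assert_allclose(twice.times, once.times, atol=1e-12)

    def test_coincident_standards_rejected(self):
        from venomprint.exceptions import ValidationError

        with pytest.raises(ValidationError):
            vp.StandardPair(15.0, 15.0)


class TestDetectPeaks:
    def test_single_gaussian(self):
        trace = make_gaussian_trace([30.0], [100])
        peaks = vp.detect_peaks(trace)
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(30.0, abs=0.02)
        assert peaks[0].height == pytest.approx(100, rel=0.01)

    def test_below_threshold_excluded(self):
        # the scoring rule counts only peaks above 20 fluorescence units
        trace = make_gaussian_trace([30.0], [19.9])
        assert vp.detect_peaks(trace, min_height=20) == []

    def test_close_peaks_suppressed(self):
        trace = make_gaussian_trace([30.0, 30.1], [80, 60], width=0.03)
        peaks = vp.detect_peaks(trace, min_separation=0.2)
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(30.0, abs=0.02)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        times = np.cumsum(rng.uniform(0.05, 0.3, n))
        values = rng.uniform(0, 60, n)
        trace = vp.Trace("r", times, values)
        ours = vp.detect_peaks(trace, min_height=20, min_prominence=5, min_separation=0.4)
        oracle_idx = brute_force_peaks(times, values, 20, 5, 0.4)
        np.testing.assert_allclose(
            [p.time for p in ours], times[oracle_idx], atol=1e-12
        )

    @given(st.lists(st.floats(0, 100), min_size=10, max_size=60, unique=True))
    def test_oracle_equivalence_property(self, values):
        values = np.array(values)
        times = 0.1 * np.arange(len(values))
        trace = vp.Trace("h", times, values)
        ours = vp.detect_peaks(trace, min_height=10, min_prominence=2, min_separation=0.25)
        oracle_idx = brute_force_peaks(times, values, 10, 2, 0.25)
        assert [p.time for p in ours] == pytest.approx(list(times[oracle_idx]))


class TestScoreableRange:
    def _peak(self, t):
        return vp.PeakCall(time=t, height=50, prominence=50)

    def test_beyond_upper_excluded(self):
        sp = vp.StandardPair(15.0, 45.0)
        kept = vp.restrict_to_scoreable_range([self._peak(47.0)], sp)
        assert kept == []

    def test_between_standards_retained(self):
        sp = vp.StandardPair(15.0, 45.0)
        kept = vp.restrict_to_scoreable_range([self._peak(30.0)], sp)
        assert len(kept) == 1

    def test_exactly_at_upper_excluded(self):
        sp = vp.StandardPair(15.0, 45.0)
        p = self._peak(45.0)
        assert vp.restrict_to_scoreable_range([p], sp) == []
        assert "out_of_range" in p.flags

    def test_lower_flank_excluded(self):
        sp = vp.StandardPair(15.0, 45.0)
        assert vp.restrict_to_scoreable_range([self._peak(15.05)], sp, margin=0.2) == []


class TestSizing:
    def test_ladder_point_exact(self):
        ladder = vp.LadderTable(points=((10.0, 1.6), (30.0, 40.0), (45.0, 95.0)))
        for t, m in ladder.points:
            mass, extrapolated = size_peak(ladder, t)
            assert mass == pytest.approx(m, rel=1e-12)
            assert not extrapolated

    def test_log_linear_midpoint(self):
        # midpoint of (10 s, 10 kDa)-(20 s, 100 kDa) sizes to 10^1.5
        ladder = vp.LadderTable(points=((10.0, 10.0), (20.0, 100.0)))
        mass, _ = size_peak(ladder, 15.0)
        assert mass == pytest.approx(10**1.5, rel=1e-12)

    def test_extrapolation_flagged(self):
        ladder = vp.LadderTable(points=((10.0, 10.0), (20.0, 100.0)))
        mass, extrapolated = size_peak(ladder, 25.0)
        assert extrapolated
        assert mass == pytest.approx(10**2.5, rel=1e-9)

    @given(st.floats(10.0, 20.0), st.floats(10.0, 20.0))
    def test_order_preserving(self, t1, t2):
        ladder = vp.LadderTable(points=((10.0, 1.6), (14.0, 10.0), (20.0, 95.0)))
        m1, _ = size_peak(ladder, t1)
        m2, _ = size_peak(ladder, t2)
        if t1 < t2:
            assert m1 < m2
        elif t1 == t2:
            assert m1 == m2
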