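"""Stitching, hockey-stick cutoff and per-sample SE calling."""

import numpy as np
import pytest

from sescout.core import GenomicInterval, SignalTrack, ValidationError
from sescout.se_caller import (
    DegenerateCurveError,
    StitchedRegion,
    call_sample_ses,
    hockey_stick_cutoff,
    stitch_peaks,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def regions_from_signals(signals):
    return [
        StitchedRegion(span=iv(1000 * i, 1000 * i + 500), constituents=(), signal=s)
        for i, s in enumerate(signals)
    ]


class TestStitchPeaks:
    def test_gap_rule(self):
        regions = stitch_peaks([iv(0, 1000), iv(5000, 6000), iv(20000, 21000)])
        spans = [(r.span.start, r.span.end) for r in regions]
        assert spans == [(0, 6000), (20000, 21000)]
        assert regions[0].n_constituents == 2

    def test_zero_stitch_distance(self):
        peaks = [iv(0, 1000), iv(5000, 6000), iv(20000, 21000)]
        regions = stitch_peaks(peaks, stitch_distance=0)
        assert [(r.span.start, r.span.end) for r in regions] == [
            (0, 1000),
            (5000, 6000),
            (20000, 21000),
        ]

    def test_empty_peaks(self):
        assert stitch_peaks([]) == []

    def test_tss_proximal_peaks_become_flagged_singletons(self):
        peaks = [iv(0, 1000), iv(5000, 6000), iv(9000, 10000)]
        tss = [iv(9400, 9401)]  # center of third peak within 2.5 kb
        regions = stitch_peaks(peaks, tss=tss)
        prox = [r for r in regions if r.promoter_proximal]
        assert len(prox) == 1 and prox[0].span.start == 9000
        other = [r for r in regions if not r.promoter_proximal]
        assert [(r.span.start, r.span.end) for r in other] == [(0, 6000)]

    def test_overlapping_peaks_merged_first(self):
        regions = stitch_peaks([iv(0, 1000), iv(500, 1500)], stitch_distance=0)
        assert [(r.span.start, r.span.end) for r in regions] == [(0, 1500)]

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        peaks = []
        for _ in range(n):
            chrom = str(rng.choice(["chr1", "chr2"]))
            start = int(rng.integers(0, 200_000))
            peaks.append(iv(start, start + int(rng.integers(100, 3000)), chrom))
        stitch = int(rng.integers(0, 20_000))
        regions = stitch_peaks(peaks, stitch_distance=stitch)

        # union-find oracle on the gap relation over merged peaks
        from sescout.se_caller import merge_overlapping

        merged = merge_overlapping(peaks)
        parent = list(range(len(merged)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(merged)):
            for j in range(len(merged)):
                a, b = merged[i], merged[j]
                if a.chrom == b.chrom and max(a.start, b.start) - min(a.end, b.end) <= stitch:
                    parent[find(i)] = find(j)
        groups = {}
        for i, p in enumerate(merged):
            groups.setdefault(find(i), []).append(p)
        expected = sorted(
            (g[0].chrom, min(p.start for p in g), max(p.end for p in g))
            for g in groups.values()
        )
        got = sorted((r.span.chrom, r.span.start, r.span.end) for r in regions)
        assert got == expected

    def test_idempotent_on_stitched_spans(self):
        rng = np.random.default_rng(5)
        peaks = [iv(int(s), int(s) + 500) for s in rng.integers(0, 500_000, 50)]
        first = stitch_peaks(peaks)
        second = stitch_peaks([r.span for r in first])
        assert [(r.span.start, r.span.end) for r in first] == [
            (r.span.start, r.span.end) for r in second
        ]


class TestHockeyStick:
    def test_worked_example(self):
        hk = hockey_stick_cutoff(regions_from_signals([0, 1, 2, 3, 100]))
        assert hk.cutoff_index == 3
        assert hk.cutoff_signal == 3
        assert [r.signal for r in hk.superenhancers] == [100]

    def test_two_point_curve(self):
        hk = hockey_stick_cutoff(regions_from_signals([0, 100]))
        assert hk.cutoff_signal == 0
        assert [r.signal for r in hk.superenhancers] == [100]

    def test_scaled_endpoints(self):
        hk = hockey_stick_cutoff(regions_from_signals([3, 7, 50]))
        assert hk.y[0] == 0.0 and hk.y[-1] == 1.0
        assert hk.x[0] == 0.0 and hk.x[-1] == 1.0

    def test_all_equal_raises_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            hockey_stick_cutoff(regions_from_signals([5.0, 5.0, 5.0]))

    def test_threshold_property(self):
        rng = np.random.default_rng(8)
        hk = hockey_stick_cutoff(regions_from_signals(rng.lognormal(0, 1, 100)))
        assert min(r.signal for r in hk.superenhancers) > max(
            r.signal for r in hk.typical
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        signals = rng.lognormal(0, 1, 60)
        base = hockey_stick_cutoff(regions_from_signals(signals))
        scaled = hockey_stick_cutoff(regions_from_signals(signals * 37.5))
        assert len(base.superenhancers) == len(scaled.superenhancers)
        assert base.cutoff_index == scaled.cutoff_index

    @pytest.mark.parametrize("seed", range(10))
    def test_convex_curves_match_slope_oracle(self, seed):
        # on a convex ascending curve the cutoff is the first point (from the
        # right) after which every discrete slope dy/dx exceeds 1
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        increments = np.sort(rng.lognormal(0, 1, n - 1))
        signals = np.concatenate([[0.0], np.cumsum(increments)])
        hk = hockey_stick_cutoff(regions_from_signals(signals))
        x, y = hk.x, hk.y
        slopes = np.diff(y) / np.diff(x)
        above = np.where(slopes > 1)[0]
        expected = int(above[0]) if len(above) else len(signals) - 2
        assert hk.cutoff_index == expected


class TestCallSampleSes:
    def _sample(self):
        rng = np.random.default_rng(42)
        peaks, segs = [], []
        # background peaks on a 14 kb grid (> stitch distance), jittered, so
        # each stays its own region and none reaches the planted cluster
        for slot in range(200):
            s = 14_000 * slot + int(rng.integers(0, 1_000))
            peaks.append(iv(s, s + 800))
            segs.append(("chr1", s, s + 800, float(rng.lognormal(0, 0.3))))
        # one planted 5-peak high-signal cluster
        for k in range(5):
            s = 3_000_000 + k * 2_500
            peaks.append(iv(s, s + 1000))
            segs.append(("chr1", s, s + 1000, 60.0))
        return peaks, SignalTrack(segs)

    def test_planted_cluster_is_the_only_se(self):
        peaks, signal = self._sample()
        calls = call_sample_ses(peaks, signal)
        assert len(calls.superenhancers) == 1
        span = calls.superenhancers[0].span
        assert (span.start, span.end) == (3_000_000, 3_011_000)

    def test_control_equal_to_signal_degenerates(self):
        peaks, signal = self._sample()
        with pytest.raises(DegenerateCurveError):
            call_sample_ses(peaks, signal, control=signal)

    def test_zero_control_identity(self):
        peaks, signal = self._sample()
        zero = SignalTrack([("chr1", 0, 1, 0.0)])
        with_ctl = call_sample_ses(peaks, signal, control=zero)
        without = call_sample_ses(peaks, signal)
        assert [r.span for r in with_ctl.superenhancers] == [
            r.span for r in without.superenhancers
        ]

    def test_partition_of_regions(self):
        peaks, signal = self._sample()
        calls = call_sample_ses(peaks, signal)
        assert len(calls.superenhancers) + len(calls.typical) == len(
            calls.hockey.regions
        )
        assert not (
            {str(r.span) for r in calls.superenhancers}
            & {str(r.span) for r in calls.typical}
        )
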