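"""Stall detection, event statistics, conservation identities, comparisons."""

import numpy as np
import pytest

from strokeangio.stalling import (
    SegmentTrace,
    StallStats,
    compare_conditions,
    detect_stalls,
    merge_event_runs,
    segment_traces,
    stall_statistics,
)
from strokeangio.synthgen import (
    SceneSpec,
    StallProcessSpec,
    generate_scene,
    render_angiogram_series,
    truth_segment_graph,
)
from strokeangio.vessels import VesselMask


def _trace(intensity, background=0.1, sid=0):
    n = len(intensity)
    return SegmentTrace(segment_id=sid,
                        intensity=np.asarray(intensity, float),
                        background=np.full(n, background))


def _run_detection(spec, stall):
    scene, truth = generate_scene(spec)
    series = render_angiogram_series(scene, truth, stall, spec)
    graph = truth_segment_graph(scene, truth)
    vmask = VesselMask(scene.vessel_mask, 0.0, int(scene.vessel_mask.sum()))
    traces = segment_traces(series, graph, vessel_mask=vmask,
                            dilate_px=spec.vessel_radius_px)
    for tr in traces:
        detect_stalls(tr)
    return scene, truth, graph, vmask, traces


class TestDetectStalls:
    def test_toy_alternating_trace_two_events(self):
        flags, n = detect_stalls(_trace([1.0, 0.1, 1.0, 0.1, 1.0]))
        assert n == 2
        assert list(flags) == [False, True, False, True, False]

    def test_never_dropping_trace_zero_events(self):
        _, n = detect_stalls(_trace([1.0, 0.9, 1.1, 1.0]))
        assert n == 0

    def test_degenerate_trace_excluded(self):
        tr = _trace([0.1, 0.1, 0.1])
        _, n = detect_stalls(tr)
        assert tr.excluded and n == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_stalls(_trace([1.0]))

    def test_brute_force_oracle_equivalence(self):
        """On small random traces the vectorized rule matches a per-frame
        Python reimplementation exactly."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 11)
            inten = rng.uniform(0.0, 1.2, n)
            bg = rng.uniform(0.0, 0.2, n)
            tr = SegmentTrace(0, inten, bg)
            flags, _ = detect_stalls(tr, drop_ratio=0.25)
            med = float(np.median(inten))
            if np.median(med - bg) <= 1e-9:
                assert tr.excluded
                continue
            expected = [inten[f] <= bg[f] + 0.25 * (med - bg[f])
                        for f in range(n)]
            assert list(flags) == expected

    def test_noise_free_flags_equal_stall_log(self):
        spec = SceneSpec.small(seed=9, noise_sigma=0.0, n_segments=120)
        stall = StallProcessSpec(stall_prob=0.04, stall_segment_fraction=1.0,
                                 seed=3)
        _, truth, _, _, traces = _run_detection(spec, stall)
        for tr in traces:
            want = np.zeros(stall.n_frames, bool)
            want[truth.stall_log[tr.segment_id]] = True
            assert np.array_equal(tr.stalled, want)

    def test_f1_at_half_contrast_noise(self):
        spec = SceneSpec.small(seed=10, noise_sigma=0.5 * (1.0 - 0.05),
                               n_segments=120)
        stall = StallProcessSpec(stall_prob=0.04, stall_segment_fraction=1.0,
                                 seed=4)
        _, truth, _, _, traces = _run_detection(spec, stall)
        tp = fp = fn = 0
        for tr in traces:
            want = np.zeros(stall.n_frames, bool)
            want[truth.stall_log[tr.segment_id]] = True
            tp += int((tr.stalled & want).sum())
            fp += int((tr.stalled & ~want).sum())
            fn += int((~tr.stalled & want).sum())
        assert 2 * tp / (2 * tp + fp + fn) >= 0.95


class TestMergeEventRuns:
    @pytest.mark.parametrize("flags,expected", [
        ([0, 1, 1, 0, 1], 2),
        ([1, 1, 1], 1),
        ([0, 0], 0),
        ([1, 0, 1, 0, 1], 3),
    ])
    def test_run_counting(self, flags, expected):
        assert merge_event_runs(np.array(flags, bool)) == expected


class TestSegmentTraces:
    def test_constant_frames_constant_traces(self):
        spec = SceneSpec.small(seed=11, noise_sigma=0.0, n_segments=30)
        stall = StallProcessSpec(stall_prob=0.0, seed=1)
        _, _, _, _, traces = _run_detection(spec, stall)
        for tr in traces:
            assert np.ptp(tr.intensity) == 0.0
            assert np.ptp(tr.background) == 0.0

    def test_trace_length_equals_kept_frames(self):
        spec = SceneSpec.small(seed=11, n_segments=30)
        stall = StallProcessSpec(n_frames=25, stall_prob=0.0, seed=1)
        _, _, _, _, traces = _run_detection(spec, stall)
        assert all(tr.n_frames == 25 for tr in traces)

    def test_stalled_frame_mean_matches_background(self):
        spec = SceneSpec.small(seed=12, noise_sigma=0.0, n_segments=40)
        stall = StallProcessSpec(stall_prob=0.1, stall_segment_fraction=1.0,
                                 seed=2)
        _, truth, _, _, traces = _run_detection(spec, stall)
        checked = 0
        for tr in traces:
            for f in truth.stall_log[tr.segment_id]:
                assert tr.intensity[f] == pytest.approx(tr.background[f])
                checked += 1
        assert checked == truth.n_stall_events


class TestStallStatistics:
    def test_hand_enumerated_three_segments(self):
        traces = [_trace([1, 1, 1, 1, 1], sid=0),
                  _trace([1.0, 0.1, 1.0, 0.1, 1.0], sid=1),
                  _trace([1, 1, 1, 1, 1], sid=2)]
        for tr in traces:
            detect_stalls(tr)
        from strokeangio.vessels import Segment, SegmentGraph
        import networkx as nx

        segs = [Segment(id=i, pixels=np.array([[0, i * 3], [0, i * 3 + 1]]),
                        endpoints=(2 * i, 2 * i + 1)) for i in range(3)]
        graph = SegmentGraph(nodes=[np.empty((0, 2), int)] * 6, segments=segs,
                             graph=nx.MultiGraph(), skeleton=np.zeros((4, 12), bool))
        mask = VesselMask(np.ones((4, 12), bool), 0.0, 48)
        stats = stall_statistics(traces, graph, mask)
        assert stats.n_events == 2
        assert stats.n_stalled_segments == 1
        assert stats.incidence == pytest.approx(1 / 3)
        assert stats.event_count_histogram == {2: 1}

    def test_no_stalls_zero_density_empty_histogram(self):
        spec = SceneSpec.small(seed=13, n_segments=30)
        stall = StallProcessSpec(stall_prob=0.0, seed=1)
        _, _, graph, vmask, traces = _run_detection(spec, stall)
        stats = stall_statistics(traces, graph, vmask)
        assert stats.n_events == 0
        assert stats.incidence == 0.0
        assert stats.event_count_histogram == {}

    def test_conservation_identities(self):
        spec = SceneSpec.small(seed=14, n_segments=100)
        stall = StallProcessSpec(stall_prob=0.05, stall_segment_fraction=0.5,
                                 seed=5)
        _, _, graph, vmask, traces = _run_detection(spec, stall)
        stats = stall_statistics(traces, graph, vmask)
        assert sum(k * v for k, v in stats.event_count_histogram.items()) == stats.n_events
        assert sum(stats.event_count_histogram.values()) == stats.n_stalled_segments
        assert stats.n_stalled_segments <= stats.n_segments_total

    def test_incidence_matches_closed_form(self):
        """100 of 400 segments eligible at p=0.05 over 60 frames:
        incidence ~ 100 (1 - 0.95^60) / 400."""
        spec = SceneSpec(grid_nx=256, grid_ny=256, grid_nz=16, n_segments=400,
                         seed=5, noise_sigma=0.0)
        stall = StallProcessSpec(stall_prob=0.05, stall_segment_fraction=0.25,
                                 seed=6)
        _, _, graph, vmask, traces = _run_detection(spec, stall)
        stats = stall_statistics(traces, graph, vmask)
        p_ever = 1 - 0.95 ** 60
        expected = 100 * p_ever / 400
        sd = np.sqrt(100 * p_ever * (1 - p_ever)) / 400
        assert abs(stats.incidence - expected) < 4 * sd

    def test_lesion_exclusion_removes_inside_segments(self):
        """Stalls on segments fully inside the lesion touch neither the
        event count nor the segment total nor the vascularized area."""
        import networkx as nx

        from strokeangio.vessels import Segment, SegmentGraph

        lesion = np.zeros((10, 20), bool)
        lesion[:, :10] = True
        segs = [Segment(id=0, pixels=np.array([[5, 1], [5, 2]]), endpoints=(0, 1)),
                Segment(id=1, pixels=np.array([[5, 15], [5, 16]]), endpoints=(2, 3))]
        graph = SegmentGraph(nodes=[np.empty((0, 2), int)] * 4, segments=segs,
                             graph=nx.MultiGraph(), skeleton=np.zeros((10, 20), bool))
        mask_arr = np.zeros((10, 20), bool)
        mask_arr[5, :] = True
        mask = VesselMask(mask_arr, 0.0, int(mask_arr.sum()))
        inside = _trace([1.0, 0.1, 0.1], sid=0)   # stalls, but inside lesion
        outside = _trace([1.0, 0.1, 1.0], sid=1)
        for tr in (inside, outside):
            detect_stalls(tr)
        stats = stall_statistics([inside, outside], graph, mask, lesion=lesion)
        assert stats.n_events == 1
        assert stats.n_segments_total == 1
        assert stats.vascularized_area_px == int((mask_arr & ~lesion).sum())


class TestCompareConditions:
    def _stats(self, n_events, n_stalled, hist, density):
        return StallStats(n_events=n_events, n_stalled_segments=n_stalled,
                          n_segments_total=100, vascularized_area_px=1000,
                          event_density_per_px2=density,
                          incidence=n_stalled / 100,
                          event_count_histogram=hist)

    def test_identical_stats_unit_ratios(self):
        s = self._stats(6, 3, {2: 3}, 0.006)
        out = compare_conditions(s, s)
        assert out["density_ratio"] == pytest.approx(1.0)
        assert out["incidence_ratio"] == pytest.approx(1.0)

    def test_empty_followup_zero_ratio(self):
        base = self._stats(6, 3, {2: 3}, 0.006)
        empty = self._stats(0, 0, {}, 0.0)
        assert compare_conditions(base, empty)["density_ratio"] == 0.0

    def test_zero_baseline_flagged_nan(self):
        base = self._stats(0, 0, {}, 0.0)
        follow = self._stats(6, 3, {2: 3}, 0.006)
        assert np.isnan(compare_conditions(base, follow)["density_ratio"])

    def test_doubled_stall_prob_doubles_density(self):
        """At small p the expected event count is linear in p."""
        ratios = []
        for seed in (1, 2, 3):
            stats = {}
            for p in (0.02, 0.04):
                spec = SceneSpec.small(seed=seed, n_segments=150)
                stall = StallProcessSpec(stall_prob=p,
                                         stall_segment_fraction=1.0,
                                         seed=seed + 50)
                _, _, graph, vmask, traces = _run_detection(spec, stall)
                stats[p] = stall_statistics(traces, graph, vmask)
            ratios.append(compare_conditions(stats[0.02], stats[0.04])["density_ratio"])
        # Monte-Carlo tolerance: ~180 vs ~360 expected events per run
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.35)

    def test_single_event_fraction_reported(self):
        base = self._stats(4, 3, {1: 2, 2: 1}, 0.004)
        out = compare_conditions(base, base)
        assert out["single_event_fraction_baseline"] == pytest.approx(2 / 3)
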