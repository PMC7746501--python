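import numpy as np
import pytest

import phonodose as pd
from phonodose.dosimetry_metrics import default_log_bins


def _track(decisions, hop=0.032):
    decisions = np.asarray(decisions, dtype=np.int8)
    grid = pd.FrameGrid(duration=len(decisions) * hop, frame_length=hop, hop=hop)
    return pd.DecisionTrack(decisions=decisions, grid=grid)


class TestFrameAccuracy:
    def test_identical_tracks_perfect(self, rng):
        d = (rng.random(1000) < 0.5).astype(np.int8)
        summary = pd.frame_accuracy(d, d)
        assert summary.agreement == 1.0
        assert summary.recall == 1.0

    def test_reported_percentage_from_frame_counts(self):
        # agreement reported to one decimal from raw frame counts
        for n_correct, n_total, expected in ((67_357, 83_157, 81.0),
                                             (199_201, 209_685, 95.0)):
            truth = np.ones(n_total, dtype=np.int8)
            pred = np.ones(n_total, dtype=np.int8)
            pred[: n_total - n_correct] = 0
            summary = pd.frame_accuracy(pred, truth)
            assert summary.n_correct == n_correct
            assert summary.as_dict()["agreement_pct"] == expected

    def test_recall_precision_asymmetry(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        pred = np.array([1, 0, 0, 1, 0, 0])
        s = pd.frame_accuracy(pred, truth)
        assert s.recall == pytest.approx(1 / 3)
        assert s.precision == pytest.approx(1 / 2)
        assert s.agreement == pytest.approx(3 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pd.frame_accuracy(np.ones(5), np.ones(6))


class TestPhonationRatio:
    def test_all_speech_is_one(self):
        assert pd.phonation_ratio(_track(np.ones(50))) == 1.0

    def test_reported_percentage_from_frame_counts(self):
        for n_speech, n_total, expected in ((33_019, 75_044, 44.0),
                                            (68_785, 88_186, 78.0)):
            d = np.zeros(n_total, dtype=np.int8)
            d[:n_speech] = 1
            assert round(100 * pd.phonation_ratio(d), 1) == expected

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            pd.phonation_ratio(np.array([], dtype=np.int8))


class TestRatioOverTime:
    def test_constant_speech_constant_ratio(self):
        track = _track(np.ones(200))
        for mode in ("cumulative", "sliding"):
            _, ratios = pd.ratio_over_time(track, mode=mode, window=1.0)
            np.testing.assert_allclose(ratios, 1.0)

    def test_sliding_window_hits_zero_after_long_gap(self):
        # 60 s speech then 60 s nonspeech with a 60 s sliding window
        n = int(60 / 0.032)
        track = _track(np.concatenate([np.ones(n), np.zeros(n)]))
        times, ratios = pd.ratio_over_time(track, mode="sliding", window=60.0)
        assert ratios[-1] == pytest.approx(0.0, abs=1e-3)

    def test_cumulative_final_value_equals_overall_ratio(self, rng):
        track = _track((rng.random(500) < 0.7).astype(np.int8))
        _, ratios = pd.ratio_over_time(track, mode="cumulative")
        assert ratios[-1] == pytest.approx(pd.phonation_ratio(track))

    def test_sliding_matches_brute_force_window_means(self, rng):
        track = _track((rng.random(300) < 0.5).astype(np.int8))
        window = 1.0
        _, ratios = pd.ratio_over_time(track, mode="sliding", window=window)
        w = int(round(window / track.grid.hop))
        d = track.decisions
        for j in range(len(d)):
            lo = max(j + 1 - w, 0)
            assert ratios[j] == pytest.approx(np.mean(d[lo:j + 1]))

    def test_sub_frame_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than one frame"):
            pd.ratio_over_time(_track(np.ones(10)), mode="sliding", window=0.001)


class TestToSegments:
    def test_run_length_arithmetic_example(self):
        segs = pd.to_segments(_track([1, 1, 0, 1]))
        assert [(s.start, s.end, s.kind) for s in segs] == [
            (0.0, pytest.approx(0.064), "speech"),
            (pytest.approx(0.064), pytest.approx(0.096), "nonspeech"),
            (pytest.approx(0.096), pytest.approx(0.128), "speech"),
        ]

    def test_all_ones_single_segment(self):
        segs = pd.to_segments(_track(np.ones(100)))
        assert len(segs) == 1
        assert segs[0].duration == pytest.approx(3.2)

    def test_matches_naive_rle_oracle(self, rng):
        for _ in range(20):
            d = (rng.random(200) < 0.5).astype(np.int8)
            segs = pd.to_segments(_track(d))
            # naive RLE
            expected = []
            run_start = 0
            for j in range(1, len(d) + 1):
                if j == len(d) or d[j] != d[run_start]:
                    expected.append((run_start, j, int(d[run_start])))
                    run_start = j
            assert len(segs) == len(expected)
            for seg, (a, b, v) in zip(segs, expected):
                assert seg.start == pytest.approx(a * 0.032)
                assert seg.end == pytest.approx(b * 0.032)
                assert seg.kind == ("speech" if v else "nonspeech")

    def test_segments_tile_and_alternate(self, rng):
        d = (rng.random(500) < 0.3).astype(np.int8)
        segs = pd.to_segments(_track(d))
        for prev, cur in zip(segs, segs[1:]):
            assert prev.end == pytest.approx(cur.start)
            assert prev.kind != cur.kind

    def test_speech_duration_consistent_with_ratio(self, rng):
        d = (rng.random(400) < 0.6).astype(np.int8)
        track = _track(d)
        segs = pd.to_segments(track)
        speech_time = sum(s.duration for s in segs if s.kind == "speech")
        total = len(d) * track.grid.hop
        assert speech_time / total == pytest.approx(pd.phonation_ratio(track))


class TestDurationHistogram:
    def test_single_segment_lands_in_decade_bin(self):
        seg = pd.Segment(start=0.0, end=5.0, kind="speech")
        edges, counts = pd.duration_histogram([seg], bins=np.array([0.01, 0.1, 1, 10, 100]))
        assert counts["speech"][2] == 1  # the [1, 10) bin
        assert counts["speech"].sum() == 1

    def test_empty_list_all_zero(self):
        _, counts = pd.duration_histogram([])
        assert counts["speech"].sum() == 0
        assert counts["nonspeech"].sum() == 0

    def test_totals_conserved_with_overflow(self, rng):
        segs = []
        t = 0.0
        for k in range(50):
            dur = float(rng.lognormal(0.5, 1.5))
            segs.append(
                pd.Segment(t, t + dur, "speech" if k % 2 == 0 else "nonspeech")
            )
            t += dur
        edges, counts = pd.duration_histogram(segs, bins=np.array([0.1, 1.0, 10.0]))
        assert counts["speech"].sum() + counts["nonspeech"].sum() == 50

    def test_default_bins_cover_frame_to_kiloseconds(self):
        edges = default_log_bins()
        assert edges[0] == pytest.approx(0.032)
        assert edges[-1] == pytest.approx(1000.0)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            pd.duration_histogram([], bins=np.array([1.0, 1.0, 2.0]))


class TestBuildReport:
    def test_report_is_internally_consistent(self, rng):
        d = (rng.random(2000) < 0.55).astype(np.int8)
        track = _track(d)
        rep = pd.build_report(track, truth=d)
        assert rep.overall_ratio == pytest.approx(np.mean(d))
        assert rep.accuracy.agreement == 1.0
        n_per_kind = {
            kind: sum(s.kind == kind for s in rep.segments)
            for kind in ("speech", "nonspeech")
        }
        for kind in n_per_kind:
            assert rep.histogram[kind].sum() == n_per_kind[kind]

    def test_track_to_labels_round_trip(self, rng):
        d = (rng.random(300) < 0.5).astype(np.int8)
        track = _track(d)
        labels = pd.track_to_labels(track)
        back = pd.labels_to_frames(labels, track.grid)
        np.testing.assert_array_equal(back, d)
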