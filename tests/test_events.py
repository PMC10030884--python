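"""Event detection, conflict resolution, classification and counting."""

import numpy as np
import pandas as pd
import pytest

from azping import (AZSet, QuantalEventDetector, StimProtocol, activity_map,
                    classify_events, detect_candidates, per_az_counts,
                    resolve_spatial_conflicts, smooth_trace)
from azping.quantify import TraceMatrix


def _tm(F_corr):
    F_corr = np.atleast_2d(np.asarray(F_corr, dtype=float))
    return TraceMatrix(F=F_corr, F_bg=np.zeros_like(F_corr),
                       roi_ids=np.arange(len(F_corr)), corrected=True,
                       F_corr=F_corr)


class TestSmoothTrace:
    def test_constant_unchanged_after_warmup(self):
        out = smooth_trace(np.full(20, 3.0), width=5)
        assert np.allclose(out[4:], 3.0)

    def test_unit_impulse_gives_plateau(self):
        x = np.zeros(20)
        x[8] = 1.0
        out = smooth_trace(x, width=5)
        assert np.allclose(out[8:13], 0.2)
        assert np.allclose(out[:8], 0.0) and np.allclose(out[13:], 0.0)

    def test_width_one_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        assert np.allclose(smooth_trace(x, width=1), x)

    def test_width_exceeding_length_raises(self):
        with pytest.raises(ValueError, match="width"):
            smooth_trace(np.ones(3), width=5)


class TestDetectCandidates:
    def test_injected_transient_found_at_peak(self, rng):
        noise = rng.normal(0, 1.0, 500)
        trace = noise.copy()
        decay = 10.0 * np.exp(-np.arange(12) / 4.0)
        trace[200 : 200 + 12] += decay  # 10x noise SD
        cands = detect_candidates(_tm(trace))
        assert len(cands) == 1
        assert abs(int(cands.loc[0, "peak_frame"]) - 200) <= 1

    def test_single_frame_spike_rejected_by_three_frame_mean(self):
        # alternating background gives the filtered trace a known SD of 1/5
        trace = (-1.0) ** np.arange(100) / 1.0
        sd = smooth_trace(trace, 5).std()
        threshold = 4 * sd
        spike = 1.2  # crosses the threshold alone, not as a 3-frame mean
        assert spike > threshold
        trace[50] += spike
        for t in (48, 49, 50):
            assert trace[t : t + 3].mean() < threshold
        cands = detect_candidates(_tm(trace))
        assert len(cands) == 0

    def test_null_false_positive_rate_below_one_per_mille(self, rng):
        """Flagged-frame fraction for pure Gaussian noise under the 4-SD rule."""
        flagged = 0
        total = 0
        for _ in range(100):
            trace = rng.normal(0, 1.0, 10_000)
            cands = detect_candidates(_tm(trace))
            flagged += len(cands)
            total += len(trace)
        assert flagged / total < 1e-3

    def test_zero_variance_trace_yields_nothing(self):
        assert len(detect_candidates(_tm(np.zeros(100)))) == 0

    def test_uncorrected_traces_rejected(self):
        tm = TraceMatrix(F=np.zeros((1, 50)), F_bg=np.zeros((1, 50)),
                         roi_ids=[0])
        with pytest.raises(ValueError, match="baseline-corrected"):
            detect_candidates(tm)


class TestResolveSpatialConflicts:
    def _dist(self, positions_um):
        p = np.asarray(positions_um, dtype=float)
        return np.abs(p[:, None] - p[None, :])

    def test_close_pair_keeps_highest_amplitude(self):
        cands = pd.DataFrame({"roi_id": [0, 1], "peak_frame": [10, 10],
                              "amplitude": [100.0, 80.0]})
        out = resolve_spatial_conflicts(cands, self._dist([0.0, 1.0]),
                                        np.array([0, 1]), radius_um=2.5)
        assert out["roi_id"].tolist() == [0]
        assert out["amplitude"].tolist() == [100.0]

    def test_distant_pair_both_survive(self):
        cands = pd.DataFrame({"roi_id": [0, 1], "peak_frame": [10, 10],
                              "amplitude": [100.0, 80.0]})
        out = resolve_spatial_conflicts(cands, self._dist([0.0, 5.0]),
                                        np.array([0, 1]), radius_um=2.5)
        assert len(out) == 2

    def test_whole_field_radius_keeps_single_event(self):
        """The 1,000 um spontaneous radius enforces one event per frame."""
        cands = pd.DataFrame({"roi_id": [0, 1, 2], "peak_frame": [10] * 3,
                              "amplitude": [50.0, 90.0, 70.0]})
        out = resolve_spatial_conflicts(cands, self._dist([0.0, 30.0, 80.0]),
                                        np.array([0, 1, 2]), radius_um=1000.0)
        assert len(out) == 1
        assert out.loc[0, "roi_id"] == 1

    def test_equal_amplitude_tie_breaks_to_lower_id(self):
        cands = pd.DataFrame({"roi_id": [3, 1], "peak_frame": [5, 5],
                              "amplitude": [60.0, 60.0]})
        dist = np.zeros((4, 4))
        out = resolve_spatial_conflicts(cands, dist, np.arange(4),
                                        radius_um=2.5)
        assert out["roi_id"].tolist() == [1]

    def test_no_surviving_pair_within_radius_property(self, rng):
        """Invariant: no two same-frame survivors closer than the radius."""
        n = 30
        pos = rng.uniform(0, 20, n)
        cands = pd.DataFrame({
            "roi_id": np.arange(n),
            "peak_frame": rng.integers(0, 5, n),
            "amplitude": rng.uniform(10, 100, n),
        })
        dist = self._dist(pos)
        out = resolve_spatial_conflicts(cands, dist, np.arange(n),
                                        radius_um=2.5)
        for _, grp in out.groupby("peak_frame"):
            ids = grp["roi_id"].to_numpy()
            for i in ids:
                for j in ids:
                    if i != j:
                        assert dist[i, j] > 2.5


class TestClassifyEvents:
    protocol = StimProtocol(stim_times=[5.0, 10.0, 15.0])

    def _events(self, frames):
        return pd.DataFrame({"roi_id": range(len(frames)),
                             "peak_frame": frames,
                             "amplitude": [50.0] * len(frames)})

    def test_event_half_second_after_stimulus_is_evoked(self):
        # stimulus at frame 100 (5 s at 20 Hz), event at frame 110
        out = classify_events(self._events([110]), self.protocol, "evoked")
        assert len(out) == 1 and out.loc[0, "mode"] == "evoked"

    def test_event_beyond_window_is_interleaved_not_evoked(self):
        out_ev = classify_events(self._events([130]), self.protocol, "evoked")
        out_int = classify_events(self._events([130]), self.protocol,
                                  "interleaved")
        assert len(out_ev) == 0
        assert len(out_int) == 1 and out_int.loc[0, "mode"] == "interleaved"

    def test_event_before_first_stimulus_never_evoked(self):
        out = classify_events(self._events([50]), self.protocol, "evoked")
        assert len(out) == 0

    def test_window_boundary_is_half_open(self):
        # stimulus frame 100: frame 100 excluded, frame 120 (1 s) included
        out = classify_events(self._events([100, 120, 121]), self.protocol,
                              "evoked")
        assert out["peak_frame"].tolist() == [120]

    def test_interleaved_and_evoked_are_disjoint(self, rng):
        frames = rng.integers(0, 400, 200)
        ev = classify_events(self._events(frames), self.protocol, "evoked")
        il = classify_events(self._events(frames), self.protocol,
                             "interleaved")
        assert len(ev) + len(il) == len(frames)
        assert not set(map(tuple, ev[["roi_id", "peak_frame"]].values)) & \
            set(map(tuple, il[["roi_id", "peak_frame"]].values))

    def test_time_shift_invariance(self):
        """Shifting stimuli and events together preserves classification."""
        frames = [110, 130, 205, 290]
        base = classify_events(self._events(frames),
                               StimProtocol(stim_times=[5.0, 10.0, 14.0]),
                               "evoked")
        shift_s, shift_f = 3.0, 60
        shifted = classify_events(
            self._events([f + shift_f for f in frames]),
            StimProtocol(stim_times=[5.0 + shift_s, 10.0 + shift_s,
                                     14.0 + shift_s]), "evoked")
        assert (shifted["peak_frame"] - shift_f).tolist() == \
            base["peak_frame"].tolist()

    def test_overlapping_windows_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_events(self._events([10]),
                            StimProtocol(stim_times=[1.0, 1.5]), "evoked")


class TestPerAzCounts:
    def _az(self, n):
        return AZSet(np.column_stack([np.linspace(5, 40, n)] * 2),
                     pixel_size=0.10833)

    def test_pooling_rule_and_flags(self):
        events = pd.DataFrame({
            "roi_id": [0, 0, 0, 0, 1, 2],
            "peak_frame": [1, 2, 3, 4, 5, 6],
            "amplitude": [10.0] * 6,
            "mode": ["spontaneous"] * 4 + ["spontaneous", "evoked"],
        })
        counts = per_az_counts(events, self._az(4))
        by_id = counts.set_index("roi_id")
        assert by_id.loc[0, "spont_group"] == ">=3"
        assert by_id.loc[1, "spont_group"] == "1"
        assert bool(by_id.loc[2, "responded"])
        assert by_id.loc[3].tolist() == [0, 0, "0", False]

    def test_detection_counts_match_truth_high_snr(self, noisy_activity_movie):
        from azping import baseline_correct, extract_traces, inter_roi_distances
        cfg, movie, truth, az = noisy_activity_movie
        tm = baseline_correct(extract_traces(movie, az, (0, 0)),
                              subtract_background=False)
        det = QuantalEventDetector()
        events = det.detect(tm, inter_roi_distances(az), mode="spontaneous")
        counts = per_az_counts(events, az).set_index("roi_id")
        truth_counts = truth.events.groupby("az_index").size()
        agree = sum(
            int(counts.loc[rid, "n_spont"]) == int(truth_counts.get(rid, 0))
            for rid in az.ids
        )
        assert agree >= len(az) - 2  # low-amplitude tail may add/merge one


class TestActivityMap:
    def test_mixed_mode_and_monotone_circles(self):
        events = pd.DataFrame({
            "roi_id": [0, 0, 1, 2, 2, 2],
            "peak_frame": range(6),
            "amplitude": [10.0] * 6,
            "mode": ["spontaneous", "evoked", "spontaneous", "evoked",
                     "evoked", "evoked"],
        })
        az = AZSet(np.array([[10.0, 10.0], [30.0, 10.0], [20.0, 30.0]]),
                   pixel_size=0.10833)
        counts = per_az_counts(events, az)
        fig, table = activity_map(counts, az, np.zeros((40, 40)))
        by_id = table.set_index("roi_id")
        assert by_id.loc[0, "mode"] == "mixed"
        assert by_id.loc[1, "mode"] == "spontaneous"
        assert by_id.loc[2, "mode"] == "evoked"
        # area ~ count: 3-event AZ draws a larger circle than 1-event AZ
        assert by_id.loc[2, "circle_radius_px"] > by_id.loc[1, "circle_radius_px"]
        import matplotlib.pyplot as plt
        plt.close(fig)

    def test_zero_counts_positions_only(self):
        az = AZSet(np.array([[10.0, 10.0]]), pixel_size=0.10833)
        counts = per_az_counts(pd.DataFrame(columns=["roi_id", "peak_frame",
                                                     "amplitude", "mode"]), az)
        fig, table = activity_map(counts, az, np.zeros((40, 40)))
        assert table.loc[0, "mode"] == "none"
        assert table.loc[0, "circle_radius_px"] == 0.0
        import matplotlib.pyplot as plt
        plt.close(fig)
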