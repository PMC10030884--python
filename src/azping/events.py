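"""Quantal event detection in corrected ROI traces.

A candidate is flagged wherever the mean of the unfiltered, baseline-
corrected signal over three consecutive frames exceeds four times the SD of
the causally smoothed (5-frame moving average) signal.  Same-frame spatial
conflicts are resolved greedily by amplitude within a distance radius
(2.5 um for evoked recordings, 1,000 um — i.e. whole-field exclusivity —
for spontaneous ones), and events are classified against the stimulus
protocol: evoked within 1 s after a stimulus, interleaved outside every
such window, spontaneous in stimulus-free recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

from .quantify import AZSet, TraceMatrix

__all__ = [
    "StimProtocol",
    "QuantalEventDetector",
    "smooth_trace",
    "detect_candidates",
    "resolve_spatial_conflicts",
    "classify_events",
    "per_az_counts",
    "activity_map",
]

EVENT_COLUMNS = ["roi_id", "peak_frame", "amplitude", "mode"]

RADIUS_EVOKED_UM = 2.5
RADIUS_SPONT_UM = 1000.0


@dataclass
class StimProtocol:
    """Stimulation protocol: times, evoked window and exclusion window.

    The canonical protocol is 36 single stimuli at 0.2 Hz over 180 s; an
    event counts as evoked when it peaks within ``evoked_window`` (1 s)
    after a stimulus, and the same window is excluded when scoring
    interleaved spontaneous activity.
    """

    stim_times: Sequence[float] = field(default_factory=list)
    evoked_window: float = 1.0
    exclusion_window: float = 1.0

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(list(self.stim_times), dtype=float)
        if self.evoked_window <= 0 or self.exclusion_window <= 0:
            raise ValueError("windows must be > 0")
        if self.stim_times.size and np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stim_times must be strictly increasing")

    @classmethod
    def regular(cls, n_stimuli: int = 36, rate_hz: float = 0.2,
                start: float = 0.0, **kw) -> "StimProtocol":
        times = start + np.arange(n_stimuli) / rate_hz
        return cls(stim_times=times, **kw)

    def stim_frames(self, frame_interval: float) -> np.ndarray:
        return np.floor(self.stim_times / frame_interval).astype(int)


def smooth_trace(trace: np.ndarray, width: int = 5) -> np.ndarray:
    """Causal moving average of the stated width (zeros before trace start)."""
    trace = np.asarray(trace, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > trace.shape[-1]:
        raise ValueError("filter width exceeds trace length")
    b = np.ones(width) / width
    return lfilter(b, 1.0, trace, axis=-1)


def detect_candidates(traces: TraceMatrix, k_sd: float = 4.0, consec: int = 3,
                      smooth_width: int = 5) -> pd.DataFrame:
    """Threshold-crossing candidates per ROI.

    Per ROI the SD of the smoothed trace over the full recording sets the
    threshold ``k_sd * SD``; frame t is flagged when the mean of the
    unfiltered corrected signal over frames t..t+consec-1 exceeds it.
    Consecutive flagged runs collapse to one candidate at the frame of
    maximal corrected signal within the run; its amplitude is that maximum.
    Zero-variance traces yield no candidates.
    """
    if not traces.corrected or traces.F_corr is None:
        raise ValueError("traces must be baseline-corrected first")
    F = traces.F_corr
    n_roi, n_frames = F.shape
    if consec < 1 or consec > n_frames:
        raise ValueError("invalid consec")
    smoothed = smooth_trace(F, width=smooth_width)
    sds = smoothed.std(axis=1, ddof=0)
    # mean over `consec` consecutive frames, anchored at the first
    kernel = np.ones(consec) / consec
    rows = []
    for i in range(n_roi):
        if sds[i] == 0:
            continue
        means = np.convolve(F[i], kernel, mode="valid")  # index t -> t..t+c-1
        flagged = means > k_sd * sds[i]
        if not flagged.any():
            continue
        idx = np.flatnonzero(flagged)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            lo, hi = run[0], run[-1] + consec  # frames covered by the run
            seg = F[i, lo:hi]
            peak = lo + int(np.argmax(seg))
            rows.append((int(traces.roi_ids[i]), peak, float(F[i, peak])))
    return pd.DataFrame(rows, columns=["roi_id", "peak_frame", "amplitude"])


def resolve_spatial_conflicts(candidates: pd.DataFrame, distances: np.ndarray,
                              roi_ids: np.ndarray,
                              radius_um: float) -> pd.DataFrame:
    """Keep one event per neighborhood and frame.

    Within each frame the highest-amplitude candidate survives and all
    others within ``radius_um`` are discarded; the rule repeats on the
    remainder.  Ties break toward the lower roi_id.
    """
    if candidates.empty:
        return candidates.copy()
    id_to_idx = {int(r): i for i, r in enumerate(np.asarray(roi_ids))}
    kept = []
    for frame, group in candidates.groupby("peak_frame"):
        group = group.sort_values(
            ["amplitude", "roi_id"], ascending=[False, True]
        )
        alive = group.to_dict("records")
        while alive:
            best = alive.pop(0)
            kept.append(best)
            bi = id_to_idx[int(best["roi_id"])]
            alive = [
                c for c in alive
                if distances[bi, id_to_idx[int(c["roi_id"])]] > radius_um
            ]
    out = pd.DataFrame(kept, columns=candidates.columns)
    return out.sort_values(["peak_frame", "roi_id"], ignore_index=True)


def classify_events(events: pd.DataFrame, protocol: StimProtocol,
                    mode: str, frame_interval: float = 0.05) -> pd.DataFrame:
    """Label and filter events against the stimulus protocol.

    mode='evoked' keeps events with peak_frame in (stim, stim + window]
    for some stimulus; mode='interleaved' keeps events outside every such
    window; mode='spontaneous' (stimulus-free recording) keeps all.
    """
    if mode not in ("spontaneous", "evoked", "interleaved"):
        raise ValueError("mode must be spontaneous, evoked or interleaved")
    events = events.copy()
    if mode == "spontaneous" or len(protocol.stim_times) == 0:
        events["mode"] = "spontaneous"
        return events
    window_s = (protocol.evoked_window if mode == "evoked"
                else protocol.exclusion_window)
    window = int(round(window_s / frame_interval))
    stim_frames = protocol.stim_frames(frame_interval)
    if np.any(np.diff(stim_frames) < window):
        raise ValueError("stimulus windows overlap")
    peaks = events["peak_frame"].to_numpy()
    in_window = np.zeros(len(events), dtype=bool)
    for sf in stim_frames:
        in_window |= (peaks > sf) & (peaks <= sf + window)
    if mode == "evoked":
        out = events[in_window].copy()
        out["mode"] = "evoked"
    else:
        out = events[~in_window].copy()
        out["mode"] = "interleaved"
    return out.reset_index(drop=True)


class QuantalEventDetector(BaseEstimator):
    """End-to-end event calling on a corrected trace matrix.

    Chains candidate detection, same-frame spatial conflict resolution at
    the mode-appropriate radius, and protocol classification.  The detected
    table is returned by :meth:`detect` and kept in ``events_``.
    """

    def __init__(self, k_sd: float = 4.0, consec: int = 3,
                 smooth_width: int = 5,
                 radius_evoked_um: float = RADIUS_EVOKED_UM,
                 radius_spont_um: float = RADIUS_SPONT_UM):
        self.k_sd = k_sd
        self.consec = consec
        self.smooth_width = smooth_width
        self.radius_evoked_um = radius_evoked_um
        self.radius_spont_um = radius_spont_um

    def detect(self, traces: TraceMatrix, distances: np.ndarray,
               mode: str = "spontaneous",
               protocol: StimProtocol | None = None) -> pd.DataFrame:
        protocol = protocol if protocol is not None else StimProtocol()
        radius = (self.radius_evoked_um if mode == "evoked"
                  else self.radius_spont_um)
        cands = detect_candidates(traces, k_sd=self.k_sd, consec=self.consec,
                                  smooth_width=self.smooth_width)
        events = resolve_spatial_conflicts(cands, distances, traces.roi_ids,
                                           radius_um=radius)
        self.events_ = classify_events(events, protocol, mode,
                                       frame_interval=traces.frame_interval)
        return self.events_


def per_az_counts(events: pd.DataFrame, az: AZSet,
                  animal_id: int | None = None) -> pd.DataFrame:
    """Per-AZ event counts and the pooled spontaneous-count group.

    Groups follow the 0 / 1 / 2 / >=3 pooling (AZs with three or more
    spontaneous events share one group); ``responded`` flags AZs with at
    least one evoked event.
    """
    spont = events[events["mode"].isin(["spontaneous", "interleaved"])]
    evoked = events[events["mode"] == "evoked"]
    n_spont = spont.groupby("roi_id").size().to_dict()
    n_evoked = evoked.groupby("roi_id").size().to_dict()
    rows = []
    for rid in az.ids:
        ns = int(n_spont.get(rid, 0))
        ne = int(n_evoked.get(rid, 0))
        group = str(ns) if ns < 3 else ">=3"
        rows.append((int(rid), ns, ne, group, ne >= 1))
    out = pd.DataFrame(
        rows, columns=["roi_id", "n_spont", "n_evoked", "spont_group", "responded"]
    )
    if animal_id is not None:
        out.insert(0, "animal_id", animal_id)
    return out


def activity_map(counts: pd.DataFrame, az: AZSet, marker_image: np.ndarray,
                 max_radius_px: float = 8.0):
    """Render the per-AZ activity overlay and its underlying table.

    The inverted marker image is overlaid with AZ positions (asterisks) and
    per-AZ circles whose area is proportional to the event count; color
    encodes the mode (spontaneous orange, evoked blue, mixed purple).
    Returns (matplotlib figure, CSV-ready DataFrame).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = np.asarray(marker_image, dtype=float)
    inverted = img.max() - img
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(inverted, cmap="gray")
    rows = []
    count_by_id = counts.set_index("roi_id")
    max_count = max(int(counts[["n_spont", "n_evoked"]].to_numpy().max()), 1) \
        if len(counts) else 1
    for rid, (x, y) in zip(az.ids, az.centers):
        ax.plot(x, y, marker="*", color="black", markersize=4, linestyle="none")
        if int(rid) not in count_by_id.index:
            continue
        rec = count_by_id.loc[int(rid)]
        ns, ne = int(rec["n_spont"]), int(rec["n_evoked"])
        total = ns + ne
        if total == 0:
            rows.append((int(rid), float(x), float(y), ns, ne, "none", 0.0))
            continue
        if ns and ne:
            color, mode = "purple", "mixed"
        elif ns:
            color, mode = "orange", "spontaneous"
        else:
            color, mode = "tab:blue", "evoked"
        # area proportional to count -> radius ~ sqrt(count)
        radius = max_radius_px * np.sqrt(total / max_count)
        circ = plt.Circle((x, y), radius, color=color, fill=False, linewidth=1.2)
        ax.add_patch(circ)
        rows.append((int(rid), float(x), float(y), ns, ne, mode, float(radius)))
    ax.set_axis_off()
    table = pd.DataFrame(
        rows,
        columns=["roi_id", "x_px", "y_px", "n_spont", "n_evoked", "mode",
                 "circle_radius_px"],
    )
    return fig, table
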