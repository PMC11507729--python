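"""Beat detection and rhythmicity analysis of cardiomyocyte motion traces.

Motion-speed signals from contracting cardiomyocytes show a double peak
("duplex") per beat: the first peak is the contraction, the second the
relaxation.  This module detects peaks, pairs them into duplexes by
inter-peak gap clustering, extracts maximal contraction/relaxation
velocities, and classifies each region of interest as rhythmic --
defined as no more than one out-of-sync beat in any 10 second window.
"Out of sync" is operationalized by walking the median-interval beat
grid with a configurable tolerance (default 50% of the median
interval): beats landing off the grid and grid slots with no beat each
count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import MotionTrace

__all__ = [
    "BeatEvent",
    "RhythmicityResult",
    "detect_beats",
    "max_velocities",
    "classify_rhythmicity",
    "contracting_fraction",
]


@dataclass
class BeatEvent:
    contraction_time_s: float
    contraction_velocity_um_s: float
    relaxation_time_s: float | None = None
    relaxation_velocity_um_s: float | None = None


@dataclass
class RhythmicityResult:
    rhythmic: bool
    n_beats: int
    n_out_of_sync: int
    median_interval_s: float | None
    low_n: bool = False


def detect_beats(
    trace: MotionTrace,
    min_peak_height: float | None = None,
    min_peak_separation_s: float = 0.15,
) -> list[BeatEvent]:
    """Detect beat duplexes on a motion-speed trace.

    Peaks above ``min_peak_height`` (default: 20% of the speed range
    above baseline) are paired into (contraction, relaxation) duplexes by
    clustering the inter-peak gaps: the gap within a duplex is smaller
    than the gap between beats, so the largest jump in the sorted gaps
    separates the two populations.  Unpaired peaks become
    contraction-only events.
    """
    if trace.duration_s < 10.0:
        raise ValueError("trace must span at least 10 s")
    y = trace.speed_um_s
    if min_peak_height is None:
        lo, hi = float(np.percentile(y, 10)), float(np.max(y))
        if hi <= lo:
            return []
        min_peak_height = lo + 0.2 * (hi - lo)
    fs = 1.0 / float(np.median(np.diff(trace.time_s)))
    distance = max(1, int(round(min_peak_separation_s * fs)))
    idx, _ = signal.find_peaks(y, height=min_peak_height, distance=distance)
    if idx.size == 0:
        return []
    times = trace.time_s[idx]
    amps = y[idx]
    if idx.size == 1:
        return [BeatEvent(float(times[0]), float(amps[0]))]

    gaps = np.diff(times)
    if gaps.size >= 3:
        p25, p75 = np.percentile(gaps, [25, 75])
        # duplex trains have clearly bimodal gaps (intra-duplex << between
        # beats); without that separation every peak is its own beat
        threshold = 0.5 * (p25 + p75) if p25 > 0 and p75 >= 2 * p25 else 0.0
    else:
        threshold = 0.0

    # smallest-gap-first matching: robust to the occasional spurious peak,
    # which would derail a greedy left-to-right walk
    partner = np.full(times.size, -1)
    for g in np.argsort(gaps):
        if gaps[g] >= threshold > 0:
            break
        if threshold > 0 and partner[g] == -1 and partner[g + 1] == -1:
            partner[g], partner[g + 1] = g + 1, g
    events: list[BeatEvent] = []
    for i in range(times.size):
        if partner[i] == i + 1:
            events.append(
                BeatEvent(
                    float(times[i]), float(amps[i]), float(times[i + 1]), float(amps[i + 1])
                )
            )
        elif partner[i] == -1:
            events.append(BeatEvent(float(times[i]), float(amps[i])))
    return events


def max_velocities(events: list[BeatEvent]) -> tuple[float, float | None]:
    """Maximal contraction and relaxation velocities over a recording.

    The relaxation maximum is taken over the events that have one and is
    None when none do.
    """
    if not events:
        raise ValueError("no beat events")
    vmax_c = max(e.contraction_velocity_um_s for e in events)
    relax = [e.relaxation_velocity_um_s for e in events if e.relaxation_velocity_um_s is not None]
    vmax_r = max(relax) if relax else None
    return float(vmax_c), (float(vmax_r) if vmax_r is not None else None)


def classify_rhythmicity(
    events: list[BeatEvent],
    window_s: float = 10.0,
    max_out_of_sync: int = 1,
    tolerance_frac: float = 0.5,
) -> RhythmicityResult:
    """Classify a beat sequence as rhythmic or arrhythmic.

    A beat is out of sync when either adjacent inter-beat interval
    deviates from the median interval by more than ``tolerance_frac`` of
    the median; a gap wide enough to have contained expected beats also
    marks the missing beats as out of sync.  The ROI is rhythmic iff
    every sliding ``window_s`` window contains at most
    ``max_out_of_sync`` out-of-sync beats.  Fewer than 3 beats is
    classified arrhythmic and flagged low-n.
    """
    if len(events) < 3:
        return RhythmicityResult(False, len(events), 0, None, low_n=True)
    times = np.array(sorted(e.contraction_time_s for e in events))
    intervals = np.diff(times)
    median = float(np.median(intervals))
    tol = tolerance_frac * median

    # walk the expected median-interval grid, re-anchoring on every beat
    # that lands in sync; early (extra) beats and empty grid slots each
    # count as one out-of-sync event
    out_times: list[float] = []
    expected = times[0] + median
    i = 1
    while i < times.size:
        if times[i] < expected - tol:
            out_times.append(float(times[i]))  # extra / badly early beat
            i += 1
        elif times[i] <= expected + tol:
            expected = times[i] + median  # in sync; re-anchor
            i += 1
        else:
            out_times.append(float(expected))  # missing beat at this slot
            expected += median

    out_arr = np.sort(np.array(out_times))
    rhythmic = True
    if out_arr.size > max_out_of_sync:
        # count out-of-sync beats in every window_s span
        for start in out_arr:
            n_in = int(np.sum((out_arr >= start) & (out_arr < start + window_s)))
            if n_in > max_out_of_sync:
                rhythmic = False
                break
    return RhythmicityResult(
        rhythmic=rhythmic,
        n_beats=len(events),
        n_out_of_sync=int(out_arr.size),
        median_interval_s=median,
    )


def contracting_fraction(
    rois: list[MotionTrace],
    motion_threshold_um_s: float,
    **detect_kwargs,
) -> float:
    """Percent of ROIs whose max speed exceeds the threshold and which
    contain at least one detected beat."""
    if not rois:
        raise ValueError("need at least one ROI")
    n_active = 0
    for roi in rois:
        if float(np.max(roi.speed_um_s)) <= motion_threshold_um_s:
            continue
        if detect_beats(roi, **detect_kwargs):
            n_active += 1
    return 100.0 * n_active / len(rois)
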