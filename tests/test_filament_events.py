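"""Single-filament segmentation: tiling, detection criteria, recovery."""

import numpy as np
import pytest

from fhodquant import filament_events as fe
from fhodquant import synthetic_data as sd
from fhodquant.types import SUBUNITS_PER_UM, FilamentTrace, SimulationParams


def make_trace(segments, dt=2.5, noise=0.0, seed=0, start_len=500.0):
    """Piecewise-linear trace from (velocity, duration) segments."""
    rng = np.random.default_rng(seed)
    total = sum(d for _, d in segments)
    t = np.arange(0.0, total + dt / 2, dt)
    breaks, vels = [0.0], []
    for v, d in segments:
        breaks.append(breaks[-1] + d)
        vels.append(v)
    breaks = np.array(breaks)
    vels = np.array(vels)
    cum = np.concatenate([[0.0], np.cumsum(vels * np.diff(breaks))])
    idx = np.clip(np.searchsorted(breaks, t, side="right") - 1, 0, vels.size - 1)
    y = start_len + cum[idx] + vels[idx] * (t - breaks[idx])
    if noise:
        y = y + rng.normal(0, noise, t.size)
    return FilamentTrace(time_s=t, length_su=y)


class TestConvertLength:
    def test_one_micron_is_370_subunits(self):
        assert fe.convert_length(1.0, "um") == pytest.approx(370.0)

    def test_zero_and_round_trip(self):
        assert fe.convert_length(0.0, "um") == 0.0
        su = fe.convert_length(1.10, "um")
        assert fe.convert_length(su, "subunits") == pytest.approx(1.10, rel=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            fe.convert_length(1.0, "nm")


class TestSegmentTrace:
    def test_pure_baseline_line_single_event(self):
        trace = make_trace([(13.0, 300.0)])
        events = fe.segment_trace(trace)
        assert [e.kind for e in events] == ["baseline"]
        assert events[0].slope_su_s == pytest.approx(13.0, abs=1e-9)

    def test_noiseless_pause_then_burst_recovered(self):
        # 10 s pause then a 1 um burst at 39 su/s, baseline 13 su/s around
        burst_d = 1.0 * SUBUNITS_PER_UM / 39.0
        trace = make_trace([(13.0, 100.0), (0.0, 10.0), (39.0, burst_d), (13.0, 100.0)])
        events = fe.segment_trace(trace)
        pauses = [e for e in events if e.kind == "pause"]
        bursts = [e for e in events if e.kind == "burst"]
        assert len(pauses) == 1 and len(bursts) == 1
        assert pauses[0].duration_s == pytest.approx(10.0, abs=2.5)
        assert bursts[0].slope_su_s == pytest.approx(39.0, rel=0.05)
        assert bursts[0].run_length_um == pytest.approx(1.0, abs=0.15)
        assert bursts[0].paired

    def test_four_second_flat_segment_not_reported_as_pause(self):
        trace = make_trace([(13.0, 100.0), (0.0, 4.0), (13.0, 100.0)])
        events = fe.segment_trace(trace)
        assert all(e.kind != "pause" for e in events)

    def test_events_tile_trace_and_are_ordered(self):
        spec = sd.FilamentEventSpec(binding_rate_per_s=0.01)
        params = SimulationParams(seed=2, noise_sd=5.0, frame_interval_s=2.5)
        trace, _ = sd.simulate_filament_trace(spec, 800.0, params)
        events = fe.segment_trace(trace)
        assert events[0].start_s == trace.time_s[0]
        assert events[-1].end_s == trace.time_s[-1]
        for prev, nxt in zip(events, events[1:]):
            assert nxt.start_s == pytest.approx(prev.end_s, abs=1e-9)
            assert nxt.end_s > nxt.start_s

    def test_no_pause_below_minimum_across_seeds(self):
        spec = sd.FilamentEventSpec(binding_rate_per_s=0.01)
        for seed in range(5):
            params = SimulationParams(seed=seed, noise_sd=6.0, frame_interval_s=2.5)
            trace, _ = sd.simulate_filament_trace(spec, 600.0, params)
            for e in fe.segment_trace(trace):
                if e.kind == "pause":
                    assert e.duration_s >= 5.0
                if e.kind == "burst":
                    assert e.r_squared > 0.5

    def test_trace_too_short_rejected(self):
        with pytest.raises(ValueError):
            FilamentTrace(time_s=np.arange(5) * 2.5, length_su=np.arange(5.0))


class TestAverageRate:
    def test_line_slope(self):
        assert fe.average_rate(make_trace([(11.0, 100.0)])) == pytest.approx(11.0)

    def test_piecewise_matches_regression_oracle(self):
        trace = make_trace([(13.0, 100.0), (39.0, 20.0), (13.0, 100.0)])
        oracle = np.polyfit(trace.time_s, trace.length_su, 1)[0]
        assert fe.average_rate(trace) == pytest.approx(oracle, rel=1e-12)

    def test_short_span_rejected(self):
        t = np.arange(8) * 1.0
        with pytest.raises(ValueError):
            fe.average_rate(FilamentTrace(time_s=t, length_su=t * 2))


def simulate_ensemble(n_traces=60, noise=5.0, seed=7, spec=None):
    spec = spec or sd.FilamentEventSpec(binding_rate_per_s=0.005)
    params = SimulationParams(seed=seed, noise_sd=noise, frame_interval_s=2.5)
    gen = params.rng()
    cfg = fe.SegmentationConfig()
    events, truths = [], []
    for _ in range(n_traces):
        tr, gt = sd.simulate_filament_trace(spec, 600.0, params, rng=gen)
        events.append(fe.segment_trace(tr, cfg))
        truths.append(gt)
    return events, truths, cfg


class TestSummarizeEvents:
    def test_single_event_sd_is_missing(self):
        burst_d = 1.0 * SUBUNITS_PER_UM / 39.0
        trace = make_trace([(13.0, 100.0), (0.0, 10.0), (39.0, burst_d), (13.0, 100.0)])
        summary = fe.summarize_events([fe.segment_trace(trace)])
        assert summary.n_bursts == 1
        assert summary.run_length_sd_um is None

    def test_paired_fraction_counts(self):
        burst_d = 1.0 * SUBUNITS_PER_UM / 39.0
        paired = make_trace([(13.0, 100.0), (0.0, 12.0), (39.0, burst_d), (13.0, 100.0)])
        unpaired = make_trace([(13.0, 100.0), (39.0, burst_d), (13.0, 100.0)])
        summary = fe.summarize_events(
            [fe.segment_trace(paired), fe.segment_trace(unpaired)]
        )
        assert summary.n_bursts == 2
        assert summary.paired_fraction == pytest.approx(0.5)

    def test_event_frequency_requires_grown_length(self):
        trace = make_trace([(13.0, 300.0)])
        with pytest.raises(ValueError):
            fe.summarize_events([fe.segment_trace(trace)], total_grown_length_um=0.0)

    def test_parameter_recovery_within_two_se(self):
        events, truths, cfg = simulate_ensemble(n_traces=120)
        s = fe.summarize_events(events, cfg=cfg, frame_interval_s=2.5)
        assert s.n_bursts >= 100 and s.n_pauses >= 100
        spec = truths[0].spec
        se_p = spec.pause_mean_s / np.sqrt(s.n_pauses)
        assert s.pause_mean_corrected_s == pytest.approx(spec.pause_mean_s, abs=2 * se_p)
        se_r = spec.run_length_mean_um / np.sqrt(s.n_bursts)
        assert s.run_length_corrected_um == pytest.approx(
            spec.run_length_mean_um, abs=2 * se_r
        )
        se_v = s.burst_rate_sd / np.sqrt(s.n_bursts)
        assert s.burst_rate_median == pytest.approx(spec.v_burst, abs=max(2 * se_v, 0.5))

    def test_detection_recall_precision_and_noise_monotonicity(self):
        def recall_precision(noise, seed=13):
            events, truths, _ = simulate_ensemble(n_traces=40, noise=noise, seed=seed)
            tp = fp = fn = 0
            for evs, gt in zip(events, truths):
                det = [e for e in evs if e.kind == "burst" and not e.censored]
                # true bursts above the quantized detection floor (the
                # minimum duration plus half a frame)
                true = [
                    e for e in gt.of_kind("burst")
                    if e.duration_s >= 5.0 + 1.25 and e.end_s < 599 and e.start_s > 1
                ]
                used = set()
                for tb in true:
                    hit = None
                    for i, db in enumerate(det):
                        if i in used:
                            continue
                        if min(tb.end_s, db.end_s) - max(tb.start_s, db.start_s) > 0:
                            hit = i
                            break
                    if hit is None:
                        fn += 1
                    else:
                        tp += 1
                        used.add(hit)
                # detected bursts count as false positives only when they
                # overlap no true burst at all (short true bursts are
                # legitimately detected but fall below the 5 s truth cut)
                all_true = gt.of_kind("burst")
                for i, db in enumerate(det):
                    if i in used:
                        continue
                    if not any(
                        min(tb.end_s, db.end_s) - max(tb.start_s, db.start_s) > 0
                        for tb in all_true
                    ):
                        fp += 1
            recall = tp / (tp + fn)
            precision = tp / max(tp + fp, 1)
            return recall, precision

        r0, p0 = recall_precision(0.0)
        assert r0 >= 0.9 and p0 >= 0.9
        r_hi, _ = recall_precision(15.0)
        assert r_hi <= r0 + 0.02  # recall does not improve with noise
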