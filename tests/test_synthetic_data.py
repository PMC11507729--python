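"""Generator contracts: determinism, analytic round trips, event statistics."""

import numpy as np
import pytest

from fhodquant import synthetic_data as sd
from fhodquant import pyrene_kinetics as pk
from fhodquant.types import SUBUNITS_PER_UM, AssayCondition, SimulationParams


class TestBulkPolymerization:
    def test_slope_at_completion_fraction_is_exact_before_noise(self, cond, noiseless):
        trace = sd.simulate_bulk_polymerization(cond, 1.0, 0.01, 600.0, noiseless)
        k = sd.logistic_rate_constant(1.0, 0.01)
        t18 = sd.logistic_crossing_time(600.0, k)
        # analytic derivative of the logistic at its 1/8-completion time
        f = 1 / 8
        assert k * 1.0 * f * (1 - f) == pytest.approx(0.01, abs=1e-12)
        # the sampled trace crosses 1/8 of plateau at the analytic time
        i = np.searchsorted(trace.value, 1.0 / 8)
        assert trace.time_s[i] == pytest.approx(t18, abs=noiseless.frame_interval_s)

    def test_deterministic_under_fixed_seed(self, cond):
        params = SimulationParams(seed=42, noise_sd=0.05, frame_interval_s=2.5)
        a = sd.simulate_bulk_polymerization(cond, 1.0, 0.01, 600.0, params)
        b = sd.simulate_bulk_polymerization(cond, 1.0, 0.01, 600.0, params)
        np.testing.assert_array_equal(a.value, b.value)

    def test_plateau_suppression_scales_with_dose(self, noiseless):
        hi = AssayCondition(formin_conc_nm=60.0)
        trace = sd.simulate_bulk_polymerization(
            hi, 1.0, 0.01, 600.0, noiseless, plateau_suppression_per_nm=0.005
        )
        assert trace.value[-1] < 0.75

    @pytest.mark.parametrize("plateau,slope", [(0.0, 0.01), (1.0, 0.0), (-1.0, 0.01)])
    def test_invalid_parameters_rejected(self, cond, noiseless, plateau, slope):
        with pytest.raises(ValueError):
            sd.simulate_bulk_polymerization(cond, plateau, slope, 600.0, noiseless)


class TestSeededElongation:
    def test_zero_formin_gives_free_rate(self, noiseless):
        cond = AssayCondition(formin_conc_nm=0.0)
        tr = sd.simulate_seeded_elongation(cond, 0.5, 0.1, 1.0, 0.2, 200.0, noiseless)
        rate, _ = pk.seeded_elongation_rate(tr)
        assert rate == pytest.approx(1.0, rel=1e-9)

    def test_saturating_formin_gives_bound_rate(self, noiseless):
        cond = AssayCondition(formin_conc_nm=1000.0)
        tr = sd.simulate_seeded_elongation(cond, 0.5, 0.1, 1.0, 0.2, 200.0, noiseless)
        rate, _ = pk.seeded_elongation_rate(tr)
        assert rate == pytest.approx(0.2, rel=5e-3)

    def test_negative_bound_rate_rejected(self, noiseless):
        with pytest.raises(ValueError):
            sd.simulate_seeded_elongation(
                AssayCondition(), 0.5, 0.1, 1.0, -0.1, 200.0, noiseless
            )


class TestFilamentTrace:
    def test_no_formin_is_pure_line(self, noiseless):
        spec = sd.FilamentEventSpec(binding_rate_per_s=0.0)
        trace, truth = sd.simulate_filament_trace(spec, 300.0, noiseless)
        assert [e.kind for e in truth.events] == ["baseline"]
        slopes = np.diff(trace.length_su) / np.diff(trace.time_s)
        np.testing.assert_allclose(slopes, spec.v_base, rtol=1e-9)

    def test_empirical_pause_mean_converges(self):
        spec = sd.FilamentEventSpec(pause_mean_s=12.0, binding_rate_per_s=0.02,
                                    paired_fraction=1.0)
        params = SimulationParams(seed=3, noise_sd=0.0, frame_interval_s=2.5)
        gen = params.rng()
        durations = []
        while len(durations) < 200:
            _, truth = sd.simulate_filament_trace(spec, 2000.0, params, rng=gen)
            durations.extend(
                e.duration_s for e in truth.of_kind("pause") if e.end_s < 1999
            )
        assert 11.0 <= np.mean(durations) <= 13.0

    def test_burst_duration_matches_run_length_over_velocity(self):
        spec = sd.FilamentEventSpec(run_length_mean_um=1.10, v_burst=39.0,
                                    binding_rate_per_s=0.02)
        params = SimulationParams(seed=5, noise_sd=0.0, frame_interval_s=2.5)
        gen = params.rng()
        durs = []
        while len(durs) < 300:
            _, truth = sd.simulate_filament_trace(spec, 2000.0, params, rng=gen)
            durs.extend(e.duration_s for e in truth.of_kind("burst") if e.end_s < 1999)
        expected = 1.10 * SUBUNITS_PER_UM / 39.0
        assert np.mean(durs) == pytest.approx(expected, rel=0.15)

    def test_event_statistics_sqrt_n_convergence(self):
        # the error of the empirical pause mean shrinks roughly as 1/sqrt(n)
        spec = sd.FilamentEventSpec(binding_rate_per_s=0.02, paired_fraction=1.0)
        errs = {}
        for n_target, seed in ((50, 11), (500, 11)):
            params = SimulationParams(seed=seed, noise_sd=0.0)
            gen = params.rng()
            durs = []
            while len(durs) < n_target:
                _, truth = sd.simulate_filament_trace(spec, 2000.0, params, rng=gen)
                durs.extend(e.duration_s for e in truth.of_kind("pause") if e.end_s < 1999)
            errs[n_target] = abs(np.mean(durs[:n_target]) - spec.pause_mean_s)
        assert errs[500] < errs[50] + 2.0  # no blow-up; larger n at least as good

    def test_deterministic_under_fixed_seed(self):
        spec = sd.FilamentEventSpec()
        params = SimulationParams(seed=9, noise_sd=4.0, frame_interval_s=2.5)
        a, _ = sd.simulate_filament_trace(spec, 500.0, params)
        b, _ = sd.simulate_filament_trace(spec, 500.0, params)
        np.testing.assert_array_equal(a.length_su, b.length_su)

    def test_too_short_duration_rejected(self, noiseless):
        with pytest.raises(ValueError):
            sd.simulate_filament_trace(sd.FilamentEventSpec(), 10.0, noiseless)


class TestGelLanes:
    def test_zero_dose_is_baseline(self, noiseless):
        (lane,) = sd.simulate_gel_lanes([0.0], 80.0, 10.0, noiseless, baseline_pct=5.0)
        frac = 100 * lane.pellet_intensity / (lane.pellet_intensity + lane.supernatant_intensity)
        assert frac == pytest.approx(5.0, abs=1e-9)

    def test_half_saturation_identity(self, noiseless):
        (lane,) = sd.simulate_gel_lanes([10.0], 80.0, 10.0, noiseless, baseline_pct=5.0)
        frac = 100 * lane.pellet_intensity / (lane.pellet_intensity + lane.supernatant_intensity)
        assert frac == pytest.approx(5.0 + (80.0 - 5.0) / 2, abs=1e-9)

    def test_intensity_conserved_before_noise(self, noiseless):
        lanes = sd.simulate_gel_lanes([0, 5, 20, 60], 80.0, 10.0, noiseless,
                                      total_intensity=1234.0)
        for lane in lanes:
            assert lane.pellet_intensity + lane.supernatant_intensity == pytest.approx(1234.0)

    def test_negative_concentration_rejected(self, noiseless):
        with pytest.raises(ValueError):
            sd.simulate_gel_lanes([-1.0], 80.0, 10.0, noiseless)


class TestLinescan:
    def test_peak_positions_at_spacing_multiples(self, noiseless):
        scan, peaks = sd.simulate_linescan(2.0, 3, 0.4, 0.1, noiseless)
        np.testing.assert_allclose(np.diff(peaks), 2.0, atol=1e-12)
        assert peaks.size == 4

    def test_zero_sarcomeres_gives_flat_profile(self, noiseless):
        scan, peaks = sd.simulate_linescan(2.0, 0, 0.4, 0.1, noiseless)
        assert peaks.size == 0
        assert np.ptp(scan.intensity) == pytest.approx(0.0, abs=1e-9)

    def test_undersampled_pixel_rejected(self, noiseless):
        with pytest.raises(ValueError):
            sd.simulate_linescan(2.0, 3, 0.4, 0.8, noiseless)


class TestMotionTrace:
    def test_ground_truth_beats_on_grid(self, noiseless):
        trace, gt = sd.simulate_motion_trace(1.0, 7.5, 6.1, 0.0, 0, 30.0, noiseless)
        intervals = np.diff(gt.contraction_times_s)
        np.testing.assert_allclose(intervals, 1.0, atol=1e-9)
        assert gt.rhythmic

    def test_out_of_sync_beats_displaced_beyond_tolerance(self, noiseless):
        _, gt = sd.simulate_motion_trace(1.0, 7.5, 6.1, 0.0, 2, 30.0, noiseless)
        assert gt.out_of_sync.sum() >= 2
        assert not gt.rhythmic

    def test_too_short_duration_rejected(self, noiseless):
        with pytest.raises(ValueError):
            sd.simulate_motion_trace(5.0, 7.5, 6.1, 0.0, 0, 2.0, noiseless)
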