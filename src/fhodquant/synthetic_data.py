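"""Ground-truth-annotated synthetic data for every assay modality.

Each generator emulates the statistical structure one analysis stage
assumes, with exactly known generating parameters, so that every
downstream estimator can be validated by parameter recovery:

* bulk pyrene assembly curves -- logistic in time, with the early slope
  (evaluated where the curve reaches a chosen completion fraction)
  controlled analytically;
* seeded-elongation traces whose initial slope follows the tight-binding
  (quadratic) occupancy of barbed ends by formin;
* single-filament growth as piecewise-linear trajectories: steady
  profilin-actin elongation interrupted by Poisson-arriving formin
  events, each a pause (exponential duration) followed by a burst of
  fast elongation (exponential run length);
* low-speed cosedimentation lanes whose pellet fraction saturates
  hyperbolically with formin dose;
* myofibril linescans as periodic Gaussian Z-line peaks;
* cardiomyocyte motion-speed traces as trains of contraction/relaxation
  peak duplexes with controllable arrhythmia.

Bulk curves are phenomenological (logistic), not mechanistic mass-action
kinetics: the quantities being tested are summary statistics of curve
shape, and the logistic gives exact analytic control over them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    SUBUNITS_PER_UM,
    AssayCondition,
    FilamentTrace,
    GelLane,
    Linescan,
    MotionTrace,
    PolymerizationTrace,
    SimulationParams,
)
from .pyrene_kinetics import quadratic_occupancy

__all__ = [
    "FilamentEventSpec",
    "FilamentGroundTruth",
    "GroundTruthEvent",
    "MotionGroundTruth",
    "logistic_rate_constant",
    "logistic_crossing_time",
    "simulate_bulk_polymerization",
    "simulate_seeded_elongation",
    "simulate_filament_trace",
    "simulate_gel_lanes",
    "simulate_linescan",
    "simulate_motion_trace",
]


# ---------------------------------------------------------------------------
# Bulk pyrene assembly


def logistic_rate_constant(plateau: float, slope_at_frac: float, fraction: float = 1 / 8) -> float:
    """Logistic rate constant giving ``slope_at_frac`` at ``fraction`` completion.

    For F(t) = P / (1 + exp(-k (t - t_mid))), dF/dt = k F (1 - F/P), so at
    F = f P the slope is k P f (1 - f).  Inverting fixes k exactly.
    """
    if plateau <= 0 or slope_at_frac <= 0:
        raise ValueError("plateau and slope_at_frac must be > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return slope_at_frac / (plateau * fraction * (1 - fraction))


def logistic_crossing_time(t_mid: float, k: float, fraction: float = 1 / 8) -> float:
    """Time at which the logistic reaches ``fraction`` of its plateau."""
    return t_mid + math.log(fraction / (1 - fraction)) / k


def simulate_bulk_polymerization(
    cond: AssayCondition,
    plateau: float,
    slope_at_t18: float,
    t_mid: float,
    params: SimulationParams,
    *,
    duration_s: float | None = None,
    completion_fraction: float = 1 / 8,
    plateau_suppression_per_nm: float = 0.0,
) -> PolymerizationTrace:
    """Simulate a bulk pyrene assembly curve as a logistic sigmoid.

    The steepness is chosen analytically so that the derivative evaluated
    where the curve reaches ``completion_fraction`` of the plateau equals
    ``slope_at_t18`` exactly (before noise).  ``plateau_suppression_per_nm``
    optionally shrinks the plateau with formin dose, mimicking the plateau
    decrease attributed to barbed-end capping; it is a phenomenological
    knob, not a kinetic model.
    """
    if plateau <= 0 or slope_at_t18 <= 0:
        raise ValueError("plateau and slope_at_t18 must be > 0")
    if t_mid <= 0:
        raise ValueError("t_mid must be > 0")
    eff_plateau = plateau * max(0.0, 1.0 - plateau_suppression_per_nm * cond.formin_conc_nm)
    if eff_plateau <= 0:
        raise ValueError("plateau suppressed to zero; reduce suppression factor")
    k = logistic_rate_constant(eff_plateau, slope_at_t18, completion_fraction)
    if duration_s is None:
        duration_s = 2.5 * t_mid
    t = np.arange(0.0, duration_s + 0.5 * params.frame_interval_s, params.frame_interval_s)
    value = eff_plateau / (1.0 + np.exp(-k * (t - t_mid)))
    if params.noise_sd > 0:
        value = value + params.rng().normal(0.0, params.noise_sd, size=t.size)
    return PolymerizationTrace(time_s=t, value=value, condition=cond)


def simulate_seeded_elongation(
    cond: AssayCondition,
    k_app_nm: float,
    barbed_ends_nm: float,
    rate_free: float,
    rate_bound: float,
    duration_s: float,
    params: SimulationParams,
    *,
    curvature_tau_s: float | None = None,
) -> PolymerizationTrace:
    """Simulate a seeded-elongation trace under the tight-binding model.

    The initial slope is rate_free + (rate_bound - rate_free) * theta,
    where theta is the exact quadratic-binding occupancy of barbed ends at
    the condition's formin concentration.  The trace is linear for at
    least its first 90 s; ``curvature_tau_s`` optionally adds late
    saturation (monomer depletion) while preserving the initial slope.
    """
    if k_app_nm < 0:
        raise ValueError("k_app_nm must be >= 0")
    if barbed_ends_nm <= 0:
        raise ValueError("barbed_ends_nm must be > 0")
    if rate_bound < 0 or rate_free < 0:
        raise ValueError("rates must be >= 0")
    theta = quadratic_occupancy(cond.formin_conc_nm, barbed_ends_nm, k_app_nm)
    slope = rate_free + (rate_bound - rate_free) * theta
    t = np.arange(0.0, duration_s + 0.5 * params.frame_interval_s, params.frame_interval_s)
    if curvature_tau_s is None:
        value = slope * t
    else:
        if curvature_tau_s < 90.0:
            raise ValueError("curvature_tau_s < 90 s would bend the regression window")
        value = slope * curvature_tau_s * (1.0 - np.exp(-t / curvature_tau_s))
    if params.noise_sd > 0:
        value = value + params.rng().normal(0.0, params.noise_sd, size=t.size)
    return PolymerizationTrace(time_s=t, value=value, condition=cond)


# ---------------------------------------------------------------------------
# Single-filament TIRF traces


@dataclass(frozen=True)
class FilamentEventSpec:
    """Generating parameters for formin events on a growing filament.

    v_base is the profilin-actin elongation velocity; a formin binding
    event pauses growth for an exponential dwell (mean ``pause_mean_s``,
    apparent slope drawn uniformly inside the detector's pause band) and
    then elongates at ``v_burst`` for an exponential run length (mean
    ``run_length_mean_um``).
    """

    v_base: float = 13.0
    binding_rate_per_s: float = 0.005
    pause_mean_s: float = 11.8
    run_length_mean_um: float = 1.10
    v_burst: float = 39.0
    pause_band: tuple[float, float] = (-10.0, 5.0)
    paired_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.pause_mean_s <= 0 or self.run_length_mean_um <= 0:
            raise ValueError("event means must be > 0")
        if self.binding_rate_per_s < 0:
            raise ValueError("binding_rate_per_s must be >= 0")
        if self.v_burst <= self.v_base:
            raise ValueError("v_burst must exceed v_base")
        if self.pause_band[0] >= self.pause_band[1]:
            raise ValueError("pause_band must be an increasing interval")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str  # baseline | pause | burst
    start_s: float
    end_s: float
    velocity_su_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FilamentGroundTruth:
    """True event timeline and generating parameters of one trace."""

    events: list[GroundTruthEvent]
    spec: FilamentEventSpec

    def of_kind(self, kind: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def pause_durations_s(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.of_kind("pause")])

    @property
    def run_lengths_um(self) -> np.ndarray:
        return np.array(
            [e.duration_s * e.velocity_su_s / SUBUNITS_PER_UM for e in self.of_kind("burst")]
        )


def simulate_filament_trace(
    spec: FilamentEventSpec,
    duration_s: float,
    params: SimulationParams,
    *,
    initial_length_su: float = 500.0,
    su_per_um: float = SUBUNITS_PER_UM,
    rng: np.random.Generator | None = None,
) -> tuple[FilamentTrace, FilamentGroundTruth]:
    """Simulate one piecewise-linear filament growth trajectory.

    Baseline growth at ``spec.v_base`` is interrupted by formin events
    arriving as a Poisson process (rate ``binding_rate_per_s`` during
    baseline growth).  Gaussian measurement noise of ``params.noise_sd``
    subunits is added independently per frame.  Pass an explicit ``rng``
    to draw several traces from one reproducible stream.
    """
    if duration_s < 10 * params.frame_interval_s:
        raise ValueError("duration_s must cover at least 10 frames")
    gen = params.rng() if rng is None else rng

    events: list[GroundTruthEvent] = []
    t = 0.0
    while t < duration_s:
        if spec.binding_rate_per_s > 0:
            wait = gen.exponential(1.0 / spec.binding_rate_per_s)
        else:
            wait = math.inf
        base_end = min(t + wait, duration_s)
        if base_end > t:
            events.append(GroundTruthEvent("baseline", t, base_end, spec.v_base))
        t = base_end
        if t >= duration_s:
            break
        if gen.uniform() < spec.paired_fraction:
            pause_dur = gen.exponential(spec.pause_mean_s)
            pause_v = gen.uniform(*spec.pause_band)
            pause_end = min(t + pause_dur, duration_s)
            events.append(GroundTruthEvent("pause", t, pause_end, pause_v))
            t = pause_end
            if t >= duration_s:
                break
        run_um = gen.exponential(spec.run_length_mean_um)
        burst_dur = run_um * su_per_um / spec.v_burst
        burst_end = min(t + burst_dur, duration_s)
        events.append(GroundTruthEvent("burst", t, burst_end, spec.v_burst))
        t = burst_end

    frames = np.arange(0.0, duration_s + 0.5 * params.frame_interval_s, params.frame_interval_s)
    # integrate the piecewise-constant velocity up to each frame time
    breaks = np.array([e.start_s for e in events] + [events[-1].end_s])
    vels = np.array([e.velocity_su_s for e in events])
    seg_growth = vels * np.diff(breaks)
    cum_at_break = np.concatenate([[0.0], np.cumsum(seg_growth)])
    idx = np.clip(np.searchsorted(breaks, frames, side="right") - 1, 0, vels.size - 1)
    length = initial_length_su + cum_at_break[idx] + vels[idx] * (frames - breaks[idx])
    if params.noise_sd > 0:
        length = length + gen.normal(0.0, params.noise_sd, size=frames.size)
    length = np.maximum(length, 0.0)
    trace = FilamentTrace(time_s=frames, length_su=length)
    return trace, FilamentGroundTruth(events=events, spec=spec)


# ---------------------------------------------------------------------------
# Cosedimentation lanes


def saturating_fraction(
    conc_nm: np.ndarray | float, baseline_pct: float, max_pct: float, half_sat_nm: float
) -> np.ndarray | float:
    """Hyperbolic pellet-fraction dose curve (percent)."""
    c = np.asarray(conc_nm, dtype=float)
    out = baseline_pct + (max_pct - baseline_pct) * c / (c + half_sat_nm)
    return float(out) if np.isscalar(conc_nm) else out


def simulate_gel_lanes(
    concs_nm: list[float],
    max_pelleted_pct: float,
    half_sat_nm: float,
    params: SimulationParams,
    *,
    baseline_pct: float = 5.0,
    total_intensity: float = 1000.0,
    construct_id: str = "",
) -> list[GelLane]:
    """Simulate supernatant/pellet band intensities along a formin dose series.

    Before noise, total intensity per lane is conserved and the pellet
    fraction follows baseline + (max - baseline) * c / (c + half_sat).
    Multiplicative Gaussian noise (sd = ``params.noise_sd``, fractional)
    is applied per band.
    """
    if not 0.0 <= max_pelleted_pct <= 100.0:
        raise ValueError("max_pelleted_pct must lie in [0, 100]")
    if any(c < 0 for c in concs_nm):
        raise ValueError("concentrations must be >= 0")
    if half_sat_nm <= 0:
        raise ValueError("half_sat_nm must be > 0")
    gen = params.rng()
    lanes = []
    for c in concs_nm:
        frac = saturating_fraction(float(c), baseline_pct, max_pelleted_pct, half_sat_nm) / 100.0
        pellet = total_intensity * frac
        sup = total_intensity - pellet
        if params.noise_sd > 0:
            pellet *= max(0.0, 1.0 + gen.normal(0.0, params.noise_sd))
            sup *= max(0.0, 1.0 + gen.normal(0.0, params.noise_sd))
        lanes.append(
            GelLane(
                formin_conc_nm=float(c),
                supernatant_intensity=sup,
                pellet_intensity=pellet,
                construct_id=construct_id,
            )
        )
    return lanes


# ---------------------------------------------------------------------------
# Sarcomere linescans


def simulate_linescan(
    spacing_um: float,
    n_sarcomeres: int,
    zline_width_um: float,
    pixel_um: float,
    params: SimulationParams,
    *,
    peak_amplitude: float = 100.0,
    baseline: float = 10.0,
    margin_um: float | None = None,
) -> tuple[Linescan, np.ndarray]:
    """Simulate a myofibril linescan of periodic Gaussian Z-line peaks.

    ``n_sarcomeres`` sarcomeres produce ``n_sarcomeres + 1`` Z-line peaks
    spaced ``spacing_um`` apart (0 sarcomeres -> flat profile).  Returns
    the scan and the true peak positions.
    """
    if n_sarcomeres < 0:
        raise ValueError("n_sarcomeres must be >= 0")
    if spacing_um <= 2 * zline_width_um:
        raise ValueError("spacing_um must exceed twice the Z-line width")
    if pixel_um > spacing_um / 4:
        raise ValueError("pixel_um too large: profile would be undersampled")
    if margin_um is None:
        margin_um = spacing_um
    n_peaks = n_sarcomeres + 1 if n_sarcomeres > 0 else 0
    extent = 2 * margin_um + max(n_peaks - 1, 0) * spacing_um
    pos = np.arange(0.0, extent + 0.5 * pixel_um, pixel_um)
    peaks = margin_um + spacing_um * np.arange(n_peaks)
    sigma = zline_width_um / 2.355  # FWHM -> sd
    intensity = np.full(pos.size, baseline)
    for p in peaks:
        intensity = intensity + peak_amplitude * np.exp(-0.5 * ((pos - p) / sigma) ** 2)
    if params.noise_sd > 0:
        intensity = intensity + params.rng().normal(0.0, params.noise_sd, size=pos.size)
    return Linescan(position_um=pos, intensity=intensity, pixel_um=pixel_um), peaks


# ---------------------------------------------------------------------------
# Contractility motion traces


@dataclass
class MotionGroundTruth:
    """True beat schedule of one simulated motion trace."""

    contraction_times_s: np.ndarray
    relaxation_times_s: np.ndarray
    out_of_sync: np.ndarray  # boolean per beat
    v_contract: float
    v_relax: float
    rhythmic: bool = field(default=True)


def simulate_motion_trace(
    beat_period_s: float,
    v_contract: float,
    v_relax: float,
    jitter_sd_s: float,
    n_out_of_sync_per_10s: int,
    duration_s: float,
    params: SimulationParams,
    *,
    fps: float = 30.0,
    intra_duplex_gap_s: float = 0.2,
    peak_width_s: float = 0.05,
    displacement_frac: float = 0.65,
    roi_id: str = "roi0",
) -> tuple[MotionTrace, MotionGroundTruth]:
    """Simulate a cardiomyocyte motion-speed trace of beat duplexes.

    Each beat is a contraction peak (amplitude ``v_contract``) followed
    ``intra_duplex_gap_s`` later by a relaxation peak (``v_relax``).
    Out-of-sync beats are displaced off the periodic grid by
    ``displacement_frac`` of the period -- beyond the 50% inter-beat
    tolerance the rhythmicity rule uses.
    """
    if beat_period_s <= 0:
        raise ValueError("beat_period_s must be > 0")
    if v_contract < 0 or v_relax < 0:
        raise ValueError("velocities must be >= 0")
    if duration_s < beat_period_s:
        raise ValueError("duration_s must cover at least one beat")
    gen = params.rng()
    beat_times = np.arange(beat_period_s / 2, duration_s - intra_duplex_gap_s, beat_period_s)
    if jitter_sd_s > 0:
        beat_times = beat_times + gen.normal(0.0, jitter_sd_s, size=beat_times.size)
    out_flags = np.zeros(beat_times.size, dtype=bool)
    n_windows = max(1, int(duration_s // 10))
    n_displace = n_out_of_sync_per_10s * n_windows
    if n_displace > 0 and beat_times.size > 2:
        # displace interior beats, spread evenly so each 10 s window gets its share
        candidates = np.arange(1, beat_times.size - 1)
        chosen = gen.choice(candidates, size=min(n_displace, candidates.size), replace=False)
        for i in chosen:
            beat_times[i] += displacement_frac * beat_period_s * gen.choice([-1.0, 1.0])
            out_flags[i] = True
        order = np.argsort(beat_times)
        beat_times, out_flags = beat_times[order], out_flags[order]
    relax_times = beat_times + intra_duplex_gap_s

    t = np.arange(0.0, duration_s, 1.0 / fps)
    speed = np.zeros(t.size)
    for bt, rt in zip(beat_times, relax_times):
        speed += v_contract * np.exp(-0.5 * ((t - bt) / peak_width_s) ** 2)
        speed += v_relax * np.exp(-0.5 * ((t - rt) / peak_width_s) ** 2)
    if params.noise_sd > 0:
        speed = speed + gen.normal(0.0, params.noise_sd, size=t.size)
    speed = np.maximum(speed, 0.0)
    trace = MotionTrace(time_s=t, speed_um_s=speed, roi_id=roi_id)
    gt = MotionGroundTruth(
        contraction_times_s=beat_times,
        relaxation_times_s=relax_times,
        out_of_sync=out_flags,
        v_contract=v_contract,
        v_relax=v_relax,
        rhythmic=n_out_of_sync_per_10s <= 1,
    )
    return trace, gt
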