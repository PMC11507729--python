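"""Shared domain containers for assay traces and conditions.

Concentration conventions follow standard actin biochemistry usage:
formin (dimer) and barbed-end concentrations in nM, actin and profilin in
uM, fluorescence in arbitrary units (a.u.), filament lengths in actin
subunits unless a micron conversion is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical actin filament geometry: subunits of G-actin per micron of
#: filament (two-start helix, 2.7 nm rise per subunit).
SUBUNITS_PER_UM = 370.0


@dataclass(frozen=True)
class AssayCondition:
    """One biochemical assay condition (construct + concentrations)."""

    construct_id: str = "actin-alone"
    formin_conc_nm: float = 0.0
    actin_conc_um: float = 4.0
    profilin_conc_um: float = 0.0
    labeled_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("formin_conc_nm", "actin_conc_um", "profilin_conc_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Reproducibility and noise settings shared by all generators."""

    seed: int = 0
    noise_sd: float = 0.0
    frame_interval_s: float = 2.5

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PolymerizationTrace:
    """Bulk pyrene fluorescence versus time under one condition."""

    time_s: np.ndarray
    value: np.ndarray
    condition: AssayCondition = field(default_factory=AssayCondition)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape:
            raise ValueError("time_s and value must have equal length")
        if self.time_s.size < 20:
            raise ValueError("trace must contain at least 20 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("trace values must be finite")

    @property
    def n(self) -> int:
        return int(self.time_s.size)


@dataclass
class FilamentTrace:
    """Single-filament length (subunits) versus time from TIRF imaging."""

    time_s: np.ndarray
    length_su: np.ndarray
    filament_id: str = "f0"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.length_su = np.asarray(self.length_su, dtype=float)
        if self.time_s.shape != self.length_su.shape:
            raise ValueError("time_s and length_su must have equal length")
        if self.time_s.size < 8:
            raise ValueError("filament trace must contain at least 8 frames")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class GelLane:
    """Integrated supernatant/pellet band intensities for one lane."""

    formin_conc_nm: float
    supernatant_intensity: float
    pellet_intensity: float
    construct_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.formin_conc_nm < 0:
            raise ValueError("formin_conc_nm must be >= 0")
        if self.supernatant_intensity < 0 or self.pellet_intensity < 0:
            raise ValueError("band intensities must be >= 0")


@dataclass
class Linescan:
    """1-D intensity profile along a myofibril, perpendicular to Z-lines."""

    position_um: np.ndarray
    intensity: np.ndarray
    pixel_um: float

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position_um.shape != self.intensity.shape:
            raise ValueError("position_um and intensity must have equal length")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be > 0")
        if self.position_um.size >= 2:
            steps = np.diff(self.position_um)
            if np.any(steps <= 0) or not np.allclose(steps, self.pixel_um, rtol=1e-6):
                raise ValueError("position_um must advance uniformly by pixel_um")


@dataclass
class MotionTrace:
    """Per-ROI motion speed versus time from contractility video analysis."""

    time_s: np.ndarray
    speed_um_s: np.ndarray
    roi_id: str = "roi0"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed_um_s = np.asarray(self.speed_um_s, dtype=float)
        if self.time_s.shape != self.speed_um_s.shape:
            raise ValueError("time_s and speed_um_s must have equal length")
        if np.any(self.speed_um_s < 0):
            raise ValueError("speeds must be >= 0")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])
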