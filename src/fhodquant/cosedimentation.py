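"""Low-speed cosedimentation (bundling) quantification.

Percent actin pelleted per lane from integrated supernatant/pellet band
densitometry, and dose-response summaries with an optional saturating
(hyperbolic) fit for cross-construct comparison.  The hyperbolic form is
a module choice for comparing curves; the underlying assay only yields
per-dose points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .types import GelLane

__all__ = ["DosePoint", "SaturatingFit", "percent_pelleted", "bundling_curve"]


@dataclass(frozen=True)
class DosePoint:
    conc_nm: float
    mean_pct: float
    sd_pct: float | None
    n: int


@dataclass(frozen=True)
class SaturatingFit:
    baseline_pct: float
    max_pct: float
    half_sat_nm: float

    def predict(self, conc_nm: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(conc_nm, dtype=float)
        out = self.baseline_pct + (self.max_pct - self.baseline_pct) * c / (c + self.half_sat_nm)
        return float(out) if np.isscalar(conc_nm) else out


def percent_pelleted(lane: GelLane, background: float = 0.0) -> float:
    """Percent actin in the pellet: 100 * P / (P + S) after optional
    constant background subtraction per band."""
    p = max(lane.pellet_intensity - background, 0.0)
    s = max(lane.supernatant_intensity - background, 0.0)
    if p + s <= 0:
        raise ValueError("pellet and supernatant intensities are both zero")
    return 100.0 * p / (p + s)


def bundling_curve(
    lanes: list[GelLane],
    *,
    background: float = 0.0,
    fit: bool = False,
) -> tuple[list[DosePoint], SaturatingFit | None]:
    """Per-dose mean +/- SD of percent pelleted, sorted by concentration.

    With ``fit=True`` a hyperbolic saturating curve is least-squares
    fitted through the per-lane points (needs >= 3 distinct doses).
    Mismatched replicate counts across doses only warn.
    """
    if len({lane.formin_conc_nm for lane in lanes}) < 2:
        raise ValueError("need at least 2 distinct doses")
    by_conc: dict[float, list[float]] = {}
    for lane in lanes:
        by_conc.setdefault(lane.formin_conc_nm, []).append(percent_pelleted(lane, background))
    counts = {len(v) for v in by_conc.values()}
    if len(counts) > 1:
        warnings.warn("unequal replicate counts across doses", stacklevel=2)
    points = []
    for conc in sorted(by_conc):
        vals = np.array(by_conc[conc])
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
        points.append(DosePoint(conc, float(np.mean(vals)), sd, vals.size))

    sat_fit = None
    if fit:
        if len(by_conc) < 3:
            raise ValueError("saturating fit needs at least 3 distinct doses")
        concs = np.array([lane.formin_conc_nm for lane in lanes], dtype=float)
        pcts = np.array([percent_pelleted(lane, background) for lane in lanes])

        def model(c, b0, m, h):
            return b0 + (m - b0) * c / (c + h)

        p0 = [float(points[0].mean_pct), float(points[-1].mean_pct), max(np.median(concs), 1e-6)]
        popt, _ = optimize.curve_fit(
            model, concs, pcts, p0=p0,
            bounds=([0.0, 0.0, 1e-9], [100.0, 100.0, np.inf]), maxfev=10000,
        )
        sat_fit = SaturatingFit(float(popt[0]), float(popt[1]), float(popt[2]))
    return points, sat_fit
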