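# fhodquant

Quantification pipeline for formin-driven actin assembly biochemistry
and cardiomyocyte sarcomere function, built around the FHOD3 family of
formins.

Formins nucleate actin filaments and processively track their growing
barbed ends.  FHOD3L, the cardiac formin, is unusual: it pauses
elongation while capping the barbed end (~12 s on average), then
elongates in short, fast bursts (~39 subunits/s over a characteristic
run length of ~1 μm) before detaching — and this elongation activity,
rather than nucleation or bundling, is what cardiomyocyte sarcomeres
depend on.  Quantifying that behaviour takes five assay modalities, and
this package implements the analysis for all of them:

* **pyrene_kinetics** — bulk pyrene-actin assembly curves: the slope at
  t_1/8 (time to one-eighth completion) as the nucleation statistic,
  specific activity from its dose dependence, seeded-elongation rates,
  and barbed-end affinity (K_app) from the tight-binding quadratic fit
  r = a + b·(S − √(S² − 4[BE][F])), S = [BE] + [F] + K_d;
* **filament_events** — single-filament TIRF traces segmented into
  baseline growth, capping pauses (> 5 s, slope in −10..5 subunits/s)
  and elongation bursts (r² > 0.5), with run lengths, pause durations
  and pause→burst pairing;
* **cosedimentation** — percent actin pelleted in low-speed bundling
  assays and saturating dose curves;
* **sarcomere_morphometry** — Z-line peak detection on myofibril
  linescans, sarcomere lengths/counts under the ≥ 3-consecutive-Z-lines
  ≥ 0.70 μm rule, expression cutoffs, expression-vs-metric correlation;
* **contractility** — beat-duplex detection on motion-speed traces,
  maximal contraction/relaxation velocities, and rhythmicity (≤ 1
  out-of-sync beat per 10 s);
* **stats_compare** — the comparison protocol: 2.5% tail trimming for
  n > 20, Shapiro-Wilk-gated t-test / Mann-Whitney U with Bonferroni
  correction, ANOVA + Tukey HSD;
* **synthetic_data** — ground-truth generators for all five modalities,
  so every estimator is validated by parameter recovery.

See `docs/methods.md` for models, defaults, corrections and
limitations.

## Worked example

Recover a barbed-end affinity from a synthetic seeded-elongation dose
series, then segment a simulated TIRF ensemble:

```python
import numpy as np
from fhodquant import synthetic_data as sd, pyrene_kinetics as pk, filament_events as fe
from fhodquant.types import AssayCondition, SimulationParams

params = SimulationParams(seed=11, noise_sd=0.0, frame_interval_s=5.0)
ref = sd.simulate_seeded_elongation(AssayCondition(), 0.47, 0.1, 1.0, 0.2, 200.0, params)
points = []
for c in [0.0, 0.06, 0.12, 0.25, 0.5, 1.0, 2.0, 4.0, 10.0]:
    tr = sd.simulate_seeded_elongation(
        AssayCondition(formin_conc_nm=c), 0.47, 0.1, 1.0, 0.2, 200.0, params)
    rate, norm = pk.seeded_elongation_rate(tr, ref)
    points.append((c, norm))
fit = pk.fit_quadratic_binding(points, barbed_ends_nm=0.1)
print(f"K_app = {fit.k_app_nm:.3f} +/- {fit.k_app_se:.3f} nM")

spec = sd.FilamentEventSpec()          # pause 11.8 s, burst 39 su/s, run 1.10 um
tirf = SimulationParams(seed=11, noise_sd=5.0, frame_interval_s=2.5)
gen = tirf.rng()
cfg = fe.SegmentationConfig()
events = [fe.segment_trace(sd.simulate_filament_trace(spec, 600.0, tirf, rng=gen)[0], cfg)
          for _ in range(100)]
s = fe.summarize_events(events, cfg=cfg, frame_interval_s=2.5)
print(f"bursts: {s.n_bursts}, velocity {s.burst_rate_median:.1f} su/s, "
      f"run length {s.run_length_corrected_um:.2f} um, pause {s.pause_mean_corrected_s:.1f} s")
```

Output:

```
K_app = 0.470 +/- 0.000 nM
bursts: 140, velocity 38.9 su/s, run length 1.04 um, pause 11.4 s
```

The fitted K_app reproduces the generating 0.470 nM exactly on
noiseless data, and the segmentation recovers the generating burst
velocity (39 subunits/s), run length (1.10 μm, here 1.04 ± sampling
error over 140 events) and mean pause (11.8 s) after the documented
detection-floor corrections.

A command-line interface mirrors the library
(`fhodquant simulate|pyrene|tirf|bundling|sarcomere|beats|stats`), e.g.

```sh
fhodquant simulate tirf --duration-s 600 --seed 3 --out trace.csv
fhodquant tirf segment trace.csv
```

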