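# Methods

`fhodquant` quantifies the biochemistry of FHOD3-family formins (actin
nucleation, barbed-end capping, processive elongation, bundling) and the
cellular phenotypes they control in cardiomyocytes (sarcomere
morphometry, contraction rhythmicity).  Every analysis stage is paired
with a synthetic-data generator with exactly known ground truth, so the
whole pipeline is testable by parameter recovery without any external
data.  This note records the models, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not demonstrate.

## Bulk pyrene kinetics

**Model.** Bulk assembly curves are *phenomenological* logistic sigmoids
F(t) = P / (1 + e^(−k(t − t_mid))).  The quantities the analysis
extracts are summary statistics of curve shape — the time to one-eighth
completion (t_1/8) and the slope there — and the logistic gives exact
analytic control over them: at completion fraction f the derivative is
k·P·f·(1−f), so k is chosen in closed form from the requested
slope-at-t_1/8.  A mechanistic mass-action model is deliberately not
used: the pipeline's claims are about the estimators, not about
polymerization mechanism.

**t_1/8 estimation.** Completion is measured between a baseline (mean
of the first 2% of samples) and a plateau (mean of the last 5%), both
configurable; the threshold crossing is linearly interpolated.  The
slope at t_1/8 is an ordinary least-squares fit over a centered window
(default 10 frames).  A finite window on a convex curve biases the
slope by ≈ 0.034·(k·w/2)² relative; keep the window below ~0.1 of the
rise time (the synthetic benchmarks sample 1000 frames per half-rise,
making this bias < 0.1%).

**Specific nucleation activity** is the OLS slope of slope-at-t_1/8
versus formin concentration (nM, dimer), requiring ≥ 3 distinct doses.

**Seeded elongation and the tight-binding fit.** Elongation rates are
OLS slopes over the first 90 s, normalized to an actin-alone reference.
Normalized rates versus formin concentration are fitted to

    r = a + b·(S − sqrt(S² − 4·[BE]·[F])),   S = [BE] + [F] + K_d,

the quadratic (ligand-depletion) binding model appropriate when K_d is
comparable to the ~0.1 nM barbed-end concentration.  The bracket equals
2·[BE]·θ (θ = occupancy), so b absorbs 1/(2[BE]) and the bound/free
rate difference.  Fitting is trust-region nonlinear least squares with
K_d ≥ 0, multistarted from 6 log-spaced K_d guesses (10⁻³–10² nM);
standard errors come from the Jacobian.  Flat dose responses return
b ≈ 0 with a very wide K_d standard error (`identifiable = False`)
rather than an error.

## Single-filament (TIRF) event segmentation

**Generator.** Filament length grows piecewise linearly: baseline
profilin-actin elongation (default 13 subunits/s) interrupted by
Poisson-arriving formin events.  An event is a capping pause
(exponential duration, mean 11.8 s; apparent slope drawn uniformly in
the detector's pause band) followed by a processive burst at 39
subunits/s whose run length is exponential with mean 1.10 μm; with
probability 1 − 0.95 the pause is skipped.  These defaults are the
published FHOD3L-CT values; the exponential forms are the memoryless
null for single-step detachment, and only means ± SD are reported for
the real data, so nothing richer is warranted.  Gaussian measurement
noise (default 5 subunits ≈ 14 nm per frame) is added per frame at the
2.5-s frame interval; lengths convert at 370 subunits/μm (canonical
filament geometry, configurable).

**Detector.** Per-interval velocities (Δlength/Δtime between adjacent
frames) are classified against two cuts: pause-like below a cut midway
between the pause band's upper edge (+5 su/s) and the baseline rate;
burst-like above a threshold set in two passes — first adaptively
(baseline + 2 robust SD of interval velocities), then midway between
the baseline rate and the fitted burst velocity.  The midpoint
thresholds make each changepoint interval join whichever side it
majority-overlaps, so event spans are unbiased to about half a frame.
Isolated single-interval label flips are closed morphologically.
Candidate events must satisfy the field's criteria: pauses last more
than 5 s with a fitted slope within −10..+5 subunits/s (the band is
applied to the *event* fit, where noise has averaged out, not to single
noisy intervals); bursts last more than 5 s, exceed the burst threshold
on the full-run fit, and have r² > 0.5.  Burst velocity is fitted on
interior frames only (boundary frames are mixtures); run length sums
interior intervals plus sub-frame junction contributions recovered by
inverting the velocity mixture of each boundary interval.  Events tile
the trace exactly; events touching a trace end are flagged censored and
excluded from duration statistics.

**Truncation/efficiency corrections.** Detected durations are quantized
to the frame grid and must strictly exceed the 5-s minimum, so the
smallest detectable true duration is 5 + dt/2.  For exponential
durations, left truncation shifts the mean by exactly the threshold
(memorylessness), so the generating means are estimated as
mean(detected) − (5 + dt/2) for pauses, and analogously for run lengths
with the floor expressed in μm through the burst velocity.  The paired
fraction is corrected for the visibility of short pauses: a pause is
seen by the pairing rule only if it majority-occupies one frame
interval, which for exponential pauses at uniform phase happens with
probability (τ/dt)(1 − e^(−dt/τ)).  The burst-velocity location
estimate is the median of per-event interior slopes: boundary-
contaminated short bursts create a one-sided low tail that would pull
the arithmetic mean down by ~0.3% (both are reported).

**Known limitations.** The detection floor is soft (a duration near the
threshold is detected with probability between 0 and 1), so the
run-length correction retains a residual bias of roughly −3 to −5% at
the default conditions; recovered pause means scatter without
systematic bias.  With pause slopes drawn uniformly across the full
−10..+5 band, pauses whose slope sits within ~1 su/s of a band edge are
occasionally rejected by the event-level band test; this removes whole
events, not durations, so it does not bias the mean.  Passing the
synthetic benchmarks demonstrates correct estimator behaviour under the
generator's assumptions (piecewise-linear growth, exponential dwells,
white Gaussian noise); it does not certify performance on real
kymographs with intensity fluctuations, drift, or tracking errors.

## Cosedimentation

Percent pelleted is 100·P/(P+S) from integrated band intensities, with
an optional constant background subtraction per band.  Dose curves are
per-dose mean ± SD; an optional hyperbolic saturating fit
(baseline + (max − baseline)·c/(c + c_half)) supports cross-construct
comparison.  The hyperbola is a module choice for summarizing curves —
the assay itself yields only points.

## Sarcomere morphometry

Z-line peaks on myofibril linescans are local maxima above a prominence
floor (default 3× the MAD-based noise level) separated by ≥ 1.0 μm,
refined to sub-pixel positions by parabolic interpolation.  Inclusion
rules: runs of ≥ 3 consecutive Z-lines each ≥ 0.70 μm long contribute
(run − 1) sarcomere lengths; cells are retained when their expression
intensity is strictly above the lower cutoff and at most the upper
cutoff (default 2700 a.u./μm²) and they contain 1–2 nuclei.  The
boundary conventions (strict lower, inclusive upper) are documented and
configurable.  Z-line widths and thin-filament lengths are accepted as
measured inputs; estimating them from 2-D images is out of scope.

## Contractility

Beats appear as contraction/relaxation peak duplexes on motion-speed
traces (30 fps default).  Peaks above a threshold (default: 20% of the
speed range above the 10th percentile) are paired into duplexes by
smallest-gap-first matching under a gap threshold placed between the
quartiles of the inter-peak gaps; pairing only happens when the gaps
are clearly bimodal (P75 ≥ 2·P25), so single-peak trains are left as
contraction-only events.  Rhythmicity follows the rule "no more than
one out-of-sync beat per 10-s window", operationalized by walking the
median-interval grid: the walk re-anchors on each beat that lands
within 50% (configurable) of the median interval of its expected slot;
early/extra beats and empty slots each count once as out of sync.  This
attribution counts a single displaced, dropped, or spurious beat as
exactly one event, which interval-deviation counting does not.
Fewer than 3 beats classifies as arrhythmic, flagged low-n.

## Statistical protocol

When a sample exceeds 20 values, floor(0.025·n) values are removed from
each tail (stable ranks) before testing; trimming precedes the
normality gate.  Each group is gated by Shapiro-Wilk at α = 0.05: two
normal groups → Student's unpaired t-test (Welch optional), otherwise
Mann-Whitney U.  Families of pairwise comparisons use Bonferroni-
corrected α; three or more groups use one-way ANOVA with Tukey HSD
(Tukey p-values are already adjusted and are compared to the family α
directly).  Monte-Carlo calibration at 10,000 null replicates puts the
gated procedure's type-I error at the nominal 0.05 ± 0.01.

## Benchmark problem sizes

The recovery benchmarks in `scripts/acceptance.py` use: 10-point
noiseless dose series for each affinity fit; 5 noiseless bulk traces
(3.75–60 nM, 1000 frames per half-rise) for nucleation activity; a
400-trace TIRF ensemble (600 s per trace, ~600 detected events) at the
published FHOD3L-CT event parameters; a 4-lane noiseless bundling
series; and a 6-peak noiseless linescan at 0.1 μm/pixel.  These sizes
put the sampling error of the stochastic quantities near 4%, well
inside the recovery tolerances, while the full run stays under ten
seconds.
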