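# Methods

This note documents the generative model behind `whiskvr.simulate`, the
analysis conventions, the numerical choices, and what the synthetic tests
do and do not establish about real recordings.

## The session model

All traces live on one frame clock (default 500 frames/s). Event times are
seconds (`frame / frame_rate`); intervals are half open `[t0, t1)`. A
single master seed fans out into named substreams (locomotion, whisking,
outcomes, spikes, tracks, amplitudes), so changing how many draws one
component consumes never perturbs the others; per-neuron spike streams are
further keyed by neuron id.

### Locomotion

Run and rest bouts alternate with exponential lengths (means 30 s and 3 s,
minimums 2 s and 0.5 s). Within a run bout the speed is
`mean_run_speed` (default 23.7 cm/s) plus an AR(1) fluctuation with 2 s
correlation time and stationary s.d. `speed_noise_sd` (1.6 cm/s), clipped
at zero. Rest speed is exactly zero, so "running frames" are
unambiguous; analyses classify running as speed > 1 cm/s.

### Whisking

A shared oscillation drives all whiskers: cycles of a cosine whose
frequency is `whisk_freq` (19 Hz) with 5% multiplicative per-cycle jitter,
so the spectrum has a realistic peak width rather than a pure tone.
Whisk/quiescent bouts alternate (means 12 s / 1.5 s). The whisking
midpoint tracks the surface position through a 200 ms low-pass with gain
`whisk_setpoint_tracking` (5°/cm), emulating the way mice re-aim their
whiskers at a displaced surface. During quiescence the angle rests at the
setpoint. Per-whisker angle = whisker resting setpoint + tracked offset +
oscillation.

### Surface protocol

Locomotor distance is integrated from the speed trace; every
`trial_distance` (200 cm) a trigger fires. At the center position the
outcome is drawn from `outcome_probs` (default equal thirds rostral /
caudal / center; an optional `out` outcome moves the surface outside the
whisker field). Displaced positions return to center at the next trigger,
so draws only ever happen at center — excursion and return movements
alternate. The translation itself is a linear ramp of 1 cm over 250 ms;
the movement profile is configurable because the response is treated as
insensitive to translation velocity.

### Contact geometry and ground truth

Each whisker has a static angular reach interval (resting setpoint ± 4°),
and the surface's axial position maps to azimuth at 10°/cm. The whisker
is *in reach* when the surface azimuth falls inside its interval; *contact*
additionally requires the animal to be whisking. Reach transitions during
surface motion while whisking emit external GoW/LoW events at the crossing
frame; whisking resumption against a stationary in-reach surface emits a
self-generated GoW per in-reach whisker. Repetition indices count from 1
within each (kind, origin, direction) stream. The deliberate subtlety:
the *reach* interval does not follow the tracked setpoint — if it did,
surface translations could never change contact.

### Spiking

Per neuron, the rate is

```
λ(t) = baseline
     + Σ_events k(t − t_ev) · gain · sign(kind) · origin_factor · h(rep)
     + sustained_gain · a(t)
```

with `k` a unit-peak difference-of-exponentials kernel (latency 10 ms,
rise 10 ms, decay 50 ms), `sign(kind)` the ±1 GoW/LoW polarity,
`origin_factor` 1 for external events and `self_attenuation` for
self-generated ones, and `h(rep) = max(0, 1 + habituation_slope·(rep−1))`
applied to external GoW repetitions. The sustained drive `a(t)` is the
preferred-whisker contact mask passed through an exponential rise
(τ = 0.5 s): self-generated touch activity builds over successive whisks
rather than stepping instantaneously, which also keeps the generative
transient and sustained classes distinguishable by the window rules below.
Spikes are drawn by thinning a homogeneous Poisson process at a per-neuron
rate bound, with a 2 ms absolute refractory period.

The refractory period imposes a dead-time compression: the realized rate
is approximately `λ/(1 + λ·r)` with `r` = 2 ms. At the rates used here
this is a few-percent effect on window counts, but it biases *differences*
between high-rate and low-rate conditions; closed-form oracles in the test
suite therefore apply the same transform.

### Population construction

`make_population` builds mixtures: a responsive fraction (default 0.67)
split between transient and sustained classes, the remainder baseline-only.
Responsive neurons receive single-whisker somatotopic preferences in
rotation — without somatotopy, rostral and caudal movements drive
identical responses and direction is undecodable. Default gains: transient
kernel peak 100 spikes/s, sustained 15 spikes/s over a ~10 spikes/s
baseline. The transient default is set so that, after somatotopic dilution
(a neuron responds on roughly half the pooled movements), the per-trial
windowed effect is still a multiple of the baseline window s.d. — the
"strong effect" regime the recovery analyses assume.

### Track rendering

Whisker angles are rendered as four labelled points along a ray from the
face reference point (radii 20–80 px; 1 px = 0.05 mm). Under contact the
shaft becomes a circular arc of curvature `contact_bend` (0.015 1/px,
10 ms smoothed rise), so the Menger curvature of the distal labels
recovers the configured bend exactly; Gaussian label jitter (0.3 px)
models tracking noise.

## Analysis conventions

* **Angle**: `atan2(x − x_face, y_face − y)` in degrees — 0° vertically
  above the face point, positive rostral; works identically in image
  (y-down) coordinates as long as rendering and analysis share it.
* **Band-pass**: 4th-order Butterworth, 1–30 Hz, applied
  forward-backward (zero phase) so onset timing is unbiased. NaN gaps
  ≤ 20 ms are bridged linearly; longer gaps split the trace into
  independently filtered segments.
* **Curvature derivative**: Savitzky–Golay first derivative, cubic
  polynomial, centred 100 ms window; edge frames are fit on truncated
  windows.
* **Touch detection**: candidates where |dκ/dt| exceeds
  `k = 5` robust s.d. (1.4826 × MAD of the whole derivative trace, which
  the no-contact majority dominates); the onset is refined to the frame
  where the curvature excursion from its median first crosses 3 robust
  s.d. (the curvature rise is much sharper than the smoothed derivative);
  the excursion must persist ≥ 10 ms, the 30 ms before the onset must be
  sub-threshold (rejecting contact releases), and onsets within 20 ms
  merge. These defaults were tuned once against simulator ground truth
  and frozen; on held-out seeds recall is 100% within ±10 ms.
* **Windows**: peri-event epoch [−1, +2] s. Baseline 300 ms
  pre-movement; the transient window is selected automatically from the
  population PSTH (50 ms bins): peak bin in (0, 0.6] s, bracketed by the
  nearest local minima (plateaus crossed to the true trough), clamped to
  [0, 0.8] s, with a [0, 0.3] s fallback when no peak exceeds baseline
  mean + 2 s.d.; the sustained window is 300 ms starting 1 s after the
  transient window ends; touch responses use 50 ms post-onset windows;
  modulation indices use 500 ms before and after movement onset, both
  anchored at onset. Events with a same-stream neighbour inside their
  baseline window are excluded.
* **Alignment**: classification windows align to *movement onset* (the
  windows are defined relative to the start of surface movement); touch
  contrasts (external vs self) align to the contact event time.
* **Classification**: one-way ANOVA across the three window-rate groups
  gates at α = 0.05; Tukey studentized-range pairwise comparisons (family
  α = 0.05 over the 3 pairs) then decide: sustained = significant
  baseline–sustained difference; transient = significant
  baseline–transient difference with the transient mean above both other
  means; both/nonresponsive accordingly. Minimum 5 trials per window;
  exact ties short-circuit to nonresponsive.
* **Wilcoxon signed rank**: zero differences dropped; exact null for
  n ≤ 25, continuity-corrected normal approximation above.
* **Drift screen**: first 10 vs last 10 trials, paired by trial order
  within block (sorting before pairing would make the differences
  dependent and break the test's null calibration); α = 0.05; fewer than
  20 trials skips the neuron rather than erroring.
* **Habituation slopes**: OLS of windowed rate against repetition index;
  skipped repetitions are gaps, not zeros. Both raw and
  baseline-subtracted series are available; slope tests use the
  baseline-subtracted series. Population test: one-sided one-sample t
  against a negative mean.
* **Decoding**: rates in 150 ms bins centred every 20 ms (overlapping);
  per-neuron z-scoring fit on the training split only (zero-variance
  neurons pass through as zeros); linear one-vs-rest maximum-margin
  classifier, C = 1 (pluggable); stratified 10-fold CV; each of 50
  resamples redraws the fold assignment; accuracy is zero-one loss on
  held-out trials, s.e.m. over resamples; decision-value ties break to
  the lowest class index. Z-scoring inside the fold avoids leakage and
  changes little under balanced designs.

## Problem sizes

The default test suite runs sessions of 30–600 s with 2–24 neurons; the
population-recovery analyses use 200 neurons with 60 movement events
(≈1900 s of simulated behaviour) and 40+40 movements for the
modulation-index contrast; outcome calibration uses 3000 draws at a 50
frames/s clock (the frame rate only discretizes trigger times, not the
outcome sampler). The full suite completes in about a minute; the
calibration script in a few minutes.

## What the synthetic tests show — and what they don't

The generator reproduces the *statistical structure* the analyses assume:
Poisson-like counts with refractoriness, kernel-shaped transients with
somatotopic selectivity, attenuated self-touch, linear habituation, and a
closed-loop trial protocol. Passing recovery tests therefore demonstrates
that the pipeline is calibrated and unbiased under its own assumptions.
They do not establish robustness to features of real recordings the
generator omits: spike-sorting contamination and unit drift beyond a
linear amplitude trend, bursting and non-Poisson interval structure,
correlated population noise, whisker-tracking dropouts longer than the
interpolation bridge, multi-whisker mechanical coupling, or behavioural
covariates (pupil, posture) that co-modulate firing. The loss-of-contact
response is modelled only as a signed kernel — no suppression dynamics.

## Known limitations

* The NWB import reads the HDF5 layout directly (acquisition series,
  units table, optional behaviour group) and ignores NWB schema versions;
  it maps what exists and leaves the rest empty.
* `find_transient_window` assumes a single dominant response peak; for
  bimodal population responses it brackets the higher peak only.
* The decoder's resample loop refits the classifier per prediction time
  and fold; wall time scales linearly in all three, so exploratory runs
  should reduce `resamples` before `folds`.
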