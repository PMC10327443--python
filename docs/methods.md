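# Methods

This note documents the models, parameter choices, and numerical decisions
behind `voltplace`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signal model

A cell's fluorescence is modeled as

    F(t) = B(t) · F₀ · (1 + a · u(t)),      B(t) = exp(−t/τ_bleach)

where `u(t)` is the membrane-potential proxy in **spike-height units** and
`a` is the fractional fluorescence change per spike (default 0.05, typical
for soma-targeted GEVIs). Because every downstream statistic divides by the
measured spike height, results are invariant to `F₀`, `a`, and any positive
rescaling of the camera counts; the test suite asserts this invariance
explicitly.

`u(t)` is the sum of:

* white Gaussian noise of σ = 1/SNR (SNR default 8.8, the regime of good
  in vivo GEVI recordings; the noise is white at the full 1 kHz bandwidth,
  matching the convention that SNR is quoted against 1 kHz-bandwidth
  baseline noise);
* action potentials: a 0.5 ms-rise / 1.5 ms-decay biexponential template,
  peak-normalized, at inhomogeneous-Poisson times thinned by a 3 ms absolute
  refractory period. The Bernoulli draw rate is dead-time compensated
  (r′ = r/(1 − r·t_ref)) so the realized post-thinning rate equals the
  requested rate — without this the F-I gain would be biased low by ~10% at
  40 Hz;
* theta: **6–10 Hz narrowband Gaussian noise** scaled so its Hilbert-envelope
  mean equals the requested amplitude (9.1% of spike height in-field, 6.5%
  out). A pure sinusoid was rejected because protocol stimuli repeat at
  exactly 1 Hz: an integer number of tone cycles fits every inter-stimulus
  interval, phase-locking "theta" to the stimulus and corrupting
  stimulus-triggered averages. Physiological theta is quasi-periodic, which
  the narrowband process reproduces;
* an in-field depolarizing ramp (default 9.4% of spike height) and plateau
  events (46 ms between half-amplitude points, 58.9% of spike height, soft
  8 ms raised-cosine edges, ≥ 2 riding spikes at ~80 Hz) whose rate follows
  the place-field profile (0.7 Hz at the field center);
* the place field itself: a Gaussian rate profile (peak 12 Hz over a 1.8 Hz
  baseline, σ = width/4 with width 60 cm for natural fields), yielding
  in-field mean rates near 9–10 Hz.

Behavior is a unidirectional 180 cm virtual track: each trial is an
inter-trial interval (1–3 s uniform, position pinned at 0) followed by a
monotone traversal at a smoothed, mean-reverting stochastic speed
(mean 20 cm/s); reward is delivered at the track end on 80% of trials.

### What the generator does not emulate

Motion artifacts (input is assumed motion-corrected), optical crosstalk
between cells, non-exponential or illumination-dependent bleaching,
theta-phase precession of spikes, trial-to-trial field drift, and
correlated (pink) noise. Passing tests therefore demonstrate that the
estimators recover their targets under the stated signal model at realistic
SNR — not that they are robust to every artifact of real movies.

## Stage-by-stage choices

**Photobleach correction** divides by a least-squares fit of
A·exp(−t/τ) + C to the frame-mean series. The offset term keeps the divisor
bounded away from zero on long records. Initialization is log-linear on the
baseline-subtracted means; a fit whose curve is flat to < 10⁻⁴ relative
range (or that fails to converge) falls back to constant normalization with
a logged warning. Correction is idempotent to < 0.1% RMS.

**Segmentation** (PCA/ICA) works per single-cell window: pixel time series
are high-passed at 100 Hz (zero-phase 4th-order Butterworth) so masks are
derived from spike-band activity only, reduced to 5 principal components,
and unmixed with temporal FastICA (up to 3 seed retries on
non-convergence). Each component's spatial map is the regression of the
high-passed pixels on its source; the mask support is map > 3 robust SD
(1.4826 × MAD — an ordinary SD would be inflated by the footprint's own
pixels). Components are accepted when their temporal skewness exceeds 0.5:
the sampling SD of skewness on Gaussian noise is ≈ √(6/T) (≈ 0.045 at 3000
frames), so the threshold sits > 10 SD above the noise expectation while
genuine spiking components score well above 1. Traces are then extracted
from the **unfiltered** movie, preserving subthreshold content.

**Spike detection** high-passes at 50 Hz before thresholding (the spike
band; configurable), estimates σ robustly, and takes one spike per
supra-threshold excursion at its maximum, with a 1 ms minimum separation.
Spike height is measured on the unfiltered trace against the local median
baseline (±4–15 ms around the peak, excluding the spike window), so riding
spikes on plateaus are measured from the plateau top. Sub-sample timing is
not attempted. `noise_sigma` can be supplied explicitly — used when
re-detecting on a spike-removed residual, where re-estimating σ on a trace
whose supra-threshold excursions were interpolated away would bias the
threshold low.

**ΔV_m** is the low-passed, spike-removed trace minus the whole-record mean
(inter-trial intervals included, anchoring ΔV_m ≈ 0 at rest), divided by
spike height.

**Filters.** Both subthreshold filters are 201-tap (200 ms at 1 kHz)
Hamming-window FIR designs applied forward-backward (zero phase, so binned
maps carry no lag; magnitude response |H|²). A 201-tap Hamming kernel has a
~16 Hz transition band, which drives two choices:

* the "<3 Hz" ramp low-pass places its −6 dB edge at 2.5 Hz, which passes
  ≤ 1 Hz content within 2% and attenuates 7 Hz theta to 4.3% — the filter's
  purpose is precisely to exclude theta from the ramp estimate;
* the 6–10 Hz theta band-pass uses the canonical [6, 10] edges. Its
  passband at 8 Hz is exact and 30 Hz is rejected to < 0.1%, but **content a
  few Hz below the band cannot be annihilated by any 200 ms Hamming
  design**: the kernel's mainlobe half-width is ~10 Hz, leaving a ~9%
  amplitude leak at 2 Hz after forward-backward filtering. This is a known
  limitation of the published design, not a tunable defect; the acceptance
  suite records it.

**Complex spikes** are detected on the 20 ms boxcar-smoothed, spike-removed
ΔV_m: excursions above 0.4 spike height qualify, and event boundaries are
then refined at **half the event's smoothed peak**. For a boxcar-smoothed
rectangular depolarization the half-amplitude width equals the true
duration exactly, whereas measuring between the 0.4 crossings would bias a
46 ms/0.59-height plateau to ~39 ms (the threshold sits at 0.68 of the
ramp). Events must exceed 10 ms and contain ≥ 2 detected spikes ("atop
spiking bursts"; the count is a design choice). Amplitude is the smoothed
peak. During Stim epochs the 300 ms evoked depolarizations satisfy the same
definition and are reported alongside spontaneous plateaus.

**Maps.** Bin i covers [i·2.25, (i+1)·2.25) cm, the final bin closed;
samples below 5 cm/s are excluded from occupancy and counting; smoothing is
a 5-point Gaussian (σ = 1 bin) with kernel weights renormalized over
visited bins so unvisited bins propagate as missing rather than zero. SI is
computed on the smoothed map by default (consistent with field detection; a
flag selects the raw map). Peak ties break to the lowest bin.

**Shuffle test.** The firing-rate series is spike counts in 100 ms windows;
each shuffle applies an independent uniform circular shift per trial and the
map and SI are recomputed (fully vectorized across shuffles). A cell is
significant when observed SI strictly exceeds the 95th percentile of 1000
shuffles; measured type-I error on homogeneous cells is ~3.5–5%, inside the
binomial 99% interval around the nominal 5%.

**Anticipatory window.** "10–30 cm before the stimulated location" is
implemented as all bins *overlapping* [stim − 30, stim − 10] cm (bins 26–35
for a 90 cm stimulus under default binning), occupancy-weighted.

**Plasticity sessions** default to Pre 30 / Stim 20 / Post 100 trials
(post epochs of 10–30 min span roughly 50–200 trials; 100 is a mid-range
choice). The induced field is a narrow bump (width 30 cm, i.e. σ = 7.5 cm)
centered 12 cm before the stimulation site — induced fields are sharply
peaked near the induction location, and this width makes the peak-bin
backward-shift estimator reproducible to ±1 bin over 100 Post trials.

**F-I.** Eight intensities from 4.8 to 20 mW/mm², 500 ms steps at 1 Hz, 20
sweeps; rate per intensity is pooled spikes over pooled window time, the
spontaneous rate comes from all samples outside stimulus windows and enters
the fit at I = 0, and the slope is OLS over the 0–17 mW/mm² range.

**Synaptic classification** follows the count/area rule: more than one
evoked spike (window 0–26 ms post onset; a 1–20 ms preset also exists) or
AUC > 0 ⇒ excitatory; no more than one evoked spike and AUC < 0 ⇒
inhibitory. AUC is computed per trial on the spike-removed,
baseline-subtracted (200 ms pre-onset) response over 0–100 ms and averaged
across trials; per-trial-then-average equals averaging first for the mean,
and the window is configurable since neither is pinned down externally.
Twelve test pulses is the protocol denominator the rule was designed for.
Note an inherent property of the rule at ~2.4 Hz spontaneous rates: with 12
trials there is a ~5–10% chance that two spontaneous spikes land inside the
evoked windows, in which case the rule itself labels the cell excitatory.
Such sessions are not "clear-margin": validation therefore requires exact
classification on all sessions whose ground truth is unambiguous (no
chance spike pair in-window for inhibitory cells) rather than on every
random draw. PSP amplitudes are measured on pooled sessions (96 pulses,
matching a pooled 8-cell × 12-trial protocol) from the spike-removed,
non-spiking-trial stimulus-triggered average, smoothed 10 ms before peak
extraction.

**Statistics.** Two-sided paired/two-sample t tests, Kruskal-Wallis for
non-Gaussian data, SEM error ranges, no multiple-comparison correction by
default (Benjamini-Hochberg available). An exactly-constant paired
difference is reported as p = 0 with a `degenerate` flag; an identically
zero difference as statistic 0, p = 1.

## Determinism and problem sizes

All generators draw from `numpy.random.default_rng` seeded by the config;
the pipeline derives every stage's stream from one top-level seed, and a
rerun is bit-identical apart from the report timestamp. Validation sizes —
50 × 30 s noise traces for the false-positive check, 200 cells × 1000
shuffles for test calibration, 20 induction sessions for plasticity
recovery — were chosen so each estimate's Monte-Carlo error is small
against its tolerance while the full suite completes in minutes on one CPU.

## Known limitations

* No overlapping-cell demixing guarantees; segmentation assumes single-cell
  windows.
* The theta band-pass leaks ~9% at 2 Hz (transition-width limit of the
  200 ms Hamming design, discussed above).
* Evoked-spike latency summaries are biased slightly below the generating
  mean because latencies are truncated to the (0, 26] ms window.
* NWB input is not supported; movies travel as TIFF/HDF5 and tabular data
  as CSV.
* The plasticity rule itself (BTSP kernel) is not modeled; the generator
  injects its outcome (a shifted field with elevated rate and ramp).
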