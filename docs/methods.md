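# Methods

This note documents the models, numerical choices and known limitations of
`physioaffect`: the per-window affect-estimation pipeline and the synthetic
cohort generator it is validated on.

## Signal model and preprocessing

Three channels are modeled: skin conductance (GSR, µS, 51.2 Hz), ECG (mV,
250 Hz) and an already-derived respiration-rate channel (breaths/min, 25 Hz;
the emulated chest-strap device reports only a mean rate, not an airflow
waveform).  Times are seconds from session start; windows are half-open
`[start, end)`.

All filters are Butterworth, order 4, applied zero-phase
(`scipy.signal.sosfiltfilt`).  The order is a package choice: 4th order is
standard electrodermal practice, and the zero-phase (forward–backward)
application avoids group delay that would smear features across 0.5-s window
boundaries; the price is that the effective magnitude response is squared
(−6 dB at the cutoff), which the tests account for.  GSR is denoised at
5 Hz, then split into complementary tonic (SCL, low-pass 0.1 Hz) and phasic
(SCR, high-pass 0.1 Hz) components.  Complementary 4th-order filters do not
sum exactly to the identity; the reconstruction tolerance (residual energy
< 5% of the denoised signal on band-limited inputs) is asserted in the
tests.

R peaks are detected on the native 250 Hz ECG (5–15 Hz band-pass energy,
150 ms integration window, adaptive threshold seeded at the 90th height
percentile with one refinement pass, 250 ms refractory period, final
refinement to the local ECG maximum) *before* any resampling.  Derived level
streams — SCL, SCR, piecewise-constant instantaneous HR, respiration rate —
are linearly interpolated onto a shared 36.5 Hz grid; linear interpolation
is exact for affine signals and adequate for these band-limited streams.
Whether filtering should precede or follow grid synchronization is not
dictated by the hardware; this package filters at native rates first, which
preserves the full ECG bandwidth for beat detection.

Baseline normalization subtracts the scalar mean over the rest period
(≥ 30 s required; the default protocol provides 240 s) from the level-type
streams only (SCL, HR, respiration rate).  The phasic SCR is zero-mean by
construction and the raw ECG waveform is not a level signal, so neither is
shifted.

## Features

Per 0.5-s window, 23 named features: SCL and SCR mean/std/min/max/(max−min),
mean first and second SCL derivatives (finite differences scaled by the grid
rate; units µS/s and µS/s²), SCR peak count and peak-amplitude mean/std, HR
mean/std/min/max/(max−min), running sDNN and rMSSD, and mean respiration
rate.  Standard deviations are population (divide by n) throughout — the
convention matters less than applying it consistently.

Two definitions deserve comment because a 0.5-s window cannot contain two
heartbeats:

* `sDNN_mean` / `rMSSD_mean` are running values over a rolling 15-s
  inter-beat-interval buffer ending at the window's end (15 s covers one
  image presentation, and the `_mean` suffix reflects the running nature).
  Intervals outside 200–3000 ms are discarded before either metric.
  Frequency-domain variability metrics are excluded on principle: they need
  minutes of data.
* HR extrema/std are computed over the resampled piecewise-constant
  instantaneous-HR samples inside the window, which works at any window
  length.

SCR peaks are local maxima whose rise from the preceding local minimum
strictly exceeds 0.03 µS (the midpoint of the 0.01–0.05 µS range used in the
electrodermal literature).  When a window contains no peak, `PA_mean` and
`PA_std` are 0 rather than undefined so classifiers always receive complete
vectors.

Windows are tiled without overlap from each image onset; windows during
blank slides and self-assessment are not part of the classification data.

## Labels, problems and evaluation

Ratings on the 1–9 scale map to [−4, 4] via `raw − 5`.  The neutral box is
closed (|v| ≤ 1 ∧ |a| ≤ 1 → N); outside it the axis boundaries follow the
sign conventions v > 0 = high valence, a > 0 = high arousal.  Binary and
4-class problems exclude neutral images.

An image is discarded by the consistency filter only when the participant's
self-assessed quadrant is the *diagonal opposite* of the normative quadrant
(both axis signs flipped, neither point neutral); single-axis disagreement
and neutral self-reports are kept.  This is the weakest defensible reading
of "completely inconsistent"; a stricter any-mismatch rule would discard
far more data.

Splits hold out every window of one image per class (seeded draw).  Feature
ranges, ReliefF weights and the selected set are computed from training
windows only.  Classifiers are scikit-learn pipelines (train-fitted
z-scoring, then distance-weighted KNN with K = 5 and exhaustive neighbour
search, cubic-polynomial or RBF SVM with C = 1 and kernel width 1/n_features
after z-scoring, one-vs-one for multi-class, or LDA).  Exhaustive KNN search
is deliberate: per-query cost then scales with the number of features, so
the estimation-time benefit of feature selection is structural rather than
an artifact of tree construction.  Accuracy is the confusion-matrix trace
over its total; the F-score is the unweighted (macro) mean of per-class
harmonic precision/recall means, appropriate for the balanced image design.
Estimation time is wall-clock per window covering filtering, feature
extraction, subset selection and prediction.  Algorithms are compared by
one-way ANOVA on per-participant accuracies with pairwise significance at
p ≤ 0.05/6 ≈ 0.008 (six comparisons).

## ReliefF

For each instance R (all instances are used, in index order — sampling noise
is pointless at this scale), the weight of attribute A is decreased by the
mean range-normalized difference to the k nearest same-class hits and
increased by the prior-weighted mean difference to the k nearest misses of
each other class, with Manhattan distance on range-normalized features,
ties broken by lowest instance index, and empirical class priors.  Weights
therefore lie in [−1, 1]; zero-range features contribute nothing and get
weight 0.  k defaults to 5.  The implementation is vectorised (chunked
distance matrix) and is verified against a literal neighbour-enumerating
oracle on a thousand random small datasets.

The 5-class quadrant label is the selection target by default (the label
set actually used for selection is configurable); selection runs per
participant on the training split, and features whose median weight across
participants is strictly positive form the optimal set.

## The synthetic cohort

The generator emulates the stimulation protocol — 240 s rest, then the
cluster order LAHV, HALV, HAHV, LALV, N twice, 5 images per cluster, 15-s
images preceded by 5-s blanks and followed by a self-assessment gap drawn
around 8.7 s (clipped to 4.5–11.3 s) — and affect-dependent physiology with
inter-subject variability (tonic level 2–10 µS, heart rate 60–80 bpm,
respiration 12–18 breaths/min, per-channel gains 0.8–1.2, all seeded).
Synthetic image ratings are drawn uniformly inside each image's quadrant
region; self-reports are the true ratings plus ±1 integer noise per axis
with a 10% chance of a diagonal flip, which exercises the consistency
filter.

Default per-quadrant effects (offsets against the neutral/rest condition):

| quadrant | SCL level (µS) | SCL slope (µS/s) | HR (bpm) | SDNN (ms) | RR (breaths/min) |
|----------|---------------:|-----------------:|---------:|----------:|-----------------:|
| HAHV     | +0.80          | +0.004           | +9       | −10       | +3.0             |
| HALV     | +0.50          | +0.0025          | +6       | −7        | +2.0             |
| LAHV     | +0.25          | +0.001           | −4       | +5        | −1.0             |
| LALV     | +0.05          | +0.0005          | −7       | +10       | −2.0             |

High arousal raises tonic level, slope, heart rate and respiration and
lowers interval variability; valence shapes the asymmetry between the two
high-arousal (and the two low-arousal) quadrants.  The SDNN offsets follow
the physiological inverse-square coupling between heart-rate variability
and heart rate (sdnn ∝ 1/HR², evaluated at a nominal 70 bpm / 45 ms): this
makes the magnitude of within-window instantaneous-HR jumps approximately
class-neutral — so `HR_std` and `HR_max_minus_min` carry no usable signal —
while the buffer-level `sDNN_mean`/`rMSSD_mean` remain informative, which
is the intended relevance structure.

Signal synthesis details (all config-exposed):

* **Tonic SCL** shifts are *sustained states* tracking each same-quadrant
  image cluster (raised-cosine rise/decay over 30 s), not per-image blips.
  This is both physiologically sensible (tonic level follows sustained
  arousal) and numerically important: per-image tonic transients occupy
  ~1/15 Hz, close enough to the 0.1 Hz tonic/phasic split that a few percent
  leak into the SCR stream, which would fabricate class information in
  phasic statistics.  Small per-image linear slope ramps provide the
  `SCL_dot` contrast.
* **Phasic SCRs** are a Poisson train with bi-exponential kinetics (0.75 s
  rise, 2.0 s decay) and exponentially distributed amplitudes (mean
  0.05 µS), drawn in inter-stimulus intervals with a 6-s guard before each
  image onset; the evoked in-image rate is zero by default.  This
  implements the default policy that phasic statistics carry *no* class
  information at the window level: because zero-phase filtering is
  non-causal, even class-neutral events near an image bleed small
  deterministic structure into its windows, and any within-image structure
  is exploitable by instance-based feature weighting under a temporally
  blocked protocol (nearest same-class neighbours are latency-matched
  same-image windows; nearest other-class neighbours never are).  Keeping
  in-window phasic content at the measurement-noise floor makes the phasic
  features behave as the noise they are meant to be.
* **ECG** is a Gaussian R-bump train (σ = 10 ms, 2 ms timestamp jitter,
  0.02 mV additive noise) driven by an AR(1) inter-beat process (ρ = 0.5,
  so rMSSD ≈ SDNN) whose mean tracks the modulated heart rate and whose
  stationary spread tracks the modulated SDNN.
* **Respiration** is the subject baseline plus the quadrant offset, slow
  wander (0.05 Hz low-passed noise, 0.3 breaths/min) and white read-out
  noise (0.05 breaths/min).
* **GSR noise** is white, σ = 0.01 µS; tonic drift is a sum of three
  sinusoids with 300–900 s periods and ~0.1 µS total scale.

The *null* configuration zeroes every quadrant offset **and** the slow
class-independent components (drift, respiratory wander).  The second part
matters: under a blocked stimulus design, a leave-one-image-out split still
shares cluster-timescale noise between a held-out image and its same-cluster
neighbours, so any slow autocorrelated component lets classifiers decode
far above chance even with zero affect modulation.  A null meant to verify
chance-level behaviour must therefore be exchangeable at the window level.
For the same reason, statistical null checks in the tests aggregate to
per-image means before two-sample testing — window-level tests are
anticonservative under within-image correlation.

## What passing tests show — and what they do not

The synthetic cohort demonstrates that the pipeline recovers a planted
relevance structure: with the default effects, the cross-participant
median-positive rule retains exactly the 13 modulated features (tonic-level
family, heart-rate level family, the two interval-variability metrics,
respiration rate) and none of the phasic/noise features, classifiers beat
5-class chance by a wide margin, binary problems score above multi-class
ones, and the selected subset never increases estimation time.  None of
this certifies performance on real recordings: real electrodermal and
cardiac signals contain motion artifacts, ectopic beats, non-stationary
baselines and far weaker, subject-specific affect modulation than the
planted effects, and real phasic activity *does* react to stimuli in
class-dependent ways the default generator deliberately avoids.

## Problem sizes used in validation

The bundled checks run the per-window pipeline at full session length
(50 images, ~1400 windows per subject).  The selected-set size check uses
one 20-subject cohort in the test suite and the mode over ten independent
20-subject cohorts in `scripts/acceptance.py`; the replicate
recovery-fraction check uses ten 5-subject cohorts; chance-level and
ordering checks use 6–20 subjects per condition.  These sizes were chosen
to keep a complete validation run in the single-digit minutes on one CPU
while leaving the per-subject data at full scale.

## Known limitations

* No artifact rejection or model-based electrodermal deconvolution; the
  protocol being emulated minimizes motion by design.
* The beat detector assumes R-dominant morphology; P/T waves, ectopy and
  polarity inversions are out of scope (the generator does not produce
  them).
* Estimation-time measurements are wall-clock and environment-dependent;
  only orderings, never absolute latencies, are asserted.
* Per-window ReliefF under a blocked protocol structurally favours features
  with smooth within-session temporal structure (see above); conclusions
  about marginally-weighted features on real blocked designs should be
  drawn with that bias in mind.
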