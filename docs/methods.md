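# Methods

This note records the models, conventions and numerical choices behind
`pulsewave`, in the order the pipeline runs.

## Signal model and ingestion

A transmissive fingertip PPG is treated as a slowly drifting baseline plus a
periodic pulsatile component plus wideband noise. Video frames are reduced
to three per-frame spatial channel means; the three mean series are combined
with weights proportional to each series' temporal standard deviation
(normalized to sum to 1), on the premise that a channel's variance under
constant illumination is dominated by pulsatile blood-volume change. The
weights are computed over the whole recording; no region of interest is
used. YUV input is converted with the BT.601 full-range matrix — the most
common mobile-camera convention — and clipped to [0, 255].

Camera timestamps jitter, so traces are linearly interpolated onto a
uniform grid (default 30 Hz, matching typical phone frame rates) before
filtering. Linear interpolation is exact for locally affine signals and
keeps the pipeline free of resampling ringing.

Two zero-phase Butterworth bands (order 3) are used deliberately:

* **detection band, 0.5–8 Hz** — aggressive low-pass that stabilises peak
  finding;
* **analysis band, 0.5–12 Hz** — morphology measurement. The 8 Hz edge
  shifts the diastolic summit by ~25 ms on sharp waveforms, which is fatal
  for peak-to-peak-time estimates at short reflected-wave lags; the 12 Hz
  edge denoises with ~3× less timing distortion, and residual noise is
  handled by local Savitzky–Golay smoothing at the beat level.

Polarity is auto-corrected by the skewness sign of the detection-band
signal (upright PPG pulses are right-peaked, skewness > 0); the same flip
is applied to both bands.

## Beat segmentation

Systolic peaks are detected with prominence ≥ 0.3 × the robust range
(10th–90th percentile) and a minimum spacing of 0.7 × the dominant period,
where the period is the strongest autocorrelation lag in [0.3, 2.0] s. The
autocorrelation estimate is what prevents large diastolic waves from being
counted as beats — the full beat pattern repeats at the cardiac period
regardless of intra-beat structure. Valleys are the minima between
consecutive peaks (plus edge minima when a leading/trailing segment is at
least 15% of the inter-peak interval). Valley argmin decisions are made on
a 0.15 s-smoothed copy because the beat foot and the dicrotic notch can be
near-equal minima at high heart rates, and raw noise otherwise flips the
choice; beat amplitudes are sliced from the unsmoothed analysis band.
Beats outside 0.3–2.0 s (30–200 bpm) are discarded. Heart rate is
60 / median BBI duration.

**Signal quality.** SQI = (mean Pearson correlation of length-normalized
beats with their median template) × (1 − coefficient of variation of beat
durations), clipped to [0, 1]. The second factor exists because
valley-delimited segments of pure noise still share a generic one-peak
envelope and correlate ≈ 0.55 with their own template; erratic durations
expose them. Samples with SQI < 0.5 are excluded. The index is a declared
surrogate: any monotone quality score honoring the 0.5 gate is
interface-compatible.

## Fiducial landmarks

Within each beat (LV at index 0, RV at the end):

* **ESP** — global maximum of the lightly smoothed beat (beats whose
  maximum sits on a boundary are rejected);
* **DP** — first positive→negative crossing of the smoothed first
  derivative after ESP with negative curvature, accepted only if the
  candidate peak sits at or below ESP and rises out of a preceding notch by
  ≥ 2% of the beat amplitude ("obvious second peak"); the dip test uses a
  heavily smoothed (0.15 s) copy so noise bumps cannot fake dicrotic
  structure. Without an accepted crossing, DP falls back to the
  second-derivative minimum on (ESP, RV) and the beat is flagged
  (`has_second_peak=False`); the flag fraction per sample is the IPP
  feature.
* **DN** — minimum between ESP and DP; **IP** — last positive→negative
  first-derivative crossing at or before the second peak. In a smooth
  two-peak beat that crossing is the DP crossing itself, so IP ≈ DP; with
  no obvious second peak IP is designated as the DN (flagged). This reading
  of the inflection point keeps the fallback flags monotone in reflected-
  wave amplitude and gives the A2 triangle nonzero area; the wording it
  operationalizes is ambiguous, and the choice is isolated in one function.
* **A–H** — alternating second-derivative extrema found by argmax/argmin
  over dependency-ordered windows (A, B before ESP; F on (ESP, RV]; E on
  (ESP, F); H on (F, RV]; G on (F, H); C, D between B and E). Ties break to
  the earliest index; an empty window marks the point, and every feature
  depending on it, missing.

Derivatives are Savitzky–Golay (cubic, ~80 ms window); sub-sample
refinement (linear interpolation at derivative zero crossings, 3-point
parabolas at extrema) removes the 1-sample quantization that would
otherwise dominate PPT error at 30–60 Hz.

## Features

Heights are measured above the LV–RV chord on the lightly smoothed beat.
ERI/EPPT/ESI use a tangent-intersection estimate of the undistorted
systolic peak (tangent at maximal upstroke × tangent at steepest early
decay) to compensate the summit flattening produced by camera
auto-exposure; the construction sits behind one function so alternative
estimators can be substituted. A1 is the shoelace area of the polygon
(LV, ESP, DN, DN-foot) and A2 the triangle (IP, DN, RV), both in
amplitude·seconds.

Spectral features need ≥ 30 s of signal. The Welch PSD (20 s segments)
yields the fundamental as the strongest peak in 0.67–3 Hz; harmonic peaks
are refined within ±0.4·f₀ of each multiple, and Sᵢ integrates the PSD
between the midpoints flanking the i-th peak (the first band starts halfway
between DC and the fundamental). Shares are normalized over harmonics 1–6:
the DC band tracks total energy rather than contour, and harmonics above
the 6th are negligible. NHA = (S₂+…+S₆)/(S₁+…+S₆) is a declared
harmonic-area surrogate. V₀…V₆ come from a least-squares Fourier fit
(sin+cos pairs, amplitudes reported) to the length-normalized median beat.

Durations are multiplied by HR/75 (mapping every beat to the 0.8 s
reference period) and PPT-like transit intervals additionally by
170/height_cm; SI and ESI are recomputed from the normalized intervals at
the reference stature; pure ratios and spectral features are untouched.
Normalizing an already-normalized record at the reference point is the
identity.

Per-sample aggregation is the median over beats, skipping missing values;
a record is flagged incomplete (feature loss) when it has fewer than 5
beats or when any *core* feature is present in under half of them. The
core set covers the robust landmarks (durations, heights, areas, |B/A|,
|F/A|, |H/A|); E/A, G/A, AI, C/D and IHAR are computed when identifiable
but are non-core, because E and G live in few-sample windows (E is pinched
between the systolic apex and the F-wave) and are frequently
unidentifiable at modest sampling rates and SNR — the same identifiability
problem long reported for C and D. IHAR is undefined whenever IPA is 0.

## Statistics

The data are nested: psychological scores are constant within participant
while waveform samples repeat. Two analysis modes are provided.
*Aggregated*: per-participant medians, then OLS — exact small-sample
inference at the cost of within-person information. *Cluster-robust*: OLS
on all observations with CR1 covariance clustered on participant and
two-sided p from t with (G − 2) degrees of freedom; with singleton
clusters this reduces exactly to HC1. CR1 is known to over-reject with few
clusters when regressors are nearly cluster-constant (we measure ≈ 7.5% at
α = 0.05 with 30 clusters, ≈ 5–6% at 113), so calibration checks run at
the cohort scale the package targets (113 × 7); small-G users should
prefer the aggregated mode.

Feature selection works within each domain (time, curvature, frequency):
while any pair exceeds |r| > 0.5, the member of the worst pair with the
larger mean absolute correlation to the remaining features is dropped;
survivors are ranked by mean |r| against the outcome block and the top 2
kept (ranking criterion configurable; outcome-block relevance is the
default). Covariates (systolic blood pressure) pass through, giving the
canonical 2×3+1 = 7-feature set.

The random forest uses 100 trees, squared-error splits, full depth and
bootstrap sampling. Folds are participant-exclusive: unique participants
are shuffled with a seeded generator and split into 5 nearly equal groups,
so no participant contributes to both training and evaluation; per-fold
seeds fan out from the master seed. Out-of-fold predictions are pooled for
MAE and Pearson r; importances are mean-decrease-in-impurity averaged over
folds. Bland–Altman agreement reports bias and bias ± 1.96·SD(differences)
(sample SD); Pearson r accompanies it because correlation alone does not
establish agreement. IQR×1.5 outlier filtering (linear-interpolation
quartiles) is applied per feature across samples before modelling.

## Synthetic data

One beat is the sum of three components on a [0, period) support, wrapped
periodically:

* an asymmetric generalized Gaussian systolic wave, exponent 4 (flat
  rounded summit, steep flanks), rise width 0.07 s and decay width
  0.065 s, centred 0.25 s after the valley — the flat summit matters
  because a plain Gaussian's sharpest curvature sits at its apex, which
  would pin the F-wave to the systolic peak and empty the E-wave's search
  window, a degeneracy measured waveforms do not show;
* a diastolic runoff pedestal (Gaussian, amplitude 0.25, width 0.15 s,
  centred 0.10 s after the systolic peak) that keeps the dicrotic notch
  well above the valley floor so beat boundaries stay unambiguous;
* a reflected wave: a Gaussian of width 0.06 s delayed by
  `reflection_lag` (default 0.26 s) and scaled by `reflection_ratio`
  (default 0.45).

Defaults: period 0.8 s (75 bpm), SNR 20 dB additive Gaussian noise, 0.3
amplitude drift at 0.1 Hz, 60 Hz sampling (oximeter-grade; the frame-stack
generator explicitly emulates ~30 fps video with timestamp jitter and
per-channel gains/noise). Because the components superpose, the landmark
PPT and RI differ slightly from the programmed lag and ratio (the summit
of a wave riding a decaying pedestal shifts early — up to ~15% at short
lags); every train therefore ships a manifest of dense-grid landmark
truth, computed with the same "obvious second peak" rule as the extractor,
and recovery is always measured against the manifest.

Cohorts: participants carry latent waveform parameters (or latent feature
means in the fast parametric mode); samples vary around them; psychological
scores are mid-scale intercepts plus declared slopes times centred
participant-mean features plus noise, integer-rounded and clipped to the
instrument ranges (SWLS 5–35, SVS 7–49, PANAS 10–50, PHQ-9 0–27, GAD-7
0–21, SAM 1–9). The parametric mode exercises the statistical layer at
Monte-Carlo scale; the extract mode runs the full signal pipeline per
sample so features carry realistic extraction error.

What the generator does **not** emulate: heart-rate variability and
respiratory modulation, motion artifacts and contact-pressure changes,
camera auto-exposure dynamics and quantization, skin-tone and perfusion
differences, or any physiologically detailed hemodynamics
(Windkessel-class models are out of scope). Passing the recovery and
calibration suites therefore demonstrates correctness of the algorithms
under the stated beat model and noise, not field performance on real
fingertip video.

## Problem sizes used in the test and acceptance suites

Recovery runs a 5×5 grid of reflection lag (0.18–0.35 s) × ratio
(0.2–0.8) with 10 seeds per cell on 16 s trains at 60 Hz; fiducial-oracle
equivalence checks 1000 beats; calibration uses 200 null cohorts of
113 × 7; leakage checks 50 random grouped splits. These sizes give stable
Monte-Carlo estimates while keeping a full run in tens of seconds.

## Known limitations

* At 30 Hz sampling the A–H landmark separations are sub-sample for sharp
  waveforms; second-derivative features there should be treated as
  unreliable (they feed the feature-loss path rather than biased values).
* The CR1 cluster-robust mode over-rejects below ~50 clusters (see above).
* The "obvious second peak" dip threshold (2% of beat amplitude) is a
  judgement call; beats whose reflected wave hovers at the threshold can
  alternate between the crossing and fallback paths under noise, which is
  visible as a nonzero IPP at intermediate reflection amplitudes.
* ERI/EPPT use a declared tangent-intersection construction; NHA and the
  SQI are declared surrogates. All three are isolated behind single
  functions for substitution.
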