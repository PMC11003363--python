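# Methods

This note documents the models, conventions and numerical choices behind
`pulsewave`, in the spirit of the methods documentation of mature
scientific Python packages.

## Signal model and preprocessing

The analysis object is a single-channel PPG sampled at `fs` (tested at
250–1000 Hz). Preprocessing produces the working set {PPG, PPG′, PPG″,
PPG‴} at the original rate plus a 75 Hz copy for beat detection:

- **Band-pass** — Chebyshev type-II, order 4 (one-way prototype), stop-band
  edges 0.5 and 12 Hz, stop-band attenuation 20 dB, applied
  forward–backward (`sosfiltfilt`). The zero-phase realization squares the
  magnitude response (effective 40 dB) and cancels phase, so extremum
  locations — on which every fiducial definition relies — are not shifted.
  The 0.5 Hz edge suppresses respiratory baseline wander while retaining
  content at 30 bpm; 12 Hz keeps the pulse-wave harmonics that shape the
  onset and notch while excluding noise. A consequence of the type-II
  design is that a constant input is attenuated to the squared stop-band
  floor (10⁻²), not to zero; raising the attenuation would visibly erode
  the passband near 8–12 Hz, so 20 dB is retained.
- **Moving averages** — flat (boxcar) kernels, window `round(width·fs)`
  forced odd for symmetry (zero phase); 50 ms on the signal (~9 Hz
  cut-off), 10 ms after every differentiation stage (~45 Hz). Edges use a
  shrinking window, which is exact on constants.
- **Derivatives** — iterated central differences scaled to per-second
  units (`np.gradient`), each followed by the 10 ms average. Central
  differences preserve extremum positions; one-sided differences would
  bias them by half a sample.
- **Resampling** — Fourier method (`scipy.signal.resample`) to 75 Hz,
  used only by the beat detector to bound its cost on long recordings.

Signals shorter than the filter warm-up raise `ShortSignalError`; the
first and last second of a recording are treated as warm-up and pulses
overlapping them are dropped.

## Beat detection

The detector processes the 75 Hz signal in 10 s windows (2 s overlap
absorbs filter edge transients; duplicate peaks at joins are merged,
keeping the higher amplitude).

1. **Heart-rate estimate.** The window is filtered to 0.5–3.3 Hz
   (zero-phase Chebyshev-II, order 5). If less than 20% of the window's
   spectral power lies in that band, the window carries no usable rhythm
   and the previous estimate is retained (band midpoint if none). The
   period is the shortest autocorrelation-peak lag whose height reaches
   75% of the global maximum over lags corresponding to 30 bpm up to
   1.5× 200 bpm — the biased autocorrelation discounts long lags
   (sub-harmonics), and the 75% rule rejects the sys–dia lag of strong
   diastolic waves. An implied rate outside 30–200 bpm is rejected and the
   previous estimate kept (marked invalid), mirroring the idea that an
   implausible count flags a low-quality segment.
2. **Peak picking.** The window is re-filtered to [0.5, 6·HR/60] Hz; six
   harmonics keep the filtered crest within the ±100 ms refinement window
   of the true peak at all tested rates. Local maxima separated by a
   refractory interval of 0.6 of the HR-implied period are thresholded at
   30% of the 75th percentile of candidate amplitudes (rank-based, hence
   robust to slow amplitude drift).
3. **Refinement.** Indices are mapped to the analysis rate and snapped to
   the local maximum of the filtered PPG within ±100 ms. A final pass
   enforces a minimum inter-beat gap of 60/hr_max.

The detector is deterministic; identical input and configuration give
identical output.

## Segmentation and fiducial points

The onset is defined as the beginning of the systolic upslope: the last
local maximum of PPG‴ preceding the pulse's p1 point. Because p1 is
defined per pulse, a provisional pass resolves the circularity: the PPG
minimum between consecutive systolic peaks anchors a provisional window,
in which a provisional a-wave (last PPG″ maximum before the steepest
upslope point), b-wave and p1 are found; the onset search then runs
backward from p1, starting no earlier than 5% of a period before the
inter-beat minimum. Both guards exist because the inter-beat trough and
the previous beat's diastolic wave carry curvature that can rival the
systolic a-wave. The offset of a pulse is the next pulse's onset, so
retained pulses tile the record; the last beat uses the first subsequent
PPG minimum as an offset surrogate or is dropped.

Detection rules per pulse window [on, off] (sample-discrete; a local
extremum is a sample strictly greater/smaller than its left neighbour and
not worse than its right; plateaus report their first sample; inflections
are zero-crossings with linear sub-sample interpolation, reported at the
nearest sample):

- **u / a** — maxima of PPG′ / PPG″ in [on, sp]; the a-wave search is
  restricted to samples with positive slope.
- **b** — first local minimum of PPG″ after a.
- **e** — highest local maximum of PPG″ in [max(b, sp), on + 0.6·T_pi];
  **f** — first *negative* local minimum of PPG″ after e, within 80% of
  the pulse duration (the negativity requirement rejects ripple in the
  near-flat diastolic tail).
- **c** — highest local maximum of PPG″ in (b, e), else the first PPG‴
  zero-crossing there; **d** — lowest local minimum in (c, e), else the
  first PPG‴ zero-crossing.
- **p1** — first local maximum of PPG‴ after b; **p2** — last local
  minimum of PPG‴ in (b, d], falling back to the d-point when no PPG‴
  minimum is admissible.
- **v** — minimum of PPG′ between u and e; **w** — first local maximum of
  PPG′ after max(e, v) and before f.
- **dn** — a class-1 notch (incisura) is the first PPG minimum after sp
  that is followed by a diastolic rebound of at least 0.5% of the
  systolic amplitude before 80% of the pulse duration — a bare trough
  running into the next upslope is not a notch. Failing that, the rising
  PPG″ zero-crossing between the d-wave (or the systolic region) and the
  e-wave is used, provided the f-wave exists (distinguishing a genuine
  notch inflection from the generic inflection of a monotone decay);
  class 2 when the local slope is below 2% of the pulse's slope range
  (plateau), class 3 otherwise (gradient change). When the derivative
  estimate and a PPG minimum disagree by more than 100 ms, the minimum is
  substituted (optional; disable for single-pulse analysis). Otherwise
  the notch is absent, class 4.
- **dp** — first PPG local maximum after the notch (fallback: after the
  e-wave) with a rise of at least 0.5% of the systolic amplitude over the
  preceding trough, before 80% of the pulse interval.

An optional correction pass enforces on ≤ u ≤ sp, a < b ≤ e < f,
sp ≤ dn ≤ dp ≤ off, recomputing the diastolic peak from the corrected
points before discarding it, and dropping any other inconsistent point.
Pulses whose systolic (on→dn) or diastolic (dn→off) times fall below
120 / 300 ms are flagged invalid rather than adjusted; invalid pulses are
excluded from biomarker aggregation. At high heart rates (≳150 bpm) the
diastolic bound is physiologically unattainable, so such recordings
yield beats and fiducials but no aggregated biomarkers by design.

## Biomarkers

All PPG amplitudes are measured relative to the amplitude at the pulse
onset; derivative amplitudes are the derivative values at the point's
sample, in units of amplitude·s⁻¹/s⁻²/s⁻³ (the spring constant SC mixes
PPG″ units with a dimensionless ratio and is reported in PPG″ units).
Durations are in ms; areas are trapezoidal integrals in amplitude·ms,
with AUC_pi = AUC_sys + AUC_dia exact by splitting at the notch sample.
Width biomarkers interpolate threshold crossings linearly between
samples; the width level x defaults to 50% and is configurable (each
level adds one Tswx/Tdwx/Tpwx triple; the canonical 74-biomarker set is
defined at a single level). A biomarker whose required points are absent,
or whose denominator is zero, is absent (NaN) — never zero.

Two symbol ambiguities were resolved in favour of the quantities'
descriptions: the ratio "pulse width over systolic peak time" is
T_pwx/T_sp, and the reflection indices RI_p1/RI_p2 divide the diastolic
peak amplitude by the onset-relative PPG amplitude at p1/p2.

Summary statistics per biomarker over a window: mean, median, SD (n−1),
quartiles by linear interpolation of order statistics (NumPy default),
IQR, adjusted Fisher–Pearson skewness, excess kurtosis (both
bias-corrected; defined as 0 for windows with fewer than three values or
zero variance), and MAD = mean |x − mean|.

## Signal-quality index

Each pulse is linearly resampled to 100 samples; the template is the
pointwise mean beat; the SQI is the Pearson correlation of a beat with
the template, clipped to [0, 1] (invariant to per-beat scale and offset).
This is a deliberately simple template matcher with the standard 0–1
contract; it gates nothing downstream.

## Validation machinery

Beat matching aligns two event trains by the single lag (searched on
10 ms binned trains) that maximizes coincidence, then matches greedily
one-to-one — references in time order, each taking its nearest unmatched
detection within the tolerance (default 150 ms; 50 ms used for the
synthetic recovery studies). F1 is the harmonic mean of sensitivity and
positive predictive value, in percent. `segment_f1` applies the same
scoring per fixed-length segment (default 10 min), excluding segments
with fewer than 300 reference beats. Fiducial errors are summarized per
point as MAE, SD of absolute errors, signed bias and Bland–Altman limits
of agreement (bias ± 1.96·SD of signed differences, ~95% coverage under
normality).

## Synthetic data

The generator emulates a clean adult fingertip pulse. Each beat on its
period grid T is a sum of Gaussians: systolic (amplitude 1.0 at 0.30 T,
σ = 0.10 T), late-systolic reflection (0.20 at 0.46 T, σ = 0.055 T) and
diastolic (0.40 at 0.70 T, σ = 0.07 T). The reflection wave is what
produces the c/d waves of PPG″ and the p2 landmark observed in fingertip
recordings; without it a two-Gaussian beat has no such structure. Options
add baseline wander (sinusoid), white noise at a stated SNR, and
inter-beat-interval jitter (Gaussian, percent of the period). Every
derivative of the model is closed-form (Hermite polynomials), so all
ground-truth landmarks are located on the continuous noise-free model by
bracketed root-finding on a 10 kHz scan grid, applying the same
morphological definitions as the detector. Identical configurations
(including the seed) produce bitwise-identical signals.

What the generator does **not** model: motion artifacts, arrhythmia,
waveform drift, sensor saturation, or morphology variation across beats.
Passing the synthetic recovery tests therefore demonstrates the
correctness of the detection logic and its robustness to stationary noise
and wander — not performance on pathological or ambulatory recordings,
which requires external data (the `fiducial_errors` / `segment_f1`
harnesses accept such annotations).

## Problem sizes and test design

The recovery studies use desk-scale problems chosen to exercise every
code path: a 3 × 3 morphology grid (systolic width 0.05–0.15 T × diastolic
amplitude 0–0.6) of 12 s records at 500 Hz for fiducial accuracy
(per-point MAE < 10 ms, typically ≤ 4 ms); 90–120 s records at 256 Hz and
40–180 bpm for beat detection (F1 = 100% clean, ≥ 95% at 20 dB SNR,
50 ms tolerance); and 10 s at 1 kHz for sample-exact equivalence between
the detector and a brute-force definitional scan. Stochastic checks
(Bland–Altman coverage, SQI noise monotonicity, log-normal moment
recovery) use fixed seeds.

## Known limitations

- The notch classes 2/3 are assigned by a slope heuristic (2% of the
  pulse's slope range) rather than by a learned classifier; borderline
  plateau/gradient-change morphologies may toggle between the two.
- The dicrotic-notch fallback requires the e- and f-waves; heavily
  distorted beats therefore report class 4 (absent) rather than a guess.
- Amplitude biomarkers are in arbitrary input units; no optical
  calibration is attempted.
- The beat detector's filter cut-offs are declared defaults exposed in
  `DetectorConfig`, not empirically optimized constants.
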