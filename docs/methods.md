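# Methods

This note documents the models, conventions and numerical choices behind
`emgassess`, and what the synthetic cohort can and cannot establish.

## Signal model and conditioning

Recordings are multi-channel surface EMG at 1 kHz from a 16-bit device with
a ±1.5 mV input range. The ADC transfer function is taken as the symmetric
linear map `v = (c/65535 − 1/2)·3000 µV` (mid-scale → 0 V), the standard
convention for bipolar front ends; the device documentation states only the
range, so the offset convention is ours.

Conditioning follows the usual sEMG chain: 4th-order Butterworth band-pass
20–300 Hz, demeaning, full-wave rectification, centered moving-RMS
envelope, per-channel amplitude normalization. Choices the chain leaves
open, and how they are fixed here:

* **Phase handling** — zero-phase (forward–backward) filtering. Offline
  analysis has no latency constraint, and zero phase keeps burst peaks
  aligned across channels. This doubles the effective stopband attenuation.
* **Envelope window** — 151 samples (~150 ms). sEMG smoothing windows of
  50–250 ms are standard; the window is forced odd so it is symmetric
  about the output sample, and edges are handled by truncating the window.
* **Normalization reference** — the 95th percentile of the envelope per
  channel per recording. It is robust to transient artifacts; `max` and
  whole-recording RMS are available alternatives. Note a consequence used
  throughout: normalization removes absolute amplitude, so classification
  rests on envelope *structure* (modulation, burst-to-baseline contrast,
  spectra, cross-channel correlation), not on raw microvolt levels.

## Segmentation

Gesture attempts are found on the channel-summed, moving-averaged
(150-sample) envelope as local maxima above `3 × median` of that trace, at
least 1000 samples apart; each peak is cut into an exactly 750-sample
window centered on the peak (shifted inward at recording edges). Rest
recordings bypass peak detection: they are tiled into non-overlapping
750-sample windows whose smoothed level stays below the same threshold,
and the first 15 quiet windows become the rest attempts. The moving-average
window, threshold factor and separation are conventions of this package
(the source procedure used manual validation of automatic detections,
which a reproducible pipeline cannot include); all are configurable.

## Feature catalogue

The named features are defined in `emgassess.features` (module docstring
carries the formula table). Where the literature admits variants, the
conventions are:

* **MMAV / MMAV3** — piecewise-constant weight windows: 1 on the middle
  half (MMAV) or the initial quarter (MMAV3) of the segment, 0.5 elsewhere,
  with 1-based inclusive indices.
* **SMAV** — MAV divided by segment duration in seconds (per-second
  scaling).
* **RMSV2** — the v-order statistic with v = 2, i.e. classic RMS.
* **EWL** — fractionally powered first differences, exponent 0.75 over the
  central 60 % of samples and 0.5 outside.
* **LPC3** — Levinson–Durbin on the biased autocorrelation;
  prediction-error convention `A(z) = 1 + a1 z⁻¹ + a2 z⁻² + a3 z⁻³`.
* **FTHT4 / PSR** — periodogram power; FTHT4 uses the four equal-width
  sub-bands of the 20–300 Hz passband (tied to the filter configuration),
  PSR uses ±10 Hz around the in-band spectral peak.
* **Wavelet packets** — Daubechies-4, level 3, periodized. Signals are
  wrapped (periodically extended) to the next multiple of 2³ before
  decomposition so every stage sees an even length and the basis stays
  orthogonal; for 750-sample segments this adds two samples (≤ 0.3 % of
  the energy) and keeps total node energy within 1 % of the segment
  energy. WENT uses natural-log Shannon entropy of the normalized node
  energies, defined as 0 for a zero signal.
* **CCS** — Pearson correlations of √-transformed envelopes over all
  unordered channel pairs, lexicographic order.

Features are computed on the normalized envelope segments by default
(the output of the conditioning chain). Whether model-based and spectral
features should instead see the raw band-passed interference pattern is a
genuinely open choice; `PreprocessConfig(domain="bandpassed")` emits the
same detected windows cut from the rectified band-passed signal
(normalized by the same reference) for that purpose.

## Classifier and validation

The discriminant standardizes features on the training split, estimates
class means and the pooled within-class covariance, adds a ridge of
1e−6 on the diagonal for numerical stability, and scores
`w = (S+λI)⁻¹(µ₁−µ₀)` with the bias at the equal-cost Bayes point of the
fitted priors. Decision threshold for confusion counts is score 0.

Validation draws 100 random subject-wise splits: 2 test subjects, the rest
training, single-class training draws redrawn (up to 1000 times). All
attempts of the held-out subjects are scored at the attempt level by
default; subject-level majority voting is available, as is one-pass
subject-wise k-fold CV. Per-iteration AUCs are undefined when the test
set is single-class — with 2 held-out subjects this happens in roughly
half the iterations — and undefined values are excluded from summaries
and counted, never imputed. ROC/PRC bands are vertical averages on a fixed
101-point grid. Mann-Whitney U model comparisons use exact enumeration for
tie-free samples below 20 per group and the tie-corrected normal
approximation otherwise, with stars at p < 0.05 / 0.01 / 0.001.

Two cutoff conventions deserve a note: thresholds are *strict* (a score of
exactly 44 is "not above 44"), and the FMA-UE lower cutoff is 29 by
default; a cutoff of 33 appears in some summaries of this task family, and
`ThresholdTask` is configurable if that variant is wanted.

## Synthetic cohort

One latent severity `s ~ Uniform(0, 1)` per subject drives everything:

| quantity | model | default |
|---|---|---|
| FMA-UE | `clip(round(66(1−s) + ε), 0, 66)`, ε ~ N(0, 2) | clinical noise 2 pts |
| BRS (hand) | `clip(1 + ⌊5(1−s) + ε⌋, 1, 6)`, ε ~ N(0, 0.2) | |
| MAS (hand) | 0 for `s ≤ 0.4`, else graded 1…4 in `s` | onset s₀ = 0.4 |
| volitional burst peak | `(120 + 400(1−s)) µV` carrier RMS | 400 ms raised cosine |
| attempt quality | lognormal amplitude jitter, SD `0.1 + 0.25 s` | |
| resting tone | `12 s µV` carrier RMS, slow AM depth `0.6 s` (0.5–3 Hz) | |
| spasticity bursts | Poisson rate `0.25·max(0, (s−0.4)/0.6)` Hz, 300 ms | gain 2.5× tone |
| cross-channel coupling | tonic AM shared fraction `ρ = 0.2 + 0.6 s` | |
| noise floor | 3 µV RMS per channel | |

Carriers are exactly band-limited Gaussian noise (frequency-domain
synthesis on 20–300 Hz), so out-of-band power is nil by construction.
Amplitudes are chosen to be physiologically plausible for a paretic
forearm montage — voluntary bursts one to two orders of magnitude above
the instrument noise floor, resting tone well below voluntary effort —
and such that attempts remain detectable across the whole severity range;
at `s = 1` bursts sit at the model's minimum amplitude, not literally in
the noise. The spasticity onset of 0.4 makes roughly a third of a default
cohort MAS-positive. The effect-size multiplier κ interpolates the
severity that drives the signals between the score-driving latent (κ = 1)
and an independent uniform draw (κ = 0, the null cohort); the clinical
scores themselves never depend on κ, so a κ = 0 cohort has genuine labels
and uninformative signals.

All randomness flows from one seeded generator with per-subject
substreams; identical seeds reproduce cohorts, splits and report tables
byte for byte.

### What the generator does and does not establish

It emulates the *structure* that makes the clinical problem learnable:
severity-coherent scores across three scales, burst amplitude/quality
declining with severity, resting tone and synergy coupling rising with it.
It does not model motor-unit physiology, electrode artifacts, ECG
contamination, session effects, or the real covariance between scales
beyond the shared latent. Passing tests therefore demonstrate that the
pipeline recovers planted severity structure through the full
preprocessing–features–validation stack and is correctly calibrated under
the null — not that the classifier would reach any particular accuracy on
real patients.

### Known limitations and protocol caveats

* With 25 subjects, a fixed null cohort can show mean AUC deviating from
  0.5 by ~0.07 (1 SD) from chance correlation between subject-level
  features and labels, and cross-validated null accuracy is biased
  slightly *below* the majority-class rate (the usual anti-learning effect
  of held-out means). Null-calibration checks at this scale are therefore
  seed-sensitive near their band edges.
* Detection recall is evaluated against planted burst centers (a detected
  peak within half a window); at high severity a few percent of attempts
  with unlucky amplitude jitter fall below threshold, mirroring attempts a
  human validator would also discard.
* Segment counts assume ~15 attempts per gesture; subjects missing a
  gesture are excluded from the affected gesture sets and logged, matching
  the reporting behavior of the task matrix.
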