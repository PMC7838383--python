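# Methods

## Signal model and pipeline

The package treats a trial as a 14-channel, 4 s, 128 Hz segment of scalp
EEG in microvolts, stimulus-locked to a product picture, with a binary
subjective response (like/dislike). The working hypothesis is the standard
frontal-asymmetry account of affective valence: relatively greater
left-frontal activation (lower left alpha, i.e. less idling; higher left
beta) accompanies approach/positive valence, and the mirror pattern
accompanies withdrawal. All preference indices are deterministic functions
of Welch band powers at the two frontal pairs (AF3, F3) on the left and
(AF4, F4) on the right.

Conditioning chain (fixed order): common average reference → polyphase
resampling to the target rate → zero-phase 4th-order Butterworth band-pass
→ ICA component rejection → Savitzky–Golay smoothing. Re-referencing
assumes artifacts and reference drift are shared across electrodes; the
band-pass assumes preference-relevant activity lies in 4–45 Hz.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| band-pass edges | (4, 45) | Hz | retains theta–gamma, rejects drift and mains |
| target rate | 128 | Hz | canonical acquisition rate of the emulated montage |
| Savitzky–Golay window / order | 11 / 3 | samples / – | mild smoothing; exact on cubic trends |
| ICA kurtosis threshold | 5.0 | – | excess kurtosis of sources; spiky components (blinks, pops) greatly exceed it, oscillations do not |
| wavelet / levels | db4 / 4 | – | at 128 Hz the dyadic details align with the clinical bands (D1 32–64 … A4 0–4 Hz) |
| Welch segment / overlap / window | 256 / 50% / Hann | samples | 2 s segments give 0.5 Hz resolution with 3 averages per 4 s trial |
| PSD bands | θ 4–8, α 8–13, β 13–30, γ 30–40 | Hz | conventional definitions; γ capped at 40 Hz inside the band-pass |
| RF trees | 500 | – | plateau of the ensemble's error on this data scale |
| KNN k / SVM | 5 / RBF, C=1 | – | library defaults; no tuning performed |
| DNN learning rate / dropout | 0.001 / 0.5 | – | Adam step size and heavy regularization for small-sample EEG |
| holdout fraction | 0.2 | – | single stratified 80/20 split |

All of these are overridable through `RunConfig` / YAML.

## Synthetic data: what it emulates and what it does not

`synthetic_eeg` generates 25 subjects × 42 stimuli (14 products × 3
variants) of 14-channel trials. Each channel is a sum of four band-limited
random-phase sinusoid mixtures (theta/alpha/beta/gamma with baseline RMS
amplitudes 4/6/3/1.5 µV — an alpha-dominant caricature of resting EEG)
plus Gaussian broadband noise (default SD 2 µV).

A latent Bernoulli(0.5) preference state modulates only the four frontal
channels: for "like", the left-pair beta and right-pair alpha amplitudes
are multiplied by (1 + d/4) and their mirror amplitudes by (1 − d/4)
(floored at 0.05); "dislike" reverses the contrast. The effect size d is
therefore a relative left–right amplitude contrast: d = 2 gives a 3× power
ratio between hemispheres in the modulated bands — a deliberately strong,
cleanly recoverable effect — while d = 0 is an exact null. Subjective
labels equal the latent state unless a flip probability is set, which
emulates self-report unreliability without asserting a mechanism.

Not emulated: 1/f background spectra, inter-subject amplitude variability,
volume conduction between channels, eye-blink and movement artifacts
(beyond an optional single sinusoid+spike contaminant used to exercise the
artifact stage), and any genuine neural correlate of preference. Passing
tests on this generator therefore demonstrate that the pipeline's
machinery recovers a planted frontal band-power asymmetry at the stated
sizes — not that real consumer preference is decodable at those accuracies.

## Numerical choices

- **DWT boundary handling** is periodized (`mode="periodization"`), which
  keeps the db4 filter bank orthogonal: perfect reconstruction (≤1e-8) and
  exact energy partition across coefficient sets (≤1e-6 relative) for
  signal lengths divisible by 2^levels — true of every canonical 512-sample
  epoch. For other lengths reconstruction still holds but intermediate
  odd-length padding breaks exact energy bookkeeping.
- **The 12th coefficient statistic** is total energy (sum of squares); the
  other eleven are mean, median, variance, SD, 25th/75th percentiles
  (linear interpolation), RMS, zero- and mean-crossing rates (fraction of
  adjacent sign changes, sign(0) treated as positive), mean first
  difference, and Shannon entropy. Entropy is computed on the normalized
  squared-coefficient distribution p_i = x_i²/Σx² with natural log and
  0·log 0 := 0, so a constant series has entropy ln n and a one-hot series
  entropy 0.
- **Band powers** are the *mean* spectral density over half-open intervals
  [low, high), avoiding double-counting shared edges. Multi-electrode band
  powers such as α(AF3, F3) are arithmetic means of the two channel powers.
- **Valence v2** is defined on the frontal pairs only: the montage has no
  Fz electrode, so the log-ratio uses ln α(AF3,F3) − ln α(AF4,F4). This is
  the only self-consistent reading given the 14-channel montage.
- **Valence-based labeling** rescales the chosen valence variant (v1 by
  default, configurable) per subject onto [1, 9] by min–max, rounds
  half-up, and thresholds between 5 and 6. Per-subject rescaling removes
  between-subject offset differences; a degenerate (constant) cohort is an
  error rather than an arbitrary label.
- **Min–max normalization** is fitted on training columns only; constant
  training columns map to 0, and held-out values may leave [0, 1].
- **Overall precision/recall** are support-weighted, under which recall is
  identically equal to accuracy — the reported metric triple is therefore
  internally redundant by construction, and a test asserts the identity.
- **DNN**: hidden widths floor(d/2), floor(d/4), floor(d/8); He-normal
  init; Adam (β₁ 0.9, β₂ 0.999); inverted dropout on input and hidden
  layers; early stopping on a 10% validation carve-out from the training
  split (patience 10) that engages only after a 30-epoch warmup, because
  cross-entropy training under heavy dropout sits on a ~ln 2 plateau for
  the first few dozen epochs and would otherwise be mistaken for
  convergence. Cross-entropy losses use a 2-unit head (softmax for
  categorical, per-unit sigmoid for binary); hinge uses a single linear
  margin unit with ±1 label coding, since a hinge objective on a softmax
  head is ill-defined. Training is exactly reproducible per seed.
- **ICA** is FastICA with unit-variance whitening, seeded; components whose
  absolute excess kurtosis exceeds the threshold are zeroed before back-
  projection. The choice of an automatic kurtosis rule (rather than manual
  inspection) is a reproducibility decision.

## Problem sizes used in the shipped analyses

The test-suite and acceptance-script benchmarks use the full canonical
synthetic dataset (1050 trials) with the PSD feature family for the
classifier grids, strong-effect runs at d = 2.0 with noise SD 0.5 µV, and
null runs at d = 0 with noise SD 2 µV. The DWT family (840-feature
matrices) is exercised end-to-end on the same dataset in the library and
validated in the unit tests; the grid benchmarks default to PSD, whose
56-feature matrices train every classifier in seconds.

## Known limitations

- The halving architecture rule leaves the network very narrow for input
  widths below ~64; combined with dropout 0.5 such networks may fail to
  leave the initial plateau. This regime never arises from the shipped
  feature extractors (56–848 inputs) but matters if the classifier is
  reused on tiny hand-made feature sets.
- Holdout evaluation is a single split; no confidence intervals or
  repeated splits are produced.
- The valence variant driving labels is a configuration choice; the four
  variants are not guaranteed to agree, and on null data the derived labels
  are arbitrary by construction.
- Synthetic accuracies are not comparable to accuracies on real
  neuromarketing recordings; see the generator's non-goals above.
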