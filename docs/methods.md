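# Methods

`ssvep_depth_lab` models a steady-state visually evoked potential (SSVEP)
experiment in which a green disc flickers at 7.5, 11.25 or 18 Hz at one of
three virtual depths (0.4, 1.0, 1.8 m) in a mixed-reality (MR) or
virtual-reality (VR) head-mounted display, while nine occipital/parietal
EEG channels (Oz, O1, O2, PO3–PO6, POz, Pz) are recorded at 1000 Hz. The
package implements the stimulus design rules, a synthetic session
generator standing in for restricted human recordings, the preprocessing
chain, three decoders (CCA, filter-bank CCA, TRCA), and the evaluation
statistics.

## Stimulus design

A disc subtending a constant visual angle θ has physical diameter
`d = 2 D tan(θ/2)` at viewing distance `D`; with θ = 2.07° the diameters
are 1.45, 3.61 and 6.50 cm at the three depths. On a display refreshing
at `R` Hz, a square-wave flicker is rendered without truncation only if
its frequency satisfies `f = R/n` for integer `n` (e.g. 90/8 = 11.25 Hz,
eight frames per cycle). The duty cycle α must give a whole number of
on-frames (`α·n` integral); fractional on-frames are rejected rather than
rounded, because whole-frame timing is the point of the rule. Schedules
are blocked — within each depth block one frequency is shown for
`reps_per_cell` consecutive cue (1 s) / flash (5 s) / rest (3 s) trials —
with an optional randomized order. Timing uses exact arithmetic on trial
multiples, so a 90-trial session is exactly 810 s.

## SNR definition

Signal quality of a trial is measured on the 5-s stimulus window as

    SNR(dB) = 10 log10( (P_f0 + P_2f0) / P_noise )

with `P_f0`, `P_2f0` the periodogram powers at the stimulus frequency and
its second harmonic and `P_noise` the mean power over bins within ±1.0 Hz
of either peak, excluding bins within ±0.1 Hz of the peaks. The
periodogram is rectangular-windowed and zero-padded onto a 0.05 Hz grid,
the coarsest grid that contains every fundamental and second harmonic as
an exact bin (a native 5-s window has 0.2 Hz bins, which miss 7.5 and
11.25 Hz). SNR is computed per channel and summarized as the mean of the
per-channel dB values; after TRCA filtering it is computed on the first
spatial component.

Two properties of this estimator matter for interpretation:

* **Noise floor.** For signal-free data the expected value is not 0 but
  ≈ +1.8 dB: the numerator holds two noise bins while the denominator is
  the mean of one, and averaging dB over χ²-distributed bins shifts the
  result below 10·log10(2). Condition targets must therefore sit above
  this floor to be reachable.
* **Leakage saturation.** At very high evoked amplitudes the rectangular
  window's sidelobes leak signal into the noise band and the measured
  SNR saturates (~20 dB); the generator's default conditions are far
  below this regime.

## Synthetic session generator

Each session is background noise plus stimulus-locked evoked responses:

* **Evoked response.** During each flash, a fundamental sinusoid at the
  stimulus frequency plus a second harmonic at `harmonic_ratio` (default
  0.5) of its amplitude, starting `response_latency` (default 0.13 s)
  after flash onset, scaled per channel by an occipitally dominant
  topography (Oz/POz 1.0 … Pz 0.5). The phase is locked to the stimulus
  with per-trial Gaussian jitter (sd 0.35 rad) — phase-locking is what
  makes inter-trial methods like TRCA physically meaningful — and the
  amplitude carries mean-one lognormal trial-to-trial jitter (sd 0.4 in
  log space), reflecting attention and state fluctuations.
* **Background.** 1/f ("pink") noise with exponent 1, scaled to unit
  expected variance *within the 0.1–40 Hz analysis band* (normalizing by
  realized variance or total variance would couple the noise floor to a
  few low-frequency draws or to session length); 60% of its variance
  comes from three shared sources with fixed mixed-sign spatial
  patterns, emulating volume-conducted background whose topography
  differs from the stimulus response, the rest is channel-independent.
  Independent white sensor noise (1 µV) and a spatially coherent
  alpha-band oscillation (10 ± 1 Hz, 2 µV, parietal-dominant topography)
  complete the model; the alpha rhythm deliberately neighbors the
  11.25 Hz stimulus.
* **Condition-dependent SNR.** Default targets decrease with depth and
  are lower in VR: MR {0.4 m: 3.8, 1.0 m: 3.4, 1.8 m: 3.0} dB and
  VR = MR − 0.85 dB. The depth step (0.4 dB) and display-mode offset
  (0.85 dB) mirror reported raw-SNR contrasts of MR/VR flicker sessions;
  the absolute level places the weakest condition safely above the
  estimator's ≈ +1.8 dB no-signal floor, below which no amplitude can
  reach a target.
* **Calibration.** The evoked amplitude for each (environment, depth,
  frequency) cell is found by deterministically inverting a Monte-Carlo
  estimate of mean measured SNR versus amplitude: 128 preprocessed
  trials drawn from four independent background realizations (averaging
  out session-level noise draws), with trial jitters sampled at
  stratified quantiles rather than at random (the amplitude jitter
  dominates the ≈2.7 dB per-trial SNR spread; stratification removes
  that variance from the estimate). Residual calibration error is
  ≈ ±0.15 dB, constant within a frequency, so it shifts a frequency's
  curve without disturbing depth or display-mode contrasts. Because the
  local noise density differs across frequencies (1/f plus alpha),
  equal-SNR calibration yields very different absolute amplitudes
  (≈0.17–0.55 µV) — see "known limitations".

Sessions are bit-reproducible for a fixed config and seed; a 2-s roll-on
and roll-off frame the schedule so filter edge transients never touch
trials.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass 0.1–40 Hz
in second-order sections on the continuous recording, epoching into
(−1, +5) s windows around the stimulus markers (half-open sample
convention), FIR anti-aliased decimation 1000 → 250 Hz (unit DC gain),
and peak-to-peak artifact rejection (default 200 µV on any channel).
Filtering precedes epoching so epochs contain no per-trial filter
transients. The 1-s baseline is carried in the epochs but excluded from
decoding and SNR windows.

## Decoders

* **CCA.** For each candidate frequency, the largest canonical
  correlation between the 9-channel trial and a template of sin/cos
  pairs at the fundamental and second harmonic (all harmonics below
  Nyquist; default 2). Solved by the whitened cross-covariance SVD with
  a 1e-9 relative ridge on the auto-covariances; the predicted frequency
  is the argmax, ties to the lowest frequency.
* **FBCCA.** The trial is decomposed with zero-phase Butterworth
  band-passes into four sub-bands (0.1–10, 10–20, 20–30, 30–40 Hz), CCA
  is run per sub-band against the full templates, and the per-class
  feature is the weighted sum of squared correlations with
  `w(n) = n^(−1.25) + 0.25` (strictly positive, strictly decreasing).
  With a single full-range band the decision reduces exactly to CCA on
  the band-filtered trial.
* **TRCA.** Per stimulus class, the spatial filter solving
  `S_t w = λ S_n w`, where `S_t = Σ_{j≠k} X_j X_kᵀ` of per-trial-centered
  signals and `S_n` is the total covariance (identity optional); filters
  are `S_n`-normalized and eigenvalue-sorted. Covariances are estimated
  on a 5–40 Hz filtered copy of the training trials — below ~5 Hz the
  data contain no stimulus-locked content, only high-power 1/f noise
  that drowns the inter-trial covariance estimate — and the resulting
  filters are applied to the full-band epochs. In the evaluation
  protocol TRCA is used as an SNR enhancer: per repeated stratified
  70/30 split, filters are trained per frequency class (trials pooled
  across depths) and held-out trials are projected onto the class's
  leading filter. A template-matching `TrcaClassifier` is provided as an
  extension beyond that role.

## Validation scheme and statistics

Model-based evaluation uses 10 seeded repetitions of stratified 70/30
train/test splits over the (depth × frequency) cells — on the canonical
90-trial session exactly 63 train / 27 test, 7/3 per cell. Accuracy is
`N_correct/N_total × 100%` per condition cell; empty cells are reported
as absent, never as 0%.

Questionnaire contrasts use the Wilcoxon signed-rank test in its
SPSS-compatible form: zero differences dropped, mid-ranks for ties,
tie-corrected variance, no continuity correction, two-sided normal p.
Z is computed from the negative-rank sum, so scores systematically
higher in the second sample (e.g. VR above MR) give negative Z.
Bonferroni correction divides the family level by the number of
comparisons (0.05/10 = 0.005). Feature-vs-SNR relationships are
summarized by least-squares fits with Pearson r.

## Reproducibility plumbing

The canonical on-disk container is HDF5 (signals, markers, JSON labels
and provenance); schedules serialize to JSON and BIDS-style events TSV.
Every pipeline artifact carries a provenance block (package version,
config hash stable under key reordering, seeds, stage parameters); the
optional timestamp defaults to off so identical config + seed produces
byte-identical outputs. A thin `ssvep-depth-lab` CLI wraps the stages
(`design`, `simulate`, `preprocess`, `decode`, `evaluate`, `run`);
chaining the stage commands reproduces `run_pipeline`'s decisions.

## Problem sizes

Unit tests run on 18–27-trial sessions. The ordering checks in the
acceptance suite average 16 sessions (fixed seeds) per display mode of
90 trials each: the 0.4 dB depth step in measured SNR is about twice the
standard error of a single-session condition mean (~0.5 dB), so
resolving the orderings requires averaging at this scale.

## What the generator does and does not emulate

It reproduces: occipital topography, fundamental-plus-harmonic spectra,
1/f background with realistic spatial coherence, an alpha rhythm
adjacent to one stimulus frequency, stimulus-locked phase with jitter,
trial-to-trial amplitude variability, depth- and display-mode-dependent
SNR, and chance-level behavior when the evoked amplitude is zero.

It does not emulate: inter-subject variability (the paper's ±35%
accuracy spreads come from a bimodal subject population), non-stationary
or non-Gaussian artifacts (ocular, muscular, motion), broadband evoked
transients at flash onset, higher harmonics beyond the second, or any
biophysical forward model. Passing tests therefore demonstrate the
analysis chain's correctness and the qualitative condition orderings on
a controlled family — not performance on real recordings.

## Known limitations

* **Equal-SNR calibration skews class difficulty.** Calibrating every
  frequency to the same narrowband SNR gives the 18 Hz class a much
  smaller absolute amplitude (its local 1/f noise floor is low), and
  broadband template decoders then rarely select it (its per-cell
  accuracy sits near zero while 7.5/11.25 Hz sit at 70–80%). Pooled
  accuracy consequently responds only weakly to the 0.4 dB depth step —
  the depth ordering of measured SNR reproduces robustly, but the
  implied accuracy ordering between 0.4 m and 1.0 m is at or below
  Monte-Carlo resolution even over 32 sessions.
* **FBCCA does not beat CCA on this synthetic family.** With the default
  harmonic ratio of 0.5 and stationary Gaussian-like noise, splitting
  into sub-bands adds more estimation noise (narrowband canonical
  correlations have high noise baselines) than the harmonic-band
  separation recovers, and FBCCA trails CCA by ~5 accuracy points at
  every SNR level tested. The advantage reported on real recordings
  reappears in this generator only when the second harmonic is strong
  (harmonic ratio ≳ 1.2), suggesting it is driven by harmonic energy and
  noise non-stationarity that the default conditions do not include.
  The defaults were kept rather than tuned to manufacture the ordering.
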