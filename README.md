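# ssvep_depth_lab

Stimulus design, synthetic EEG simulation and decoding for steady-state
visually evoked potential (SSVEP) experiments under varying virtual
stimulus depth and display mode.

SSVEP brain-computer interfaces present flickering targets and detect
which one the user attends from periodic occipital EEG responses at the
flicker frequency and its harmonics. In mixed-reality (MR) and
virtual-reality (VR) headsets the vergence–accommodation conflict grows
with virtual depth and can weaken these responses. This package provides
the full analysis chain for studying that effect when the underlying
human recordings are not redistributable: a synthetic session generator
with condition-dependent signal-to-noise ratio stands in for the data,
and every downstream stage — preprocessing, decoding, statistics — is
implemented and tested against independent oracles.

The core quantities:

* frame-locked flicker design: `f = R/n` on an `R` Hz display, constant
  visual angle `d = 2D·tan(θ/2)`, square-wave `S(t)` with duty cycle α;
* SNR of a trial, `10·log10((P_f0 + P_2f0)/P_noise)` from periodogram
  bins at the stimulus frequency `f0` and harmonic `2f0` against
  adjacent-bin noise;
* decoders: canonical correlation analysis (CCA) against sin/cos
  templates, filter-bank CCA with `w(n) = n^(−1.25) + 0.25` weighted
  sub-band fusion, and task-related component analysis (TRCA) spatial
  filters from the generalized eigenproblem `S_t w = λ S_n w`;
* evaluation: accuracy `N_correct/N_total × 100%` under repeated
  stratified 70/30 validation, Wilcoxon signed-rank questionnaire
  contrasts with Bonferroni correction, and feature-vs-SNR linear fits.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from ssvep_depth_lab import (
    GeneratorConfig, build_schedule, simulate_session,
    preprocess_recording, decode_trials, snr_db,
)

# 90-trial MR session: 3 depths x 3 frequencies x 10 flashes
schedule = build_schedule(["MR"], [0.4, 1.0, 1.8], [7.5, 11.25, 18.0], 10)
recording = simulate_session(GeneratorConfig(seed=1), schedule)
epochs = preprocess_recording(recording).kept()

stim, freqs = epochs.stimulus_data(), epochs.frequencies()
depths = np.array([l["depth"] for l in epochs.labels])
for d in (0.4, 1.0, 1.8):
    idx = np.flatnonzero(depths == d)
    snr = np.mean([snr_db(stim[i], 250.0, freqs[i]).snr_per_trial[0] for i in idx])
    print(f"depth {d} m: mean SNR {snr:+.2f} dB")
```

prints (seed 1):

```
depth 0.4 m: mean SNR +3.34 dB
depth 1.0 m: mean SNR +3.36 dB
depth 1.8 m: mean SNR +3.50 dB
```

Each value is the trial-average SNR of that depth's 30 trials: power at
the stimulus frequency and its second harmonic over neighboring-bin
noise power, in dB. The generator calibrates the evoked amplitudes so
these means are 3.8 / 3.4 / 3.0 dB in expectation; a single session's
cell estimate carries about ±0.5 dB of noise (hence the inverted
ordering above), and the test suite averages 16 sessions per display
mode to resolve the depth and MR-vs-VR orderings.

The `examples/` directory contains one narrative script per capability:
stimulus design, simulation + SNR, CCA/FBCCA decoding, TRCA SNR
enhancement, and the questionnaire statistics. A thin CLI wraps the same
stages:

```bash
ssvep-depth-lab design --depths 0.4,1.0,1.8 --freqs 7.5,11.25,18 --reps 10 --out events.tsv
ssvep-depth-lab run --seed 7 --out-dir results/
```

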