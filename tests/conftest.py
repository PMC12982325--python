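"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from ssvep_depth_lab.decoding import make_references
from ssvep_depth_lab.preprocess import preprocess_recording
from ssvep_depth_lab.simulate import GeneratorConfig, simulate_session
from ssvep_depth_lab.stimulus import build_schedule

FREQS = (7.5, 11.25, 18.0)
DEPTHS = (0.4, 1.0, 1.8)


@pytest.fixture(scope="session")
def small_session():
    """27-trial MR session with a fixed evoked amplitude (no calibration).

    Returns (kept EpochSet, stimulus-window array, ReferenceSet).
    """
    cfg = GeneratorConfig(seed=11, fundamental_amplitude=1.2)
    sched = build_schedule(["MR"], DEPTHS, FREQS, reps_per_cell=3)
    eps = preprocess_recording(simulate_session(cfg, sched)).kept()
    stim = eps.stimulus_data()
    refs = make_references(FREQS, 2, eps.sample_rate, stim.shape[-1])
    return eps, stim, refs


@pytest.fixture(scope="session")
def strong_session():
    """18-trial MR session with a clearly decodable evoked amplitude."""
    cfg = GeneratorConfig(seed=12, fundamental_amplitude=2.5)
    sched = build_schedule(["MR"], DEPTHS, FREQS, reps_per_cell=2)
    eps = preprocess_recording(simulate_session(cfg, sched)).kept()
    stim = eps.stimulus_data()
    refs = make_references(FREQS, 2, eps.sample_rate, stim.shape[-1])
    return eps, stim, refs


@pytest.fixture(scope="session")
def planted_epoch():
    """Noiseless 9-channel epoch of a 11.25 Hz SSVEP with second harmonic."""
    fs, n = 250.0, 1250
    t = np.arange(n) / fs
    wave = np.sin(2 * np.pi * 11.25 * t + 0.4) + 0.5 * np.sin(
        2 * np.pi * 22.5 * t + 0.8
    )
    gains = np.array([1.0, 0.9, 0.9, 0.7, 0.7, 0.7, 0.7, 1.0, 0.5])
    return np.outer(gains, wave)
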