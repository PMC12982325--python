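"""Continuous-recording containers and the epoching pipeline.

Default processing order follows standard SSVEP practice: zero-phase
band-pass (0.1-40 Hz, 4th-order Butterworth) on the continuous signal,
segmentation into (-1, +5) s epochs around each stimulus-onset marker,
anti-aliased decimation from 1000 Hz to 250 Hz, and peak-to-peak artifact
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "EpochSet",
    "bandpass",
    "epoch",
    "decimate",
    "reject_bad",
]

#: occipital/parietal montage used for SSVEP recording
DEFAULT_CHANNELS = ("Oz", "O1", "O2", "PO3", "PO4", "PO5", "PO6", "POz", "Pz")


@dataclass
class RawRecording:
    """Multi-channel continuous EEG with stimulus-onset markers.

    ``signal`` is channels x samples in microvolts.  ``markers`` holds
    ``(sample_index, trial_index)`` pairs at stimulus onset; per-trial
    condition labels live in ``trial_info`` keyed by trial index with
    ``environment``, ``depth`` and ``frequency`` entries.
    """

    signal: np.ndarray
    sample_rate: float
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    markers: list[tuple[int, int]] = field(default_factory=list)
    trial_info: dict[int, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("signal row count must match channel_names")
        n = self.signal.shape[1]
        for s, _ in self.markers:
            if not 0 <= s < n:
                raise ValueError(f"marker sample {s} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EpochSet:
    """Trial-segmented EEG: ``data`` is trials x channels x samples.

    ``window`` is (start, end) in seconds relative to stimulus onset, with
    half-open sample convention [start, end).  ``labels`` carries one
    ``{environment, depth, frequency}`` dict per trial; ``kept_mask``
    marks trials surviving artifact rejection.
    """

    data: np.ndarray
    sample_rate: float
    window: tuple[float, float]
    labels: list[dict]
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    kept_mask: np.ndarray | None = None
    rejection_report: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self) -> "EpochSet":
        """View restricted to trials surviving rejection."""
        m = self.kept_mask
        return EpochSet(
            data=self.data[m],
            sample_rate=self.sample_rate,
            window=self.window,
            labels=[l for l, k in zip(self.labels, m) if k],
            channel_names=self.channel_names,
        )

    def stimulus_data(self) -> np.ndarray:
        """Trials x channels x samples restricted to [0, end) s post-onset.

        The pre-stimulus baseline is carried in the epochs but excluded
        from decoding and SNR windows.
        """
        start, end = self.window
        i0 = int(round(-start * self.sample_rate)) if start < 0 else 0
        return self.data[:, :, i0:]

    def frequencies(self) -> np.ndarray:
        return np.array([l["frequency"] for l in self.labels])


def _band_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges ({low}, {high}) Hz invalid for Nyquist {nyq} Hz"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    raw: RawRecording, low: float = 0.1, high: float = 40.0, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward (filtfilt) filtering in second-order sections; the
    length is preserved and the effective magnitude response is the squared
    single-pass response.
    """
    sos = _band_sos(low, high, order, raw.sample_rate)
    filtered = sps.sosfiltfilt(sos, raw.signal, axis=-1)
    return replace(raw, signal=filtered)


def epoch(raw: RawRecording, window: tuple[float, float] = (-1.0, 5.0)) -> EpochSet:
    """Segment a continuous recording into one epoch per marker.

    ``window`` is (start, end) in seconds relative to the marker, sampled
    half-open at the recording rate.  Raises if any epoch would extend
    outside the recording, naming the offending trials.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    fs = raw.sample_rate
    i_start = int(round(start * fs))
    n_win = int(round((end - start) * fs))
    bad = [
        trial
        for s, trial in raw.markers
        if s + i_start < 0 or s + i_start + n_win > raw.n_samples
    ]
    if bad:
        raise ValueError(f"epoch window out of bounds for trials {bad}")
    data = np.empty((len(raw.markers), raw.signal.shape[0], n_win))
    labels = []
    for j, (s, trial) in enumerate(raw.markers):
        data[j] = raw.signal[:, s + i_start : s + i_start + n_win]
        labels.append(dict(raw.trial_info.get(trial, {}), trial=trial))
    return EpochSet(
        data=data,
        sample_rate=fs,
        window=window,
        labels=labels,
        channel_names=raw.channel_names,
    )


def decimate(epochs: EpochSet, target_rate: float = 250.0) -> EpochSet:
    """Anti-aliased downsampling by an integer factor.

    Uses a zero-phase FIR decimator (unit DC gain); with the band already
    limited to 40 Hz the passband is untouched far below the new Nyquist.
    """
    q = epochs.sample_rate / target_rate
    q_int = round(q)
    if q_int < 1 or abs(q - q_int) > 1e-9:
        raise ValueError(
            f"sample_rate {epochs.sample_rate} not an integer multiple of "
            f"target {target_rate}"
        )
    if q_int == 1:
        return epochs
    data = sps.decimate(epochs.data, q_int, ftype="fir", zero_phase=True, axis=-1)
    return EpochSet(
        data=data,
        sample_rate=target_rate,
        window=epochs.window,
        labels=list(epochs.labels),
        channel_names=epochs.channel_names,
        kept_mask=epochs.kept_mask.copy(),
        rejection_report=epochs.rejection_report,
    )


def reject_bad(epochs: EpochSet, peak_to_peak_limit: float = 200.0) -> EpochSet:
    """Flag epochs whose any-channel peak-to-peak exceeds the limit (uV).

    Returns a new EpochSet with an updated ``kept_mask`` and a
    ``rejection_report`` of rejected counts per (environment, depth,
    frequency) condition.
    """
    if not peak_to_peak_limit > 0:
        raise ValueError("peak_to_peak_limit must be positive")
    p2p = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)  # trials x channels
    ok = (p2p <= peak_to_peak_limit).all(axis=-1)
    mask = epochs.kept_mask & ok
    rejected: dict = {}
    for lbl, keep in zip(epochs.labels, ok):
        if not keep:
            key = (lbl.get("environment"), lbl.get("depth"), lbl.get("frequency"))
            rejected[key] = rejected.get(key, 0) + 1
    report = {
        "peak_to_peak_limit": peak_to_peak_limit,
        "n_rejected": int((~ok).sum()),
        "rejected_per_condition": {str(k): v for k, v in rejected.items()},
    }
    return EpochSet(
        data=epochs.data,
        sample_rate=epochs.sample_rate,
        window=epochs.window,
        labels=list(epochs.labels),
        channel_names=epochs.channel_names,
        kept_mask=mask,
        rejection_report=report,
    )


def preprocess_recording(
    raw: RawRecording,
    low: float = 0.1,
    high: float = 40.0,
    order: int = 4,
    window: tuple[float, float] = (-1.0, 5.0),
    target_rate: float = 250.0,
    peak_to_peak_limit: float = 200.0,
) -> EpochSet:
    """Band-pass -> epoch -> decimate -> reject, with the default parameters."""
    return reject_bad(
        decimate(epoch(bandpass(raw, low, high, order), window), target_rate),
        peak_to_peak_limit,
    )
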