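"""Flicker stimulus design for depth-varying SSVEP experiments.

A steady-state visually evoked potential (SSVEP) paradigm presents a
square-wave flickering disc at a virtual depth ``D`` while keeping its
visual angle constant, so the retinal image size is identical across
depths.  On a head-mounted display with a fixed refresh rate the flicker
frequency must divide the refresh rate (``f = refresh / n`` for integer
``n``), otherwise the waveform is truncated mid-frame and distorted.

This module encodes that geometry and frame arithmetic, the square-wave
flicker model, and the blocked trial schedule (cue -> flash -> rest).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "FlickerWaveform",
    "Trial",
    "TrialSchedule",
    "visual_angle_to_diameter",
    "admissible_frequencies",
    "square_wave",
    "build_schedule",
]


def visual_angle_to_diameter(depth: float, angle: float) -> float:
    """Physical diameter of a disc subtending ``angle`` degrees at ``depth`` m.

    ``d = 2 D tan(theta / 2)``: the size a target must have so that its
    visual angle stays constant as its viewing distance changes.

    Parameters
    ----------
    depth : float
        Viewing distance in meters, >= 0.
    angle : float
        Visual angle in degrees, in (0, 180).

    Returns
    -------
    float
        Diameter in meters.
    """
    if not math.isfinite(depth) or depth < 0:
        raise ValueError(f"depth must be finite and non-negative, got {depth!r}")
    if not math.isfinite(angle) or not 0 < angle < 180:
        raise ValueError(f"visual angle must lie in (0, 180) degrees, got {angle!r}")
    return 2.0 * depth * math.tan(math.radians(angle) / 2.0)


def admissible_frequencies(
    refresh_rate: float, n_min: int, n_max: int
) -> list[tuple[int, float]]:
    """Frame-locked flicker frequencies ``f = refresh_rate / n``.

    Returns one ``(n, frequency)`` pair per integer ``n`` in
    ``[n_min, n_max]``, sorted by ``n``.  An empty range yields an empty
    list.
    """
    if refresh_rate <= 0:
        raise ValueError("refresh_rate must be positive")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    return [(n, refresh_rate / n) for n in range(n_min, n_max + 1)]


def _frames_per_cycle(frequency: float, refresh_rate: float) -> int:
    """Integer frames per flicker cycle, or raise if not frame-locked."""
    if frequency <= 0 or refresh_rate <= 0:
        raise ValueError("frequency and refresh_rate must be positive")
    n = refresh_rate / frequency
    n_int = round(n)
    if n_int < 1 or abs(n - n_int) > 1e-9 * max(1.0, n_int):
        raise ValueError(
            f"frequency {frequency} Hz is not frame-locked to a {refresh_rate} Hz "
            f"refresh: f = refresh/n requires an integer n (got n = {n:.6g})"
        )
    return n_int


@dataclass(frozen=True)
class StimulusSpec:
    """One flicker source: frequency, duty cycle, depth and geometry.

    ``frames_per_cycle`` is derived from the ``f = refresh/n`` rule and
    validated on construction; ``duty_cycle * frames_per_cycle`` must be a
    whole number of on-frames.
    """

    frequency: float
    refresh_rate: float = 90.0
    duty_cycle: float = 0.5
    depth: float = 1.0
    visual_angle: float = 2.07
    peak_intensity: float = 1.0

    def __post_init__(self) -> None:
        n = _frames_per_cycle(self.frequency, self.refresh_rate)
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")
        on = self.duty_cycle * n
        if abs(on - round(on)) > 1e-9:
            raise ValueError(
                f"duty_cycle {self.duty_cycle} x {n} frames/cycle is not a whole "
                "number of on-frames; whole-frame timing requires an integer"
            )
        if self.depth < 0 or not math.isfinite(self.depth):
            raise ValueError("depth must be finite and non-negative")

    @property
    def frames_per_cycle(self) -> int:
        return _frames_per_cycle(self.frequency, self.refresh_rate)

    @property
    def on_frames(self) -> int:
        return round(self.duty_cycle * self.frames_per_cycle)

    @property
    def period(self) -> float:
        """Flicker period T = 1/f in seconds."""
        return 1.0 / self.frequency

    @property
    def diameter(self) -> float:
        """Physical disc diameter (m) from the constant-visual-angle rule."""
        return visual_angle_to_diameter(self.depth, self.visual_angle)


@dataclass(frozen=True)
class FlickerWaveform:
    """Sampled on/off intensity sequence of one flicker source."""

    samples: np.ndarray
    sample_rate: float
    period: float

    def mean_intensity(self) -> float:
        return float(np.mean(self.samples)) if self.samples.size else 0.0


def square_wave(
    spec: StimulusSpec, duration: float, sample_rate: float
) -> FlickerWaveform:
    """Sample the square-wave intensity S(t) of a flicker source.

    Within each period ``T = 1/f`` the source emits ``peak_intensity`` for
    the first ``duty_cycle * T`` seconds and 0 for the rest.  The sample
    rate must be an integer multiple of the flicker frequency so each cycle
    contains a whole number of samples (the frame-locked case: sampling at
    the refresh rate gives one sample per frame).
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    samples_per_cycle = sample_rate / spec.frequency
    m = round(samples_per_cycle)
    if m < 1 or abs(samples_per_cycle - m) > 1e-9 * m:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is not an integer multiple of "
            f"{spec.frequency} Hz; frame-locked sampling requires f = rate/m "
            "with integer m (cf. the f = refresh/n rule)"
        )
    on = spec.duty_cycle * m
    if abs(on - round(on)) > 1e-9:
        raise ValueError(
            "duty_cycle does not give a whole number of on-samples per cycle"
        )
    on = round(on)
    cycle = np.zeros(m)
    cycle[:on] = spec.peak_intensity
    n_samples = int(round(duration * sample_rate))
    reps = -(-n_samples // m) if n_samples else 0
    samples = np.tile(cycle, reps)[:n_samples]
    return FlickerWaveform(samples=samples, sample_rate=sample_rate, period=spec.period)


@dataclass(frozen=True)
class Trial:
    """One cue/flash/rest trial with absolute event times in seconds."""

    index: int
    environment: str
    depth: float
    frequency: float
    cue_onset: float
    stim_onset: float
    stim_offset: float
    rest_end: float
    round_index: int = 0


@dataclass
class TrialSchedule:
    """Ordered, non-overlapping trial sequence of a flicker session.

    Trials are blocked by depth (and, within a depth block, by frequency)
    by default: one frequency is shown for ``reps_per_cell`` consecutive
    flashes, one depth for ``reps_per_cell * n_frequencies`` flashes.
    """

    trials: list[Trial]
    cue_duration: float = 1.0
    stim_duration: float = 5.0
    rest_duration: float = 3.0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def trial_duration(self) -> float:
        return self.cue_duration + self.stim_duration + self.rest_duration

    @property
    def total_duration(self) -> float:
        return len(self.trials) * self.trial_duration

    @property
    def conditions(self) -> list[tuple[str, float, float]]:
        """Sorted unique (environment, depth, frequency) cells."""
        return sorted({(t.environment, t.depth, t.frequency) for t in self.trials})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    def to_events_tsv(self, path) -> None:
        """Write a BIDS-style events table (onset/duration/trial_type...)."""
        df = self.to_frame()
        events = pd.DataFrame(
            {
                "onset": df["stim_onset"],
                "duration": self.stim_duration,
                "trial_type": "flash",
                "frequency": df["frequency"],
                "depth": df["depth"],
                "environment": df["environment"],
            }
        )
        events.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "cue_duration": self.cue_duration,
            "stim_duration": self.stim_duration,
            "rest_duration": self.rest_duration,
            "trials": [t.__dict__ for t in self.trials],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TrialSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        trials = [Trial(**t) for t in payload["trials"]]
        return cls(
            trials=trials,
            cue_duration=payload["cue_duration"],
            stim_duration=payload["stim_duration"],
            rest_duration=payload["rest_duration"],
        )


def build_schedule(
    environments: Sequence[str],
    depths: Sequence[float],
    frequencies: Sequence[float],
    reps_per_cell: int = 10,
    cue_s: float = 1.0,
    stim_s: float = 5.0,
    rest_s: float = 3.0,
    order: str = "blocked",
    rng: np.random.Generator | None = None,
) -> TrialSchedule:
    """Build the blocked cue/flash/rest schedule of a session.

    Each environment scenario covers ``len(depths) * len(frequencies) *
    reps_per_cell`` trials; scenarios are concatenated.  ``order='blocked'``
    shows one frequency for ``reps_per_cell`` consecutive flashes within a
    depth block; ``order='randomized'`` shuffles trials within each
    scenario (requires ``rng``).
    """
    if not environments or not len(depths) or not len(frequencies):
        raise ValueError("environments, depths and frequencies must be non-empty")
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    if min(cue_s, stim_s, rest_s) <= 0:
        raise ValueError("cue, stimulus and rest durations must be positive")
    if order not in ("blocked", "randomized"):
        raise ValueError("order must be 'blocked' or 'randomized'")
    if order == "randomized" and rng is None:
        rng = np.random.default_rng()

    trials: list[Trial] = []
    t = 0.0
    index = 0
    trial_len = cue_s + stim_s + rest_s
    for env in environments:
        cells = [
            (depth, freq)
            for depth in depths
            for freq in frequencies
            for _ in range(reps_per_cell)
        ]
        if order == "randomized":
            cells = [cells[i] for i in rng.permutation(len(cells))]
        for depth, freq in cells:
            trials.append(
                Trial(
                    index=index,
                    environment=env,
                    depth=float(depth),
                    frequency=float(freq),
                    cue_onset=t,
                    stim_onset=t + cue_s,
                    stim_offset=t + cue_s + stim_s,
                    rest_end=t + trial_len,
                )
            )
            t += trial_len
            index += 1
    return TrialSchedule(
        trials=trials, cue_duration=cue_s, stim_duration=stim_s, rest_duration=rest_s
    )
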