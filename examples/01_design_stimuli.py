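"""Design frame-locked flicker stimuli and the session schedule.

Builds the canonical blocked session (3 depths x 3 frequencies x 10
flashes) and prints the geometry and frame arithmetic behind it.
"""

from ssvep_depth_lab import (
    StimulusSpec,
    admissible_frequencies,
    build_schedule,
    square_wave,
    visual_angle_to_diameter,
)

# A constant 2.07 degree visual angle means the physical disc grows with
# viewing distance; these are the diameters the renderer must draw.
for depth in (0.4, 1.0, 1.8):
    d = visual_angle_to_diameter(depth, 2.07)
    print(f"depth {depth:>3} m -> diameter {d * 100:.2f} cm")

# On a 90 Hz display only f = 90/n avoids cut-off flicker frames.
print("\nframe-locked frequencies for n = 5..12:")
for n, f in admissible_frequencies(90, 5, 12):
    print(f"  n = {n:>2}: {f:.2f} Hz")

# One 11.25 Hz cycle at 50% duty spans 8 frames: 4 on, 4 off.
spec = StimulusSpec(frequency=11.25, refresh_rate=90, duty_cycle=0.5)
wf = square_wave(spec, duration=8 / 90, sample_rate=90)
print(f"\n11.25 Hz frame pattern: {wf.samples.astype(int).tolist()}")

# The full session: cue 1 s, flash 5 s, rest 3 s per trial.
sched = build_schedule(["MR"], [0.4, 1.0, 1.8], [7.5, 11.25, 18.0], 10)
print(f"\nschedule: {len(sched)} trials, {sched.total_duration / 60:.1f} min")
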