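"""Simulate a three-bat group flight and look at the ground truth.

Builds the narrow-space scene (2 x 4.5 x 2.4 m), generates looping
trajectories, a Doppler-shift-compensated vocalization schedule and the
three telemetry-microphone channels, then prints what was put into them.
"""

import numpy as np

from sonarjam import (make_scene, simulate_trajectories,
                      simulate_vocalizations, render_telemetry_waveforms,
                      mean_pairwise_distance, write_scene)

scene = make_scene("narrow", n_bats=3, duration=10.0, seed=7)
trajs = simulate_trajectories(scene)
emissions = simulate_vocalizations(scene, trajs)
waves, ground_truth = render_telemetry_waveforms(scene, trajs, emissions)

print(f"chamber {scene.chamber_dims} m, {scene.n_bats} bats, "
      f"{scene.duration:.0f} s at {scene.sample_rate:.0f} Hz")
for tr in trajs:
    print(f"  bat {tr.bat_id}: mean speed {tr.speeds().mean():.2f} m/s, "
          f"RF {scene.profiles[tr.bat_id].reference_frequency:.0f} Hz")
print(f"mean inter-bat distance: {mean_pairwise_distance(trajs):.2f} m")
print(f"{len(emissions)} pulses emitted; per-pulse emitted CF2 spans "
      f"{emissions.cf2_emit_hz.min():.0f}-{emissions.cf2_emit_hz.max():.0f} Hz")
ech = ground_truth.arrivals.query("kind == 'own_echo'")
print(f"{len(ech)} wall echoes rendered; with full compensation their CF2 "
      f"sits at each bat's reference frequency "
      f"(sd {ech.groupby('channel_bat_id').cf2_arrival_hz.std().max():.2e} Hz)")

out = write_scene("scratch/example_scene", scene, trajs, waves, ground_truth)
print(f"scene written to {out} (WAV per channel + TSV tables)")
# The emitted CF2 sits ~0.5-1.5 kHz below each bat's reference frequency
# while it approaches a wall: that is Doppler shift compensation at work.
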