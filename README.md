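# sonarjam

Simulation and analysis of group-flight echolocation in CF-FM bats —
how Doppler-shift-compensating horseshoe bats keep hearing their own
echoes while flying with noisy conspecifics.

Japanese horseshoe bats (*Rhinolophus ferrumequinum nippon*) emit long
constant-frequency pulses whose dominant second harmonic (CF2, ~68–70 kHz)
is individually stereotyped. In flight each bat lowers its emitted CF2 so
that the wall echo, up-shifted by the two-way Doppler effect, returns at a
fixed individual *reference frequency* (RF) — the centre of its auditory
fovea. When three bats fly together, every bat also receives the other
bats' pulses, Doppler-shifted by the pairwise relative velocities. This
package provides, for researchers in bioacoustics and behavioural
neuroethology:

* a physics-based generator of synthetic group-flight sessions —
  trajectories, compensation-governed vocalization schedules, and per-bat
  telemetry-microphone waveforms with exact ground truth;
* automatic pulse/echo detection, segmentation and feature measurement
  (CF2 by 16 384-point FFT, tFM bandwidth/duration, pulse duration, sonar
  sound groups and silent times), replacing manual spectrogram reading
  with documented criteria;
* trajectory-based estimation of the CF2 of other bats' pulses as audible
  to each listener;
* reference-frequency statistics (per-flight mean and s.d., ΔRF between
  the two group members closest in RF, RF-normalized frequency
  distributions);
* linear-mixed-model comparisons of acoustic features across flight
  conditions, with a simulation harness validating their calibration.

## The model

Doppler shift compensation with gain *g* toward a reflector approached at
closing speed *v* (sound speed *C*):

```
CF2_emit = RF * ((C − v) / (C + v))^g          # g = 1: echo returns at RF
```

Flight directions from smoothed trajectories (10th-order polynomials per
5-s segment), at frame *n*:

```
θ_n = atan2(y_n − y_{n−1}, x_n − x_{n−1})       # x–y azimuth
φ_n = atan2(z_n − z_{n−1}, |x_n − x_{n−1}|)     # x–z inclination
```

Relative radial velocity of emitter B with respect to listener A, with
inter-bat bearings θ_AB, φ_AB:

```
v_BA = v_B cos(θ_B − θ_AB) cos(φ_B − φ_AB) − v_A cos(θ_A − θ_AB) cos(φ_A − φ_AB)
```

and the CF2 of B's pulse audible to A, in two modes (always labelled):

```
CF2_BA = CF2_B * C / (C − |v_BA|)     # "as_printed": every estimate an up-shift
CF2_BA = CF2_B * C / (C + v_BA)       # "signed": down-shifts receding pairs
```

An exact 3-D projection `v_BA = (v⃗_B − v⃗_A)·û_AB` is available alongside
the cosine-product form (which is exact only for planar motion).

## Worked example

`python examples/02_measure_pulses_and_reference_frequency.py` simulates
one bat flying the narrow (2 × 4.5 × 2.4 m) space for 5 s and analyses
its telemetry channel:

```
emitted 77 pulses; detected 77 focal pulses
pulse duration 22.7 ms, tFM bandwidth 13.8 kHz, tFM duration 1.80 ms
58 sonar sound groups; mean silent time 52.1 ms
reference frequency: 68398.2 +/- 0.8 Hz from 90 echoes (true set-point 68398.2 Hz)
```

Every emitted pulse is recovered; the echo-derived reference frequency
matches the generator's set-point to sub-Hz precision — the s.d. is far
below the ~31 Hz analysis bin because the compensation loop is closed.

`python examples/03_received_frequencies.py` adds two more bats and
contrasts what each bat hears:

```
bat 0: own echoes sd 0.3 Hz (n=11), conspecific estimates sd 431.8 Hz (n=288)
bat 1: own echoes sd 0.9 Hz (n=8), conspecific estimates sd 600.1 Hz (n=296)
bat 2: own echoes sd 1.1 Hz (n=12), conspecific estimates sd 708.3 Hz (n=298)
```

Own echoes stay pinned to the reference frequency while conspecific
pulses arrive spread over hundreds of Hz — the frequency contrast that
lets a sharply tuned auditory fovea reject conspecific jamming.

The other examples cover scene generation/ground truth
(`01_simulate_group_flight.py`) and the mixed-model condition comparison
(`04_condition_comparison.py`). A thin CLI mirrors the stages
(`sonarjam simulate | analyze-audio | doppler | metrics | stats | run`).

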