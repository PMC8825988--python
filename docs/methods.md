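# Methods

## Overview

The package models a telemetry-microphone experiment: horseshoe bats
flying alone or in groups of three in an echoic chamber, each carrying a
microphone that records its own pulses, the wall echoes of those pulses
and the other bats' pulses. Because no recordings of this kind are
publicly deposited, the package pairs every analysis stage with a
physics-based generator so that each stage can be validated against
exact ground truth.

## Synthetic scenes

**Chamber and kinematics.** Presets mirror the experimental spaces: a
full 9 × 4.5 × 2.4 m chamber partitioned into "wide" (6 × 4.5 × 2.4 m)
and "narrow" (2 × 4.5 × 2.4 m) flight spaces. Bats fly elliptical loops
with a linearly advancing phase plus slow (< 0.3 Hz) wobbles of phase,
loop radius and height. This construction is deliberately band-limited:
every coordinate must be representable by a 10th-order polynomial over a
5-s window, the smoothing applied downstream, so the generator cannot
hide spectral content the analysis could never follow. Instantaneous
speed therefore covaries with path curvature; the configured speed band
constrains each bat's *mean* speed (defaults: 1.8–2.6 m/s narrow,
2.3–3.1 m/s wide, matching the slower flight observed in confined
space). A degenerate band selects a circular loop, making instantaneous
speed exactly constant. Mean inter-bat distance comes out smaller in the
narrow than the wide space (≈1.4 vs ≈2.5 m), reproducing the
confinement contrast.

**Vocalizations.** Each bat draws CF-FM pulses (defaults: duration
23 ± 2 ms, tFM 1.8 ± 0.2 ms sweeping 14 ± 1.2 kHz downward, optional
weak iFM present half the time) organised into sonar sound groups;
intra- and inter-group intervals are offset-to-onset gaps (defaults
10 ± 2 ms and 52 ± 5 ms; the inter-group gap is the silent time).
Reference frequencies are drawn uniformly over 68.2–69.4 kHz,
reproducing a colony-typical ≤1.2 kHz spread. Each pulse's emitted CF2
follows Doppler shift compensation with gain *g* toward the side wall
with the largest closing speed: `CF2_emit = RF·((C−v)/(C+v))^g`, so at
*g* = 1 (the default) the first-order wall echo returns at exactly RF.
Floor and ceiling are excluded as reflectors; when the bat closes on no
side wall it emits at RF and the echo Doppler uses the (possibly
negative) closing speed toward the wall ahead, which contributes a
small, realistic spread to echo frequencies.

**Rendering.** Pulses are synthesized as phase-continuous frequency
trajectories (fundamental = CF2/2; CF1 at −20 dB, CF2 dominant; higher
harmonics off by default), with 0.15-ms raised-cosine ramps and a −10 dB
iFM segment. Each channel receives: the bat's own pulses at a nominal
0.5 amplitude (mouth-to-mic distance 0.1 m); the first-order
image-source echo with two-way Doppler, 1/r spreading and a flat −6 dB
wall loss; and the other bats' pulses with one-way Doppler from the
instantaneous source and receiver velocities at emission time (pulse
durations are short relative to manoeuvre timescales) and 1/r
spreading. Doppler scales frequencies by *q* and durations by 1/*q*.
Amplitude constants are free parameters — the source levels of the real
system are unknown — chosen so that echoes sit 20–35 dB and conspecific
pulses 15–30 dB below own pulses, the regime the classification rules
are designed for. Atmospheric absorption and higher-order reflections
are omitted (echoes only serve reference-frequency estimation).

**What the generator does not emulate.** Behavioural responses
(obstacle avoidance, jamming-induced feature shifts), room reverberation
beyond first-order images, telemetry-channel noise and dropouts, and
imperfect compensation (the gain is constant per bat). Passing tests
therefore demonstrate that the analysis chain recovers what the model
puts in at realistic geometry and SNR — not that it is robust to every
artefact of real telemetry recordings.

## Sound analysis

All level thresholds are dB relative to the channel maximum. The
channel is bandpassed to 10–200 kHz (zero-phase Butterworth). Events
are detected where a block-maximum envelope (16-sample blocks, 0.032 ms)
exceeds max(−40 dB, rolling noise floor + 12 dB); the floor is a rolling
median of per-50-ms 1st percentiles, which stays pinned to the quiet
gaps even at high duty cycle. Runs are bridged across gaps < 1 ms,
events shorter than 2 ms are dropped, and within each run, portions more
than 20 dB below the run peak hanging off its ends are split into their
own events — this separates the trailing part of a wall echo from the
pulse it overlaps.

CF2 is measured on the CF plateau: the longest run of ridge frames
(256-sample window, 32-sample hop) whose instantaneous-frequency slope
stays below 1 kHz/ms, trimmed 0.25 ms at each end; the plateau samples
are Hann-windowed and zero-padded into a 16 384-point FFT (bin width
fs/16384 ≈ 31 Hz at 500 kHz; zero-padding is flagged), with a parabolic
refinement of the peak reported alongside the raw bin. The terminal
sweep is the post-plateau ridge more than 1 kHz below CF2; a straight
line fitted to it is extrapolated to the event offset, so the measured
bandwidth does not lose the final half-window of the sweep. iFM is
declared when a rising ridge ≥ 2 kHz below CF2 precedes the plateau.

**Classification** works across time-synchronized channels: an event is
a focal pulse where its absolute level is within 6 dB of the loudest
overlapping event on any channel (the margin keeps simultaneous pulses
of different bats from suppressing each other, while a remote copy
~20 dB down is still rejected); a weaker event starting while a remote
focal pulse could still be arriving (source span + 15 ms propagation
horizon) is that bat's pulse; weaker same-channel events in a 3–60 ms
echo window and within ±2 kHz of the focal CF2 are own echoes.

**Overlapping echoes.** At this geometry (pulse 20–27 ms, wall distance
0.7–2 m, delay 4–12 ms) the wall echo rides on top of its own pulse and
never triggers the envelope detector. It is recovered spectrally: inside
each pulse's CF window the echo appears as a secondary peak near the
pulse CF2, separated by the two-way Doppler shift. The search notch
around the carrier adapts to the window's mainlobe width (≥4.5 window
bins), the peak must stand ≥15 dB above the band median and within 45 dB
of the carrier, and pulses whose CF window may contain another bat's
pulse are skipped (any loud other-channel event within the propagation
horizon). Echoes hidden inside the notch (closing speed ≲ 0.8 m/s) are
simply not reported; since compensated echoes sit at RF regardless of
speed, this costs sample size, not accuracy.

## Trajectory smoothing and received frequencies

Each coordinate is fitted with a 10th-order polynomial per 5-s segment
on time rescaled to [−1, 1] (plain least squares; the rescaling keeps
the Vandermonde system well conditioned at order 10). Flights are cut
into consecutive 5-s windows; a trailing remainder shorter than 2.5 s is
merged backward. Residual RMS is reported; noiseless generator loops fit
to a few mm.

Azimuths use the full-quadrant `atan2` throughout. The x–z inclination
keeps the dz-over-dx convention but is computed as `atan2(dz, |dx|)`:
putting the x-quadrant into φ as well would flip the cosine product's
sign for westbound planar flight and break the identity that, for
z-constant motion, the angle-decomposition relative velocity equals the
exact 2-D projection. Even so, the dz-over-dx convention is singular
where |dx| ≪ |dz| (flight along the y-axis), so the cosine-product form
is an approximation for genuinely 3-D motion; the `exact3d` mode
projects the velocity difference on the line of sight and is exact.

Received CF2 is computed in two labelled modes, neither silently
corrected into the other: `as_printed` (`C/(C−|v_BA|)`, every estimate
an up-shift — the magnitude form cannot represent receding pairs) and
`signed` (`C/(C+v_BA)`, physically directional). Geometry defaults to
the video frame nearest each emission; sub-frame evaluation of the
fitted polynomials (with analytic derivatives) is available and removes
the half-frame quantisation (~0.13 m/s at 30 fps, i.e. ~26 Hz at
68.5 kHz). Physical validation against waveform-level ground truth
therefore uses signed + exact3d + sub-frame, where >95% of clean-pulse
estimates agree within one analysis bin; the angle form with
nearest-frame evaluation, kept as the default for fidelity to the
formulas above, reaches only ~15–35% at that tolerance on 3-D paths —
both numbers are reported by the acceptance script.

## Jamming metrics

The reference frequency is the per-flight mean of a bat's own-echo CF2
(contaminated echo windows excluded); its s.d. measures compensation
precision. ΔRF is each bat's signed difference from the group member
nearest in RF, with the group's closest pair marked (ties break toward
the lower bat id); signed and absolute values are both emitted. For the
normalized distributions, own-echo and estimated conspecific frequencies
have the listener's RF subtracted and are histogrammed at 50 Hz (echoes)
and 200 Hz (estimates) over ±4 kHz, with sd and IQR per source.

## Statistics

The analysis unit is the per-flight mean (per-pulse observations are
not pooled across flights). Models are fitted by REML via `statsmodels`
`MixedLM`: response ~ condition × space with bat as a random intercept;
the RF s.d. is modelled per space with condition only, since its
distribution differs strongly between spaces and wide-space estimates
can be excluded outright via a flag. Fixed effects are screened with
Wald χ² tests per term under sum-to-zero coding (equivalent to the
classical type II/III analysis on balanced designs). Pairwise condition
contrasts use containment degrees of freedom
(observations − subjects − non-intercept fixed effects; 27/9/3 → 16,
the classical repeated-measures error df) and the Tukey–Kramer
studentized-range adjustment. The simulation harness validates this
exact path: on null tables (9 bats × 3 conditions, σ_bat = 0.5,
σ_res = 1.0) the unadjusted group-vs-single contrast rejects at
0.046 ± 0.01 across seeds (500 replicates per run), the Tukey-adjusted
single-contrast rate is conservative by construction (~0.02), and an
injected +3 kHz group effect is detected (both adjusted contrasts
significant) in >99% of 200 replicates.

## Problem sizes and determinism

Validation scenes are 3 bats × 20 s (group) and 1 bat × 5 s (single) in
the narrow space at 500 kHz sampling and 30 fps — roughly 900 and 77
pulses respectively, enough to estimate recovery rates to a few percent
while keeping the full suite to a couple of minutes. Every stochastic
draw descends from a single scene seed through fixed per-stream salts;
identical seeds reproduce waveforms, schedules and pipeline artifact
checksums bit for bit.

## Known limitations

* The cosine-product relative velocity degrades off-plane near the
  dz/dx singularity; use `exact3d` when physical accuracy matters.
* The overlapping-echo extractor requires the echo to be
  Doppler-separated from the carrier by the adaptive notch width and
  assumes at most one dominant reflector; multi-wall echoes (the reason
  wide-space reference frequencies are noisy in practice) are not
  modelled or resolved.
* Classification assumes the emitter's channel records its own pulse at
  much higher level than any conspecific copy; with bats closer than
  ~0.2 m the 6 dB focal margin could misassign events.
* Generator amplitudes are plausible but unconstrained by measured
  source levels; absolute-level analyses are out of scope.
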