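"""Doppler-shift-compensated vocalization schedules and waveform rendering.

Horseshoe bats emit CF-FM pulses whose dominant second-harmonic CF
component (CF2) is actively lowered in flight so that the wall echo —
up-shifted by the two-way Doppler effect — returns at the bat's individual
*reference frequency* (RF).  With compensation gain ``g`` the emitted CF2 is

    CF2_emit = RF * ((C - v) / (C + v)) ** g

where ``v`` is the closing speed toward the reflecting wall and ``C`` the
speed of sound.  At ``g = 1`` the echo from a stationary wall returns at
exactly RF; at ``g = 0`` the bat emits at RF and the echo is up-shifted.

Rendering places, on each bat's telemetry-microphone channel:

* the bat's own pulses at full level,
* the first-order image-source echo from the wall the bat is flying
  toward, with two-way Doppler, 1/r spreading and a flat wall loss,
* the other bats' pulses with one-way Doppler from the instantaneous
  radial relative velocity and 1/r spreading.

Every arrival is logged with its true Doppler-shifted CF2 so downstream
feature extraction can be scored against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import SimulationScene, VocalProfile, _subseed
from .trajectories import Trajectory

__all__ = [
    "GroundTruth",
    "dsc_emitted_cf2",
    "simulate_vocalizations",
    "render_telemetry_waveforms",
    "synth_cf_fm_pulse",
]

log = logging.getLogger(__name__)

#: reference distance (m) at which a pulse has its nominal amplitude; the
#: telemetry mic rides on the bat's back about this far from the mouth
MIC_DISTANCE = 0.1
#: nominal peak amplitude of an own pulse on its own channel
OWN_PULSE_AMP = 0.5

EMISSION_COLUMNS = [
    "bat_id", "pulse_id", "group_id", "t_emit", "duration_ms",
    "ifm_duration_ms", "tfm_duration_ms", "ifm_bandwidth_hz",
    "tfm_bandwidth_hz", "has_ifm", "cf2_emit_hz", "v_wall_mps", "wall"]

ARRIVAL_COLUMNS = [
    "channel_bat_id", "source_bat_id", "pulse_id", "kind", "t_arrival",
    "cf2_arrival_hz", "doppler_factor", "amplitude", "level_db", "wall"]


@dataclass
class GroundTruth:
    """Oracle record of everything the simulator put into the waveforms.

    ``emissions`` has one row per emitted pulse (columns
    ``EMISSION_COLUMNS``); ``arrivals`` one row per component landing on a
    channel (columns ``ARRIVAL_COLUMNS``, ``kind`` in
    {own_pulse, own_echo, other_pulse}).
    """

    emissions: pd.DataFrame
    arrivals: pd.DataFrame

    def validate(self) -> None:
        emitted_ids = set(zip(self.emissions.bat_id, self.emissions.pulse_id))
        arr_ids = set(zip(self.arrivals.source_bat_id, self.arrivals.pulse_id))
        if not arr_ids <= emitted_ids:
            raise ValueError("arrival refers to a pulse never emitted")
        merged = self.arrivals.merge(
            self.emissions, left_on=["source_bat_id", "pulse_id"],
            right_on=["bat_id", "pulse_id"])
        if np.any(merged.t_arrival.to_numpy() < merged.t_emit.to_numpy() - 1e-12):
            raise ValueError("arrival precedes emission")


def dsc_emitted_cf2(reference_frequency: float,
                    closing_speed: float,
                    compensation_gain: float = 1.0,
                    sound_speed: float = 343.5) -> float:
    """Emitted CF2 under Doppler shift compensation.

    ``closing_speed`` is positive when the bat approaches the reflector.
    Full compensation (gain 1) makes the two-way echo from a stationary
    reflector return at exactly ``reference_frequency``.
    """
    if abs(closing_speed) >= sound_speed:
        raise ValueError("closing speed must be below the speed of sound")
    ratio = (sound_speed - closing_speed) / (sound_speed + closing_speed)
    return reference_frequency * ratio ** compensation_gain


def _wall_normals_and_distances(pos: np.ndarray, dims) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit normals and distances to the four side walls."""
    lx, ly, _ = dims
    normals = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0, -1.0, 0], [0, 1.0, 0]])
    dists = np.array([pos[0], lx - pos[0], pos[1], ly - pos[1]])
    return normals, dists


def select_wall(pos: np.ndarray, vel: np.ndarray, dims) -> tuple[int, float, float]:
    """Pick the side wall the bat is flying toward.

    Returns (wall index 0..3, distance to wall, closing speed toward it).
    The wall with the largest closing speed is chosen; if the bat closes on
    no wall (purely vertical or zero velocity) the nearest wall is used and
    the (non-positive) closing speed toward it is reported.
    """
    normals, dists = _wall_normals_and_distances(pos, dims)
    closing = normals @ vel
    i = int(np.argmax(closing))
    if closing[i] <= 0.0:
        i = int(np.argmin(dists))
    return i, float(dists[i]), float(closing[i])


def _draw_trunc(rng, mean_sd, lo=1e-6):
    mean, sd = mean_sd
    return max(lo, float(rng.normal(mean, sd)))


def _interp_state(traj: Trajectory, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Position and velocity at time ``t`` (linear interp / central diff)."""
    pos = np.array([np.interp(t, traj.t, traj.xyz[:, k]) for k in range(3)])
    vel_frames = np.gradient(traj.xyz, traj.t, axis=0)
    vel = np.array([np.interp(t, traj.t, vel_frames[:, k]) for k in range(3)])
    return pos, vel


class _TrajInterp:
    """Vectorised position/velocity interpolation along one trajectory."""

    def __init__(self, traj: Trajectory):
        self.t = traj.t
        self.xyz = traj.xyz
        self.vel = np.gradient(traj.xyz, traj.t, axis=0)

    def pos(self, t):
        return np.stack([np.interp(t, self.t, self.xyz[:, k])
                         for k in range(3)], axis=-1)

    def v(self, t):
        return np.stack([np.interp(t, self.t, self.vel[:, k])
                         for k in range(3)], axis=-1)


def simulate_vocalizations(scene: SimulationScene,
                           trajectories: list[Trajectory]) -> pd.DataFrame:
    """Draw the emitted-pulse schedule for every bat.

    Pulses are organised into sonar sound groups; intra- and inter-group
    intervals are offset-to-onset gaps (the inter-group gap is the silent
    time).  Each pulse's emitted CF2 follows the bat's Doppler shift
    compensation toward the wall it is flying at.
    """
    if len(trajectories) != scene.n_bats:
        raise ValueError("one trajectory per bat required")
    rows = []
    for b, (profile, traj) in enumerate(zip(scene.profiles, trajectories)):
        rng = np.random.default_rng(_subseed(scene.seed, 0x5EED + 31 * b))
        interp = _TrajInterp(traj)
        sizes = np.array(sorted(profile.pulses_per_group))
        weights = np.array([profile.pulses_per_group[k] for k in sizes],
                           dtype=float)
        weights /= weights.sum()
        t = float(rng.uniform(0.0, 0.06))
        pulse_id = group_id = 0
        max_dur = profile.pulse_duration[0] + 4 * profile.pulse_duration[1]
        while True:
            n_in_group = int(rng.choice(sizes, p=weights))
            for i in range(n_in_group):
                dur = _draw_trunc(rng, profile.pulse_duration, lo=2.0)
                tfm_d = _draw_trunc(rng, profile.tfm_duration, lo=0.3)
                tfm_bw = _draw_trunc(rng, profile.tfm_bandwidth, lo=500.0)
                has_ifm = bool(rng.random() < profile.ifm_present)
                ifm_d = _draw_trunc(rng, profile.ifm_duration, lo=0.3) if has_ifm else 0.0
                ifm_bw = _draw_trunc(rng, profile.ifm_bandwidth, lo=500.0) if has_ifm else 0.0
                if t + dur / 1e3 > scene.duration - max_dur / 1e3:
                    break
                pos, vel = interp.pos(t), interp.v(t)
                wall, dist, v_wall = select_wall(pos, vel, scene.chamber_dims)
                cf2 = dsc_emitted_cf2(
                    profile.reference_frequency, max(0.0, v_wall),
                    profile.compensation_gain, scene.sound_speed)
                rows.append((b, pulse_id, group_id, t, dur, ifm_d, tfm_d,
                             ifm_bw, tfm_bw, has_ifm, cf2, v_wall, wall))
                pulse_id += 1
                gap = (profile.intra_group_interval if i < n_in_group - 1
                       else profile.inter_group_interval)
                t += dur / 1e3 + max(0.0, float(rng.normal(*gap))) / 1e3
            else:
                group_id += 1
                continue
            break
    df = pd.DataFrame(rows, columns=EMISSION_COLUMNS)
    return df.sort_values(["bat_id", "pulse_id"]).reset_index(drop=True)


def synth_cf_fm_pulse(fs: float, cf2: float, duration_ms: float,
                      tfm_duration_ms: float, tfm_bandwidth_hz: float,
                      ifm_duration_ms: float = 0.0,
                      ifm_bandwidth_hz: float = 0.0,
                      harmonic_levels_db=(-20.0, 0.0),
                      doppler_factor: float = 1.0,
                      amplitude: float = 1.0,
                      ramp_ms: float = 0.15) -> np.ndarray:
    """Synthesize one CF-FM pulse as heard after a Doppler factor ``q``.

    The fundamental follows a piecewise-linear frequency law: optional iFM
    up-sweep, CF plateau at ``cf2 / 2``, terminal down-sweep over
    ``tfm_bandwidth_hz``.  Doppler scales all frequencies by ``q`` and
    durations by ``1 / q``.  Harmonics are phase-locked multiples of the
    fundamental with the given levels (last entry = CF2, the dominant one).
    """
    q = doppler_factor
    n = int(round(duration_ms / 1e3 / q * fs))
    if n < 4:
        return np.zeros(0)
    # emitted-frame time of each output sample
    te = np.arange(n) / fs * q
    f1 = np.full(n, cf2 / 2.0)
    ifm_s = ifm_duration_ms / 1e3
    tfm_s = tfm_duration_ms / 1e3
    dur_s = duration_ms / 1e3
    if ifm_s > 0:
        m = te < ifm_s
        f1[m] = (cf2 - ifm_bandwidth_hz * (1 - te[m] / ifm_s)) / 2.0
    m = te > dur_s - tfm_s
    frac = (te[m] - (dur_s - tfm_s)) / tfm_s
    f1[m] = (cf2 - tfm_bandwidth_hz * frac) / 2.0
    phase = 2 * np.pi * np.cumsum(f1 * q) / fs
    wave = np.zeros(n)
    for h, lvl in enumerate(harmonic_levels_db, start=1):
        wave += 10 ** (lvl / 20.0) * np.sin(h * phase)
    # raised-cosine on/off ramps; weak iFM segment
    env = np.ones(n)
    nr = min(n // 2, int(round(ramp_ms / 1e3 / q * fs)))
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] *= r
        env[-nr:] *= r[::-1]
    if ifm_s > 0:
        m = te < ifm_s
        env[m] *= 10 ** (-10.0 / 20.0)
    return amplitude * env * wave


def render_telemetry_waveforms(
        scene: SimulationScene, trajectories: list[Trajectory],
        emissions: pd.DataFrame) -> tuple[np.ndarray, GroundTruth]:
    """Render per-bat microphone channels and the full ground-truth log.

    Returns ``(waves, gt)`` where ``waves`` has shape
    ``(n_bats, n_samples)``.
    """
    fs = scene.sample_rate
    c = scene.sound_speed
    n_samples = scene.n_samples
    waves = np.zeros((scene.n_bats, n_samples))
    interps = [_TrajInterp(tr) for tr in trajectories]
    levels = scene.harmonic_levels_db
    arr_rows = []
    truncated = 0

    def _place(ch, t_arr, pulse, q, amp, kind, src, wall):
        nonlocal truncated
        w = synth_cf_fm_pulse(
            fs, pulse.cf2_emit_hz, pulse.duration_ms, pulse.tfm_duration_ms,
            pulse.tfm_bandwidth_hz, pulse.ifm_duration_ms,
            pulse.ifm_bandwidth_hz, levels, q, amp)
        i0 = int(round(t_arr * fs))
        if i0 >= n_samples:
            truncated += 1
            return
        i1 = min(n_samples, i0 + len(w))
        if i1 < i0 + len(w):
            truncated += 1
        waves[ch, i0:i1] += w[: i1 - i0]
        arr_rows.append((ch, src, int(pulse.pulse_id), kind, t_arr,
                         pulse.cf2_emit_hz * q, q, amp,
                         20 * np.log10(amp / OWN_PULSE_AMP), wall))

    for pulse in emissions.itertuples(index=False):
        b = int(pulse.bat_id)
        t0 = float(pulse.t_emit)
        pos_b = interps[b].pos(t0)
        vel_b = interps[b].v(t0)
        # own pulse, at the on-animal mic a mouth-to-back distance away
        _place(b, t0 + MIC_DISTANCE / c, pulse, 1.0, OWN_PULSE_AMP,
               "own_pulse", b, -1)
        # first-order image-source echo from the wall flown toward
        if np.isfinite(scene.wall_loss_db):
            wall, dist, v_wall = select_wall(pos_b, vel_b, scene.chamber_dims)
            q = (c + v_wall) / (c - v_wall)
            amp = (OWN_PULSE_AMP * MIC_DISTANCE / max(2 * dist, MIC_DISTANCE)
                   * 10 ** (scene.wall_loss_db / 20.0))
            _place(b, t0 + 2 * dist / c, pulse, q, amp, "own_echo", b, wall)
        # conspecific arrivals with one-way Doppler
        for a in range(scene.n_bats):
            if a == b:
                continue
            pos_a = interps[a].pos(t0)
            vel_a = interps[a].v(t0)
            u = pos_a - pos_b
            d = float(np.linalg.norm(u))
            u /= max(d, 1e-9)
            # moving source (B) and moving receiver (A)
            q = (c - float(vel_a @ u)) / (c - float(vel_b @ u))
            amp = (OWN_PULSE_AMP * scene.conspecific_gain * MIC_DISTANCE
                   / max(d, MIC_DISTANCE))
            _place(a, t0 + d / c, pulse, q, amp, "other_pulse", b, -1)

    if truncated:
        log.warning("%d arrivals truncated at the waveform end", truncated)
    if scene.noise_rms > 0:
        rng = np.random.default_rng(_subseed(scene.seed, 0x0153))
        waves += rng.normal(0.0, scene.noise_rms, size=waves.shape)
    waves = waves.astype(np.float32)
    arrivals = pd.DataFrame(arr_rows, columns=ARRIVAL_COLUMNS)
    arrivals = arrivals.sort_values(
        ["channel_bat_id", "t_arrival"]).reset_index(drop=True)
    gt = GroundTruth(emissions=emissions, arrivals=arrivals)
    gt.validate()
    return waves, gt
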