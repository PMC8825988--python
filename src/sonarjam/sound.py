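"""Pulse/echo detection and acoustic feature measurement.

Replaces manual spectrogram reading of telemetry-microphone recordings
with documented automatic criteria:

* events are detected where the band-limited envelope exceeds a threshold
  relative to the channel maximum (with a rolling-median noise floor),
  bridged across sub-millisecond gaps, and split where a weak tail (e.g. a
  trailing wall echo) hangs off a much stronger core;
* CF2 is the peak of a 16 384-point FFT over the automatically selected CF
  plateau (instantaneous-frequency slope below 1 kHz/ms), reported both as
  the raw bin and parabolically interpolated, with bin width fs / 16 384;
* tFM bandwidth/duration come from a line fit to the frequency ridge of
  the terminal sweep; iFM presence from a rising ridge before the plateau;
* events are classified across synchronized channels as focal pulse, own
  echo or another bat's pulse from relative level and timing;
* wall echoes that overlap the emitting pulse (the usual case at
  room-scale wall distances) are recovered as a secondary spectral peak
  near the pulse CF2 inside the pulse's own CF window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "AnalysisConfig", "SoundEvent", "bandpass", "spectrogram",
    "detect_events", "estimate_cf2", "measure_components",
    "classify_events", "extract_overlapping_echoes",
    "group_and_silent_times", "analyze_channels", "events_to_frame",
]


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the automatic analysis.

    All level thresholds are dB relative to the channel maximum unless
    noted; durations in ms; frequencies in Hz.
    """

    band: tuple = (10_000.0, 200_000.0)   # analysis bandpass
    threshold_db: float = -40.0           # detection threshold rel. channel max
    noise_margin_db: float = 12.0         # ... but at least this far above floor
    min_dur_ms: float = 2.0
    merge_gap_ms: float = 1.0
    split_drop_db: float = 20.0           # weak-tail split depth rel. event peak
    env_block: int = 16                   # envelope resolution, samples
    n_fft: int = 16_384                   # CF2 analysis transform length
    fm_window: int = 256                  # ridge-tracking STFT window
    fm_hop: int = 32
    cf_slope_hz_per_ms: float = 1_000.0   # CF plateau slope criterion
    ridge_floor_db: float = -20.0         # ridge valid above event peak + this
    tfm_drop_hz: float = 1_000.0          # tFM starts this far below CF2
    ifm_drop_hz: float = 2_000.0
    echo_window_ms: tuple = (3.0, 60.0)   # separate-event echo timing window
    echo_cf2_tol_hz: float = 2_000.0
    other_window_ms: float = 15.0         # max conspecific propagation delay
    echo_notch_hz: float = 150.0          # overlap extractor: carrier notch
    echo_rel_floor_db: float = -45.0      # min secondary peak rel. main peak
    echo_prominence_db: float = 15.0      # min secondary peak above band median
    echo_demote_db: float = 6.0           # focal→echo demotion level margin
    focal_margin_db: float = 6.0          # focal if within this of loudest rival
    echo_min_level_db: float = -60.0      # ignore echoes below this, rel. max
    group_gap_ms: float = 30.0            # sonar-sound-group gap threshold


@dataclass
class SoundEvent:
    """One detected pulse or echo on a telemetry channel."""

    channel_bat_id: int
    onset: float
    offset: float
    kind: str = "unknown"
    peak_level_db: float = 0.0      # dB rel. channel max
    peak_amp: float = 0.0           # absolute linear peak
    cf2: float = math.nan           # parabolic-interpolated CF2 (Hz)
    cf2_raw: float = math.nan       # raw FFT-bin CF2 (Hz)
    cf2_bin_width: float = math.nan
    cf_start: float = math.nan      # CF plateau bounds (s)
    cf_end: float = math.nan
    tfm_onset: float = math.nan
    tfm_bandwidth: float = math.nan
    tfm_duration: float = math.nan  # ms
    ifm_detected: bool = False
    flags: str = ""

    @property
    def pulse_duration(self) -> float:
        """Event duration in ms (iFM included when present)."""
        return (self.offset - self.onset) * 1e3

    def flag(self, name: str) -> None:
        if name not in self.flags.split("|"):
            self.flags = f"{self.flags}|{name}" if self.flags else name


def events_to_frame(events: list[SoundEvent]) -> pd.DataFrame:
    rows = [asdict(e) | {"pulse_duration": e.pulse_duration} for e in events]
    cols = list(SoundEvent.__dataclass_fields__) + ["pulse_duration"]
    return pd.DataFrame(rows, columns=cols)


def bandpass(wave: np.ndarray, fs: float, band=(10_000.0, 200_000.0),
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass over the telemetry band."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, wave)


def spectrogram(wave: np.ndarray, fs: float, window_len: int = 1024,
                overlap: float = 0.875):
    """Magnitude spectrogram (Hann window, ``scaling='spectrum'``).

    Returns ``(freqs, times, magnitude)``; a window longer than the signal
    is an error.
    """
    if window_len > len(wave):
        raise ValueError("window longer than signal")
    noverlap = int(round(window_len * overlap))
    f, t, S = scipy.signal.spectrogram(
        wave, fs=fs, window="hann", nperseg=window_len, noverlap=noverlap,
        mode="magnitude", scaling="spectrum")
    return f, t, S


# --------------------------------------------------------------------------
# detection


def _envelope_db(wave: np.ndarray, block: int):
    """Block-maximum amplitude envelope in dB rel. channel max."""
    n = len(wave)
    nb = n // block
    env = np.abs(wave[: nb * block]).reshape(nb, block).max(axis=1)
    peak = env.max()
    if peak <= 0:
        return np.full(nb, -200.0), 0.0
    env_db = 20 * np.log10(np.maximum(env, peak * 1e-10) / peak)
    return env_db, peak


def _rolling_floor(env_db: np.ndarray, blocks_per_chunk: int,
                   chunks_window: int = 21) -> np.ndarray:
    """Rolling noise floor: per-chunk low percentile, median across chunks.

    A low percentile (not the median) keeps the floor pinned to the quiet
    gaps even when pulses, echoes and conspecific copies occupy most of a
    chunk, as happens whenever bats fly close together.
    """
    nb = len(env_db)
    nc = max(1, nb // blocks_per_chunk)
    coarse = np.array([np.percentile(env_db[i * blocks_per_chunk:
                                            (i + 1) * blocks_per_chunk], 1)
                       for i in range(nc)])
    if nc > 2:
        from scipy.ndimage import median_filter
        k = min(chunks_window, nc if nc % 2 else nc - 1)
        coarse = median_filter(coarse, size=max(1, k | 1), mode="nearest")
    centers = (np.arange(nc) + 0.5) * blocks_per_chunk
    return np.interp(np.arange(nb), centers, coarse)


def detect_events(wave: np.ndarray, fs: float,
                  cfg: AnalysisConfig | None = None,
                  channel_bat_id: int = 0,
                  already_filtered: bool = False) -> list[SoundEvent]:
    """Detect supra-threshold events on one channel (kind left unknown).

    Runs above threshold are bridged across gaps shorter than
    ``merge_gap_ms``; inside each run, portions more than ``split_drop_db``
    below the run peak and hanging off its ends are split into their own
    events (this is what separates a trailing wall-echo tail from the
    pulse it overlaps).
    """
    cfg = cfg or AnalysisConfig()
    x = wave if already_filtered else bandpass(wave, fs, cfg.band)
    env_db, peak = _envelope_db(x, cfg.env_block)
    if peak <= 0:
        return []
    block_s = cfg.env_block / fs
    # a channel whose envelope has almost no dynamic range is noise (or a
    # constant tone) — there is nothing to segment above a floor
    if (np.percentile(env_db, 99) - np.percentile(env_db, 1)
            < cfg.noise_margin_db):
        return []
    floor = _rolling_floor(env_db, max(1, int(round(0.05 / block_s))))
    thr = np.maximum(cfg.threshold_db, floor + cfg.noise_margin_db)
    mask = env_db > thr
    min_blocks = max(1, int(round(cfg.min_dur_ms / 1e3 / block_s)))
    gap_blocks = int(round(cfg.merge_gap_ms / 1e3 / block_s))

    # runs of True, then bridge short gaps
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    runs = list(zip(idx[::2], idx[1::2]))
    merged = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] <= gap_blocks:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    events: list[SoundEvent] = []

    def _emit(lo, hi, depth=0):
        if hi - lo < min_blocks or depth > 6:
            return
        seg = env_db[lo:hi]
        pk = seg.max()
        strong = seg > pk - cfg.split_drop_db
        idx2 = np.flatnonzero(np.diff(
            np.concatenate([[0], strong.view(np.int8), [0]])))
        sruns = list(zip(idx2[::2], idx2[1::2]))
        smerged = []
        for a, b in sruns:
            if smerged and a - smerged[-1][1] <= gap_blocks:
                smerged[-1] = (smerged[-1][0], b)
            else:
                smerged.append((a, b))
        cursor = lo
        for a, b in smerged:
            a, b = lo + a, lo + b
            if a - cursor >= min_blocks:
                _emit(cursor, a, depth + 1)   # weaker leftover, own peak
            if b - a >= min_blocks:
                lvl = float(env_db[a:b].max())
                events.append(SoundEvent(
                    channel_bat_id=channel_bat_id,
                    onset=a * block_s, offset=b * block_s,
                    peak_level_db=lvl,
                    peak_amp=float(peak * 10 ** (lvl / 20.0))))
            cursor = b
        if hi - cursor >= min_blocks:
            _emit(cursor, hi, depth + 1)

    for lo, hi in merged:
        _emit(lo, hi)
    events.sort(key=lambda e: e.onset)
    return events


# --------------------------------------------------------------------------
# per-event frequency analysis


def _ridge(x: np.ndarray, fs: float, cfg: AnalysisConfig):
    """Track the dominant frequency ridge of an event segment.

    Returns (times, freqs, levels_db rel segment peak); parabolic
    interpolation refines each frame's peak bin.
    """
    w, hop = cfg.fm_window, cfg.fm_hop
    if len(x) < w:
        return np.array([]), np.array([]), np.array([])
    f, t, S = scipy.signal.spectrogram(
        x, fs=fs, window="hann", nperseg=w, noverlap=w - hop,
        mode="magnitude")
    sel = (f >= cfg.band[0]) & (f <= cfg.band[1])
    f, S = f[sel], S[sel]
    k = np.argmax(S, axis=0)
    amp = S[k, np.arange(S.shape[1])]
    lvl = 20 * np.log10(np.maximum(amp, amp.max() * 1e-10) / amp.max())
    df = f[1] - f[0]
    freq = f[k].astype(float)
    inner = (k > 0) & (k < len(f) - 1)
    ki = k[inner]
    cols = np.flatnonzero(inner)
    a = np.log(np.maximum(S[ki - 1, cols], 1e-30))
    b = np.log(np.maximum(S[ki, cols], 1e-30))
    c = np.log(np.maximum(S[ki + 1, cols], 1e-30))
    denom = a - 2 * b + c
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / denom, 0.0)
    freq[cols] += np.clip(delta, -1, 1) * df
    return t, freq, lvl


def _parabolic_peak(spec: np.ndarray, freqs: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(spec) - 1:
        return float(freqs[i])
    a, b, c = (math.log(max(spec[i - 1], 1e-30)),
               math.log(max(spec[i], 1e-30)),
               math.log(max(spec[i + 1], 1e-30)))
    denom = a - 2 * b + c
    if abs(denom) < 1e-12:
        return float(freqs[i])
    delta = max(-1.0, min(1.0, 0.5 * (a - c) / denom))
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def _cf_spectrum(wave, fs, t0, t1, cfg):
    """Hann-windowed ``n_fft``-point spectrum of waveform span [t0, t1)."""
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    seg = np.asarray(wave[max(0, i0):i1], dtype=float)
    padded = len(seg) < cfg.n_fft
    if not padded:
        mid = len(seg) // 2
        seg = seg[mid - cfg.n_fft // 2: mid + cfg.n_fft // 2]
    spec = np.abs(np.fft.rfft(seg * np.hanning(len(seg)), cfg.n_fft))
    freqs = np.fft.rfftfreq(cfg.n_fft, 1.0 / fs)
    return freqs, spec, padded


def estimate_cf2(event: SoundEvent, wave: np.ndarray, fs: float,
                 cfg: AnalysisConfig | None = None) -> SoundEvent:
    """Estimate the event's CF2 from its CF plateau.

    The plateau is the longest ridge run whose instantaneous-frequency
    slope stays below ``cf_slope_hz_per_ms``; CF2 is the peak of a
    ``n_fft``-point transform over that span (bin width fs / n_fft),
    with a parabolic refinement stored in ``cf2``.  Events with no
    plateau are flagged and left without CF2.
    """
    cfg = cfg or AnalysisConfig()
    event.cf2_bin_width = fs / cfg.n_fft
    i0, i1 = int(event.onset * fs), int(event.offset * fs)
    t, freq, lvl = _ridge(wave[i0:i1], fs, cfg)
    if len(t) < 3:
        event.flag("no_cf_plateau")
        return event
    slope = np.abs(np.gradient(freq, t)) / 1e3       # Hz per ms
    ok = (slope < cfg.cf_slope_hz_per_ms) & (lvl > cfg.ridge_floor_db)
    best = _longest_run(ok)
    if best is None:
        event.flag("no_cf_plateau")
        return event
    a, b = best
    t0, t1 = event.onset + t[a], event.onset + t[b - 1]
    # trim the plateau ends away from the FM sweeps
    t0, t1 = t0 + 2.5e-4, t1 - 2.5e-4
    if t1 - t0 < 1e-3:
        event.flag("no_cf_plateau")
        return event
    freqs, spec, padded = _cf_spectrum(wave, fs, t0, t1, cfg)
    sel = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    base = np.flatnonzero(sel)[0]
    i = base + int(np.argmax(spec[sel]))
    event.cf2_raw = float(freqs[i])
    event.cf2 = _parabolic_peak(spec, freqs, i)
    event.cf_start, event.cf_end = t0, t1
    if padded:
        event.flag("cf_zero_padded")
    return event


def _longest_run(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    runs = list(zip(idx[::2], idx[1::2]))
    if not runs:
        return None
    return max(runs, key=lambda r: r[1] - r[0])


def measure_components(event: SoundEvent, wave: np.ndarray, fs: float,
                       cfg: AnalysisConfig | None = None) -> SoundEvent:
    """Measure tFM bandwidth/duration and iFM presence from the ridge.

    The terminal sweep is the post-plateau ridge more than ``tfm_drop_hz``
    below CF2; a straight line fitted to it is extrapolated to the event
    offset, so the measured bandwidth does not lose the last
    half-analysis-window of the sweep.  Requires :func:`estimate_cf2`
    first.
    """
    cfg = cfg or AnalysisConfig()
    if math.isnan(event.cf2):
        event.flag("components_skipped")
        return event
    i0, i1 = int(event.onset * fs), int(event.offset * fs)
    t, freq, lvl = _ridge(wave[i0:i1], fs, cfg)
    if len(t) < 3:
        event.flag("ridge_untrackable")
        return event
    tt = event.onset + t
    valid = lvl > cfg.ridge_floor_db
    post = (tt > event.cf_end) & valid & (freq < event.cf2 - cfg.tfm_drop_hz)
    if post.sum() >= 2:
        coef = np.polyfit(tt[post], freq[post], 1)
        if coef[0] < 0:
            t_on = (event.cf2 - coef[1]) / coef[0]
            t_on = float(np.clip(t_on, event.cf_end - 1e-3, event.offset))
            f_end = float(np.polyval(coef, event.offset))
            event.tfm_onset = t_on
            event.tfm_bandwidth = max(0.0, event.cf2 - f_end)
            event.tfm_duration = (event.offset - t_on) * 1e3
        else:
            event.tfm_duration = 0.0
            event.flag("no_tfm")
    else:
        event.tfm_duration = 0.0
        event.flag("no_tfm")
    pre = (tt < event.cf_start) & valid & (freq < event.cf2 - cfg.ifm_drop_hz)
    if pre.sum() >= 2:
        slope = np.polyfit(tt[pre], freq[pre], 1)[0]
        event.ifm_detected = bool(slope > 0)
    return event


# --------------------------------------------------------------------------
# cross-channel classification


def classify_events(events: list[SoundEvent],
                    cfg: AnalysisConfig | None = None,
                    n_channels: int | None = None) -> list[SoundEvent]:
    """Assign focal_pulse / other_pulse / own_echo / unknown labels.

    Channels must be time-synchronized.  An event is a focal pulse where
    its absolute level tops every overlapping event on the other channels;
    a weaker event trailing another channel's focal pulse within the
    propagation-delay window is that bat's pulse heard remotely; a weaker
    event on the same channel inside the echo window and within
    ``echo_cf2_tol_hz`` of the focal CF2 is an own echo.
    """
    cfg = cfg or AnalysisConfig()
    if n_channels is None:
        n_channels = max((e.channel_bat_id for e in events), default=-1) + 1
    if n_channels < 1:
        return events
    by_ch = [sorted([e for e in events if e.channel_bat_id == c],
                    key=lambda e: e.onset) for c in range(n_channels)]
    if any(len(ch) == 0 for ch in by_ch) and len(events) > 0 and n_channels > 1:
        pass  # empty channels are fine; missing sync offsets are caught upstream

    tol = 1e-3
    # an event is focal where its level tops every cross-channel overlap;
    # the margin keeps simultaneous pulses of *different* bats (whose
    # summed-overlap peaks differ by a few dB) from suppressing each other,
    # while a remote copy of the same pulse (~20 dB down after spreading)
    # is still rejected
    margin = 10 ** (-cfg.focal_margin_db / 20.0)
    for e in events:
        rivals = [o for o in events
                  if o.channel_bat_id != e.channel_bat_id
                  and o.onset < e.offset + tol and o.offset > e.onset - tol]
        if all(e.peak_amp >= o.peak_amp * margin for o in rivals):
            e.kind = "focal_pulse"

    focals = [e for e in events if e.kind == "focal_pulse"]
    demote = 10 ** (-cfg.echo_demote_db / 20.0)
    for e in events:
        if e.kind != "unknown":
            continue
        # immediate tail: a weak event starting right at a focal pulse's
        # offset on its own channel is the un-overlapped remainder of that
        # pulse's wall echo — but only when no conspecific pulse can be
        # arriving there, because a suppressed copy's remainder starts at
        # exactly the same place
        for f in focals:
            if (f.channel_bat_id == e.channel_bat_id
                    and -1e-3 <= e.onset - f.offset <= 2e-3
                    and e.peak_amp < f.peak_amp * demote
                    and (math.isnan(e.cf2) or math.isnan(f.cf2)
                         or abs(e.cf2 - f.cf2) <= cfg.echo_cf2_tol_hz)
                    and not _contaminated(e.onset, e.offset,
                                          e.channel_bat_id, events, cfg)):
                e.kind = "own_echo"
                break
    for e in events:
        if e.kind != "unknown":
            continue
        # another bat's pulse (or a detected fragment of one): starts while
        # a remote focal pulse could still be arriving here, i.e. within
        # the source event plus the propagation-delay horizon
        for f in focals:
            if (f.channel_bat_id != e.channel_bat_id
                    and 0.0 <= e.onset - f.onset
                    <= (f.offset - f.onset) + cfg.other_window_ms / 1e3
                    and e.peak_amp < f.peak_amp):
                e.kind = "other_pulse"
                break

    # a markedly weaker event trailing a focal pulse on its own channel is
    # that pulse's wall echo, not a new focal pulse — demote it
    lo, hi = cfg.echo_window_ms
    demote = 10 ** (-cfg.echo_demote_db / 20.0)
    by_onset = sorted(events, key=lambda e: e.onset)
    for e in by_onset:
        if e.kind != "focal_pulse":
            continue
        for f in by_onset:
            if (f.kind == "focal_pulse" and f is not e
                    and f.channel_bat_id == e.channel_bat_id
                    and lo / 1e3 <= e.onset - f.onset <= hi / 1e3
                    and e.peak_amp < f.peak_amp * demote):
                cf_ok = (math.isnan(e.cf2) or math.isnan(f.cf2)
                         or abs(e.cf2 - f.cf2) <= cfg.echo_cf2_tol_hz)
                if cf_ok:
                    e.kind = "own_echo"
                    break
    focals = [e for e in events if e.kind == "focal_pulse"]
    for e in events:
        if e.kind != "unknown":
            continue
        for f in focals:
            if f.channel_bat_id != e.channel_bat_id or f.onset >= e.onset:
                continue
            dt = e.onset - f.onset
            if not (lo / 1e3 <= dt <= hi / 1e3) or e.peak_amp >= f.peak_amp:
                continue
            cf_ok = (math.isnan(e.cf2) or math.isnan(f.cf2)
                     or abs(e.cf2 - f.cf2) <= cfg.echo_cf2_tol_hz)
            if cf_ok and not _contaminated(e.onset, e.offset,
                                           e.channel_bat_id, events, cfg):
                e.kind = "own_echo"
                break
    return events


def _contaminated(t0: float, t1: float, channel: int,
                  events: list[SoundEvent], cfg: AnalysisConfig,
                  loud_db: float = -10.0) -> bool:
    """Could another bat's pulse land inside [t0, t1] on this channel?

    Any loud event on another channel (a pulse at emission level, whatever
    its assigned kind) reaches this channel within the propagation-delay
    horizon and lasts its own duration; if that span intersects the
    window, the window may contain conspecific energy.
    """
    horizon = cfg.other_window_ms / 1e3
    return any(
        f.channel_bat_id != channel and f.peak_level_db > loud_db
        and f.onset < t1 and f.offset + horizon > t0
        for f in events)


def extract_overlapping_echoes(events: list[SoundEvent],
                               waves: np.ndarray, fs: float,
                               cfg: AnalysisConfig | None = None
                               ) -> list[SoundEvent]:
    """Recover wall echoes that overlap the emitting pulse.

    At room-scale wall distances the two-way delay (4–12 ms) is far
    shorter than the pulse (20–27 ms), so the echo rides on top of the
    pulse and never triggers the envelope detector on its own.  It is,
    however, Doppler-separated from the emitted CF2, so it shows up as a
    secondary spectral peak inside the pulse's CF window.  Pulses whose CF
    window may contain another bat's pulse (a remote focal pulse onset
    within the propagation-delay horizon) are skipped to avoid mistaking
    conspecific energy for an echo.

    Returns new ``own_echo`` events (flagged ``overlapped``); the input
    list is not modified.
    """
    cfg = cfg or AnalysisConfig()
    focals = sorted([e for e in events if e.kind == "focal_pulse"],
                    key=lambda e: e.onset)
    out: list[SoundEvent] = []
    for e in focals:
        if math.isnan(e.cf2) or math.isnan(e.cf_start):
            continue
        if _contaminated(e.cf_start, e.cf_end, e.channel_bat_id, events, cfg):
            continue
        freqs, spec, _ = _cf_spectrum(
            waves[e.channel_bat_id], fs, e.cf_start, e.cf_end, cfg)
        # the notch must swallow the analysis window's mainlobe skirt and
        # first sidelobes (4.5 window bins), else zero-padding exposes the
        # skirt as a fake secondary peak whenever the true echo is absent
        win_res = fs / max(1.0, (e.cf_end - e.cf_start) * fs)
        notch = max(cfg.echo_notch_hz, 4.5 * win_res)
        sel = np.flatnonzero(
            (freqs >= e.cf2 - cfg.echo_cf2_tol_hz)
            & (freqs <= e.cf2 + cfg.echo_cf2_tol_hz)
            & (np.abs(freqs - e.cf2) > notch))
        if len(sel) == 0:
            continue
        main_amp = spec[np.argmin(np.abs(freqs - e.cf2))]
        i = sel[np.argmax(spec[sel])]
        amp = spec[i]
        if (amp < main_amp * 10 ** (cfg.echo_rel_floor_db / 20.0)
                or amp >= main_amp):
            continue
        if not (spec[i - 1] <= amp >= spec[i + 1]):
            continue
        # a real echo is a tone standing clear of the leakage floor; when
        # the echo hides inside the carrier notch, the residual band peak
        # is broad and shallow — reject it
        floor = np.median(spec[sel])
        if amp < floor * 10 ** (cfg.echo_prominence_db / 20.0):
            continue
        level_db = e.peak_level_db + 20 * math.log10(amp / main_amp)
        if level_db < cfg.echo_min_level_db:
            continue
        echo = SoundEvent(
            channel_bat_id=e.channel_bat_id, onset=e.onset, offset=e.offset,
            kind="own_echo", peak_level_db=level_db,
            peak_amp=e.peak_amp * amp / main_amp,
            cf2=_parabolic_peak(spec, freqs, i), cf2_raw=float(freqs[i]),
            cf2_bin_width=fs / cfg.n_fft)
        echo.flag("overlapped")
        out.append(echo)
    return out


# --------------------------------------------------------------------------
# temporal patterning


@dataclass
class SonarSoundGroup:
    """Pulses emitted in a burst of short interpulse intervals."""

    events: list = field(default_factory=list)

    @property
    def onset(self) -> float:
        return self.events[0].onset

    @property
    def offset(self) -> float:
        return max(e.offset for e in self.events)


def group_and_silent_times(focal_events: list[SoundEvent],
                           gap_threshold_ms: float = 30.0
                           ) -> tuple[list[SonarSoundGroup], np.ndarray]:
    """Cluster focal pulses into sonar sound groups and report silent times.

    Pulses separated by an offset-to-onset gap below the threshold share a
    group; the silent time is the gap from one group's last offset to the
    next group's first onset.  Fewer than two groups yield an empty
    silent-time array.
    """
    ev = sorted(focal_events, key=lambda e: e.onset)
    groups: list[SonarSoundGroup] = []
    for e in ev:
        if groups and (e.onset - groups[-1].offset) * 1e3 < gap_threshold_ms:
            groups[-1].events.append(e)
        else:
            groups.append(SonarSoundGroup(events=[e]))
    silent = np.array([groups[i + 1].onset - groups[i].offset
                       for i in range(len(groups) - 1)]) * 1e3
    return groups, silent


# --------------------------------------------------------------------------
# channel-level driver


def analyze_channels(waves: np.ndarray, fs: float,
                     cfg: AnalysisConfig | None = None):
    """Run the full per-channel analysis over synchronized channels.

    Returns ``(events, groups_by_channel, silent_by_channel)`` where
    ``events`` includes detected events with kinds assigned plus extracted
    overlapping echoes.
    """
    cfg = cfg or AnalysisConfig()
    waves = np.atleast_2d(waves)
    events: list[SoundEvent] = []
    filtered = np.vstack([bandpass(w, fs, cfg.band) for w in waves])
    for ch in range(len(waves)):
        events.extend(detect_events(filtered[ch], fs, cfg,
                                    channel_bat_id=ch, already_filtered=True))
    for e in events:
        estimate_cf2(e, filtered[e.channel_bat_id], fs, cfg)
        measure_components(e, filtered[e.channel_bat_id], fs, cfg)
    classify_events(events, cfg, n_channels=len(waves))
    # separately detected echoes (trailing tails) can carry conspecific
    # energy in their CF window; flag those so set-point estimates can
    # exclude them
    for e in events:
        if e.kind == "own_echo" and _contaminated(
                e.onset, e.offset, e.channel_bat_id, events, cfg):
            e.flag("contaminated")
    events.extend(extract_overlapping_echoes(events, filtered, fs, cfg))
    groups, silent = {}, {}
    for ch in range(len(waves)):
        focal = [e for e in events
                 if e.channel_bat_id == ch and e.kind == "focal_pulse"]
        groups[ch], silent[ch] = group_and_silent_times(focal, cfg.group_gap_ms)
    return events, groups, silent
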