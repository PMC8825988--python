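"""Reference frequencies, ΔRF and normalized frequency distributions.

The *reference frequency* (RF) of a Doppler-shift-compensating bat is the
frequency its echo CF2 is held at; operationally it is estimated per
flight as the mean CF2 of the bat's own wall echoes.  Its standard
deviation measures how tightly the compensation loop is closed.

ΔRF is the difference in mean reference frequency between the two group
members closest in RF — the quantity that would shrink under a
frequency-shifting jamming avoidance response and stay put without one.

For the jamming picture, each bat's acoustic input is normalized by its
own RF: own-echo frequencies minus RF cluster tightly near zero, while
the (estimated) CF2s of other bats' pulses, spread by emitter identity,
their compensation state and the pairwise Doppler shifts, form a much
broader distribution — the synthetic counterpart of the published
own-echo vs conspecific-pulse histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sound import SoundEvent

__all__ = ["ReferenceFrequency", "reference_frequency", "delta_rf",
           "normalize_and_histogram", "echo_cf2_values", "flight_summary"]


@dataclass
class ReferenceFrequency:
    """Per-bat, per-flight reference-frequency estimate."""

    bat_id: int
    mean_cf2: float
    sd_cf2: float
    n_echoes: int
    flagged: bool = False   # True when no usable echo was available


def echo_cf2_values(events: list[SoundEvent], channel_bat_id: int,
                    include_contaminated: bool = False) -> np.ndarray:
    """CF2 values of a channel's own echoes usable for RF estimation."""
    vals = [e.cf2 for e in events
            if e.channel_bat_id == channel_bat_id and e.kind == "own_echo"
            and math.isfinite(e.cf2)
            and (include_contaminated or "contaminated" not in e.flags)]
    return np.asarray(vals, dtype=float)


def reference_frequency(echo_cf2: np.ndarray | list,
                        bat_id: int = 0) -> ReferenceFrequency:
    """Mean and sample s.d. of a flight's own-echo CF2 values.

    With no echoes the record is flagged and carries NaN estimates; a
    single echo gives s.d. 0.
    """
    x = np.asarray(echo_cf2, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return ReferenceFrequency(bat_id, math.nan, math.nan, 0, flagged=True)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ReferenceFrequency(bat_id, float(np.mean(x)), sd, int(len(x)))


def delta_rf(rfs: dict[int, float]) -> pd.DataFrame:
    """Nearest-neighbour RF differences within a flight group.

    Returns one row per bat with its signed and absolute difference from
    the group member nearest in RF, plus ``closest_pair`` marking the two
    bats forming the group's minimum |ΔRF| pair.  Ties in nearest
    neighbour break toward the lower bat id.  With two bats, ΔRF is simply
    their difference.
    """
    ids = sorted(rfs)
    if len(ids) < 2:
        raise ValueError("delta_rf needs at least two reference frequencies")
    rows = []
    for b in ids:
        others = [o for o in ids if o != b]
        # stable sort on (|diff|, id) breaks ties toward lower bat id
        nb = min(others, key=lambda o: (abs(rfs[o] - rfs[b]), o))
        rows.append({"bat_id": b, "neighbour": nb,
                     "delta_rf": rfs[nb] - rfs[b],
                     "abs_delta_rf": abs(rfs[nb] - rfs[b])})
    df = pd.DataFrame(rows)
    pair_i = df["abs_delta_rf"].idxmin()
    a, b = df.loc[pair_i, "bat_id"], df.loc[pair_i, "neighbour"]
    df["closest_pair"] = df["bat_id"].isin([a, b]) & df["neighbour"].isin([a, b])
    return df


def flight_summary(events: list[SoundEvent], silent_times_ms,
                   channel_bat_id: int, flight_id, condition: str,
                   space: str) -> dict:
    """Per-flight feature means for one bat, ready for the feature table.

    Units: tFM bandwidth in kHz, durations and silent time in ms, RF s.d.
    in Hz.  Missing features (no echoes, no silent times) stay NaN.
    """
    focal = [e for e in events
             if e.channel_bat_id == channel_bat_id
             and e.kind == "focal_pulse"]
    bw = [e.tfm_bandwidth for e in focal if math.isfinite(e.tfm_bandwidth)]
    td = [e.tfm_duration for e in focal
          if math.isfinite(e.tfm_duration) and e.tfm_duration > 0]
    rf = reference_frequency(echo_cf2_values(events, channel_bat_id),
                             channel_bat_id)
    silent = np.asarray(silent_times_ms, dtype=float)
    return {
        "bat_id": channel_bat_id, "flight_id": flight_id,
        "condition": condition, "space": space,
        "tfm_bandwidth": float(np.mean(bw)) / 1e3 if bw else math.nan,
        "tfm_duration": float(np.mean(td)) if td else math.nan,
        "pulse_duration": float(np.mean([e.pulse_duration for e in focal]))
        if focal else math.nan,
        "silent_time": float(np.mean(silent)) if len(silent) else math.nan,
        "rf_sd": rf.sd_cf2 if not rf.flagged else math.nan,
        "rf_mean": rf.mean_cf2 if not rf.flagged else math.nan,
        "n_pulses": len(focal), "n_echoes": rf.n_echoes,
    }


def normalize_and_histogram(own_echo_cf2: np.ndarray | list,
                            received_cf2: np.ndarray | list,
                            listener_rf: float,
                            echo_bin_hz: float = 50.0,
                            est_bin_hz: float = 200.0,
                            span_hz: float = 4000.0):
    """Normalize frequencies by the listener's RF and histogram them.

    Returns ``(samples, hists)``: ``samples`` is a tidy frame with columns
    ``source`` ({own_echo, other_pulse_estimate}) and ``value`` (Hz,
    frequency minus listener RF); ``hists`` maps source to
    ``(bin_edges, counts)`` with the stated bin width over ±``span_hz``.
    Spread statistics (sd, IQR) per source are attached as
    ``samples.attrs["spread"]``.  Empty inputs yield zero-count
    histograms.
    """
    frames = []
    for name, vals in (("own_echo", own_echo_cf2),
                       ("other_pulse_estimate", received_cf2)):
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)] - listener_rf
        frames.append(pd.DataFrame({"source": name, "value": v}))
    samples = pd.concat(frames, ignore_index=True)
    hists = {}
    spread = {}
    for name, bw in (("own_echo", echo_bin_hz),
                     ("other_pulse_estimate", est_bin_hz)):
        v = samples.loc[samples["source"] == name, "value"].to_numpy()
        edges = np.arange(-span_hz, span_hz + bw, bw)
        counts, edges = np.histogram(v, bins=edges)
        hists[name] = (edges, counts)
        spread[name] = {
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "iqr": float(np.subtract(*np.percentile(v, [75, 25])))
            if len(v) else 0.0,
            "n": int(len(v)),
        }
    samples.attrs["spread"] = spread
    return samples, hists
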