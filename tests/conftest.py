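"""Shared fixtures: simulated scenes are expensive, so the group-flight
scene and its full audio analysis are built once per session."""

import numpy as np
import pandas as pd
import pytest

from sonarjam import (make_scene, simulate_trajectories,
                      simulate_vocalizations, render_telemetry_waveforms,
                      analyze_channels, events_to_frame)


@pytest.fixture(scope="session")
def group_scene():
    """Narrow-space scene, 3 bats, 20 s: the study's group-flight setting."""
    sc = make_scene("narrow", n_bats=3, duration=20.0, seed=7)
    trs = simulate_trajectories(sc)
    em = simulate_vocalizations(sc, trs)
    waves, gt = render_telemetry_waveforms(sc, trs, em)
    return sc, trs, em, waves, gt


@pytest.fixture(scope="session")
def group_analysis(group_scene):
    sc, trs, em, waves, gt = group_scene
    events, groups, silent = analyze_channels(waves, sc.sample_rate)
    return events, groups, silent


@pytest.fixture(scope="session")
def single_scene():
    """Single bat flying alone in the narrow space, 5 s."""
    sc = make_scene("narrow", n_bats=1, duration=5.0, seed=2)
    trs = simulate_trajectories(sc)
    em = simulate_vocalizations(sc, trs)
    waves, gt = render_telemetry_waveforms(sc, trs, em)
    return sc, trs, em, waves, gt


@pytest.fixture(scope="session")
def single_analysis(single_scene):
    sc, trs, em, waves, gt = single_scene
    events, groups, silent = analyze_channels(waves, sc.sample_rate)
    return events, groups, silent


def match_focal_to_emissions(events, emissions, mic_delay_s=0.1 / 343.5):
    """Pair detected focal pulses with emitted pulses by onset time."""
    foc = (events_to_frame([e for e in events if e.kind == "focal_pulse"])
           .sort_values("onset").reset_index(drop=True))
    rows = []
    for ch, g in foc.groupby("channel_bat_id"):
        em = (emissions[emissions.bat_id == ch]
              .sort_values("t_emit").reset_index(drop=True))
        m = pd.merge_asof(g.sort_values("onset"),
                          em.assign(t_on=em.t_emit + mic_delay_s),
                          left_on="onset", right_on="t_on",
                          direction="nearest")
        rows.append(m[np.abs(m.onset - m.t_on) < 2e-3])
    return pd.concat(rows, ignore_index=True)
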