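"""On-disk layout of a simulated (or recorded) session.

A scene directory holds one WAV file per telemetry channel, a trajectory
TSV, the ground-truth emission/arrival TSVs (for synthetic scenes) and a
flat ``key = value`` scene config.  Everything is plain text except the
WAVs, which are 32-bit float PCM with the sample rate in the header.
"""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .scene import SimulationScene, VocalProfile
from .synthesis import GroundTruth, EMISSION_COLUMNS, ARRIVAL_COLUMNS
from .trajectories import Trajectory, trajectories_to_frame, frame_to_trajectories

__all__ = ["write_scene", "read_scene", "write_wav", "read_wav",
           "read_trajectories_tsv"]

_FLOAT_FMT = "%.17g"   # lossless for float64

_SCENE_SCALARS = ["n_bats", "duration", "frame_rate", "sample_rate",
                  "sound_speed", "seed", "wall_margin", "min_turn_radius",
                  "wall_loss_db", "conspecific_gain", "noise_rms"]
_PROFILE_FIELDS = ["reference_frequency", "pulse_duration", "tfm_duration",
                   "tfm_bandwidth", "ifm_bandwidth", "ifm_duration",
                   "ifm_present", "pulses_per_group", "inter_group_interval",
                   "intra_group_interval", "source_level_rolloff",
                   "compensation_gain"]


def write_wav(path, wave: np.ndarray, sample_rate: float) -> None:
    wavfile.write(path, int(round(sample_rate)), np.asarray(wave, np.float32))


def read_wav(path) -> tuple[float, np.ndarray]:
    fs, data = wavfile.read(path)
    return float(fs), np.asarray(data)


def write_scene(outdir, scene: SimulationScene,
                trajectories: list[Trajectory] | None = None,
                waves: np.ndarray | None = None,
                ground_truth: GroundTruth | None = None) -> Path:
    """Write a scene directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "scene.cfg", "w") as fh:
        for k in _SCENE_SCALARS:
            fh.write(f"{k} = {getattr(scene, k)!r}\n")
        fh.write(f"chamber_dims = {tuple(scene.chamber_dims)!r}\n")
        fh.write(f"speed_band = {tuple(scene.speed_band)!r}\n")
        fh.write(f"harmonic_levels_db = {tuple(scene.harmonic_levels_db)!r}\n")
        for b, p in enumerate(scene.profiles):
            for f in _PROFILE_FIELDS:
                fh.write(f"profile{b}.{f} = {getattr(p, f)!r}\n")
    if trajectories is not None:
        trajectories_to_frame(trajectories).to_csv(
            outdir / "trajectories.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
    if waves is not None:
        for b in range(len(waves)):
            write_wav(outdir / f"bat{b}.wav", waves[b], scene.sample_rate)
    if ground_truth is not None:
        ground_truth.emissions.to_csv(
            outdir / "ground_truth_emissions.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        ground_truth.arrivals.to_csv(
            outdir / "ground_truth_arrivals.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
    return outdir


def _parse_cfg(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = ast.literal_eval(val.strip())
    return out


def read_scene(outdir):
    """Read back a scene directory.

    Returns ``(scene, trajectories, waves, ground_truth)``; missing pieces
    come back as ``None``.  A WAV whose header sample rate disagrees with
    the scene config is a hard error.
    """
    outdir = Path(outdir)
    cfg = _parse_cfg(outdir / "scene.cfg")
    n_bats = int(cfg["n_bats"])
    profiles = []
    for b in range(n_bats):
        kwargs = {f: cfg[f"profile{b}.{f}"] for f in _PROFILE_FIELDS}
        profiles.append(VocalProfile(**kwargs))
    scene = SimulationScene(
        chamber_dims=tuple(cfg["chamber_dims"]),
        speed_band=tuple(cfg["speed_band"]),
        harmonic_levels_db=tuple(cfg["harmonic_levels_db"]),
        profiles=tuple(profiles),
        **{k: cfg[k] for k in _SCENE_SCALARS if k != "n_bats"},
        n_bats=n_bats)

    trajectories = waves = gt = None
    tpath = outdir / "trajectories.tsv"
    if tpath.exists():
        trajectories = frame_to_trajectories(pd.read_csv(tpath, sep="\t"))
    wav_paths = sorted(outdir.glob("bat*.wav"))
    if wav_paths:
        chans = []
        for p in wav_paths:
            fs, data = read_wav(p)
            if abs(fs - scene.sample_rate) > 0.5:
                raise ValueError(
                    f"{p.name}: header sample rate {fs} != scene "
                    f"sample_rate {scene.sample_rate}")
            chans.append(data)
        waves = np.vstack(chans)
    epath = outdir / "ground_truth_emissions.tsv"
    if epath.exists():
        gt = GroundTruth(
            emissions=pd.read_csv(epath, sep="\t")[EMISSION_COLUMNS],
            arrivals=pd.read_csv(outdir / "ground_truth_arrivals.tsv",
                                 sep="\t")[ARRIVAL_COLUMNS])
    return scene, trajectories, waves, gt


def read_trajectories_tsv(path) -> list[Trajectory]:
    return frame_to_trajectories(pd.read_csv(path, sep="\t"))
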