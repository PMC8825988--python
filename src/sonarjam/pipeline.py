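"""End-to-end orchestration: simulate -> analyze -> doppler -> metrics -> stats.

A single YAML config drives a deterministic run.  One *flight set*
comprises, for a group of bats, an optional pair of single flights around
a group flight (the single1 / group / single2 protocol); each flight is a
scene simulated, rendered and analysed in isolation, so every stage can
be re-run from its on-disk artifacts.  All intermediate products are
plain text (TSV + flat config) except the per-channel WAVs.

The manifest lists every artifact with a SHA-256 checksum; re-running the
same config reproduces the checksums bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .scene import make_scene
from .trajectories import simulate_trajectories
from .synthesis import simulate_vocalizations, render_telemetry_waveforms
from .io import write_scene, read_scene
from .sound import AnalysisConfig, analyze_channels, events_to_frame
from .doppler import fit_polynomials, estimate_received_series
from .metrics import (reference_frequency, echo_cf2_values, delta_rf,
                      normalize_and_histogram, flight_summary)
from .stats import build_feature_table, compare_conditions

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"

DEFAULT_CONFIG = {
    "outdir": "sonarjam_run",
    "seed": 7,
    "scene": {"preset": "narrow", "n_bats": 3, "duration": 20.0},
    "conditions": ["single1", "group", "single2"],
    "single_duration": 10.0,
    "analysis": {},
    "doppler": {"mode": "as_printed", "velocity_method": "angles",
                "subframe": False},
    "metrics": {"echo_bin_hz": 50.0, "est_bin_hz": 200.0,
                "exclude_wide": True},
    "stats": {"responses": ["tfm_bandwidth", "tfm_duration",
                            "pulse_duration", "silent_time"]},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(
            base.get(k), dict) and isinstance(v, dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config) -> Path:
    """Run every stage under ``config`` (path, dict or None for defaults).

    Returns the path to the manifest TSV.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    space = cfg["scene"].get("preset", "narrow")
    n_bats = int(cfg["scene"].get("n_bats", 3))
    seed = int(cfg["seed"])
    acfg = AnalysisConfig(**cfg["analysis"])

    # ---- stage: simulate -------------------------------------------------
    flights = []   # (flight_id, condition, scene_dir, bat_ids)
    try:
        fid = 0
        for cond in cfg["conditions"]:
            if cond == "group":
                plans = [(list(range(n_bats)), n_bats,
                          float(cfg["scene"]["duration"]))]
            else:
                plans = [([b], 1, float(cfg["single_duration"]))
                         for b in range(n_bats)]
            for bat_ids, nb, dur in plans:
                sc = make_scene(space, n_bats=nb, duration=dur,
                                seed=seed + 101 * fid)
                trs = simulate_trajectories(sc)
                em = simulate_vocalizations(sc, trs)
                waves, gt = render_telemetry_waveforms(sc, trs, em)
                d = write_scene(outdir / f"flight{fid:02d}_{cond}",
                                sc, trs, waves, gt)
                flights.append((fid, cond, d, bat_ids))
                fid += 1
    except Exception as e:          # noqa: BLE001 - stage isolation
        raise PipelineError("simulate", e) from e

    # ---- stage: analyze-audio -------------------------------------------
    summaries, all_events = [], {}
    try:
        for fid, cond, d, bat_ids in flights:
            sc, trs, waves, gt = read_scene(d)
            events, groups, silent = analyze_channels(
                waves, sc.sample_rate, acfg)
            events_to_frame(events).to_csv(
                d / "events.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
            all_events[fid] = (sc, trs, events, silent)
            for ch, bat in enumerate(bat_ids):
                row = flight_summary(events, silent.get(ch, []), ch,
                                     fid, cond, space)
                row["bat_id"] = bat   # channel index -> group-level bat id
                summaries.append(row)
    except Exception as e:
        raise PipelineError("analyze-audio", e) from e
    summary = pd.DataFrame(summaries)
    summary.to_csv(outdir / "feature_summary.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)

    # ---- stage: doppler (group flights only) ----------------------------
    received = []
    try:
        for fid, cond, d, bat_ids in flights:
            if cond != "group":
                continue
            sc, trs, events, silent = all_events[fid]
            sm = {tr.bat_id: fit_polynomials(tr) for tr in trs}
            pulses = pd.DataFrame(
                [{"bat_id": e.channel_bat_id, "t": e.onset, "cf2": e.cf2}
                 for e in events if e.kind == "focal_pulse"])
            est = estimate_received_series(
                pulses, sm, sc.sound_speed, **cfg["doppler"])
            est.insert(0, "flight_id", fid)
            received.append(est)
    except Exception as e:
        raise PipelineError("doppler", e) from e
    received = (pd.concat(received, ignore_index=True) if received
                else pd.DataFrame())
    received.to_csv(outdir / "received.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)

    # ---- stage: metrics --------------------------------------------------
    try:
        mrows, nrows, hrows = [], [], []
        for fid, cond, d, bat_ids in flights:
            if cond != "group":
                continue
            sc, trs, events, silent = all_events[fid]
            rfs = {}
            for ch in range(sc.n_bats):
                rf = reference_frequency(echo_cf2_values(events, ch), ch)
                rfs[ch] = rf
                mrows.append({"flight_id": fid, "bat_id": ch,
                              "rf_mean": rf.mean_cf2, "rf_sd": rf.sd_cf2,
                              "n_echoes": rf.n_echoes})
            ok = {b: r.mean_cf2 for b, r in rfs.items() if not r.flagged}
            if len(ok) >= 2:
                drf = delta_rf(ok)
                drf.insert(0, "flight_id", fid)
                nrows.append(drf)
            for ch, rf in rfs.items():
                if rf.flagged or received.empty:
                    continue
                mine = received[(received.flight_id == fid)
                                & (received.listener == ch)]
                samples, hists = normalize_and_histogram(
                    echo_cf2_values(events, ch),
                    mine["cf2_received"].to_numpy(), rf.mean_cf2,
                    cfg["metrics"]["echo_bin_hz"],
                    cfg["metrics"]["est_bin_hz"])
                samples.insert(0, "bat_id", ch)
                samples.insert(0, "flight_id", fid)
                hrows.append(samples)
        pd.DataFrame(mrows).to_csv(outdir / "reference_frequency.tsv",
                                   sep="\t", index=False,
                                   float_format=_FLOAT_FMT)
        (pd.concat(nrows, ignore_index=True) if nrows else pd.DataFrame()
         ).to_csv(outdir / "delta_rf.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
        (pd.concat(hrows, ignore_index=True) if hrows else pd.DataFrame()
         ).to_csv(outdir / "normalized_frequencies.tsv", sep="\t",
                  index=False, float_format=_FLOAT_FMT)
    except Exception as e:
        raise PipelineError("metrics", e) from e

    # ---- stage: stats ----------------------------------------------------
    try:
        table = build_feature_table(summary)
        if cfg["metrics"]["exclude_wide"]:
            rf_table = table[table["space"] == "narrow"]
        else:
            rf_table = table
        srows = []
        for resp in cfg["stats"]["responses"]:
            sub = table.dropna(subset=[resp])
            if sub["condition"].nunique() < 2 or len(sub) < 6:
                continue
            res = compare_conditions(sub, resp)
            for r in res.contrasts.itertuples(index=False):
                srows.append({"response": resp, **r._asdict()})
        pd.DataFrame(srows).to_csv(outdir / "stats_contrasts.tsv", sep="\t",
                                   index=False, float_format=_FLOAT_FMT)
        del rf_table  # rf_sd models need >=2 conditions with echoes
    except Exception as e:
        raise PipelineError("stats", e) from e

    # ---- manifest --------------------------------------------------------
    rows = []
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({**cfg, "version": __version__}, fh,
                       sort_keys=True)
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.tsv":
            rows.append({"artifact": p.stem, "path": str(p.relative_to(outdir)),
                         "sha256": _sha256(p)})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    log.info("pipeline complete: %d flights, manifest %s",
             len(flights), manifest)
    return manifest
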