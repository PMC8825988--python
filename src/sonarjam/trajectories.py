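"""Kinematic flight-path generation.

Bats circling a flight chamber are modelled as elliptical loops traversed
with a linearly advancing phase plus slow, band-limited wobbles of phase,
loop radius and height.  Keeping all spectral content of each coordinate
below ~0.6 Hz is deliberate: measured horseshoe-bat trajectories are
routinely smoothed with 10th-order polynomials over 5-s windows, and the
generator must produce paths that such a fit can represent.  Instantaneous
speed therefore covaries with path curvature (bats slow into turns); the
configured speed band constrains each bat's *mean* speed.  A degenerate
band (lo == hi) selects a circular loop, which makes the instantaneous
speed exactly constant.

This is a kinematic stand-in, not a behavioural model — downstream stages
only care about realistic speeds, turn radii and time-varying inter-bat
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import SimulationScene, _subseed

__all__ = ["Trajectory", "simulate_trajectories", "trajectories_to_frame",
           "mean_pairwise_distance"]

_FINE = 4096  # quadrature points for the loop perimeter integral


@dataclass
class Trajectory:
    """Time-stamped 3-D positions of one bat at the video frame rate."""

    bat_id: int
    frame: np.ndarray      # 0-based frame indices, consecutive
    t: np.ndarray          # seconds, frame / frame_rate
    xyz: np.ndarray        # (n_frames, 3) metres

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame)
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if np.any(np.diff(self.frame) != 1):
            raise ValueError("frames must be consecutive")
        if len(self.t) != len(self.xyz):
            raise ValueError("t and xyz length mismatch")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def speeds(self) -> np.ndarray:
        """Frame-to-frame speeds, m/s (length n_frames - 1)."""
        return np.linalg.norm(np.diff(self.xyz, axis=0), axis=1) * self.frame_rate


def simulate_trajectories(scene: SimulationScene) -> list[Trajectory]:
    """Generate one looping trajectory per bat.

    Raises ``ValueError`` if the chamber cannot host a loop with the
    configured minimum turn radius inside the wall margin.
    """
    lx, ly, lz = scene.chamber_dims
    margin = scene.wall_margin
    eps_r = 0.05  # radial wobble amplitude (fraction of loop radius)
    ax_max = (lx / 2 - margin) / (1 + eps_r)
    ay_max = (ly / 2 - margin) / (1 + eps_r)
    if min(ax_max, ay_max) < scene.min_turn_radius:
        raise ValueError(
            f"chamber {scene.chamber_dims} too small for minimum turn "
            f"radius {scene.min_turn_radius} m with wall margin {margin} m")
    # cap loop aspect so speed does not swing more than ~2.5x over a lap
    aspect_cap = 2.5
    ay_max = min(ay_max, aspect_cap * ax_max)
    ax_max = min(ax_max, aspect_cap * ay_max)

    constant_speed = scene.speed_band[1] - scene.speed_band[0] < 1e-12
    rng = np.random.default_rng(_subseed(scene.seed, 0x7247))
    t = np.arange(scene.n_frames) / scene.frame_rate
    out: list[Trajectory] = []
    for b in range(scene.n_bats):
        scale = rng.uniform(0.85, 1.0)
        a_x, a_y = ax_max * scale, ay_max * scale
        if constant_speed:
            a_x = a_y = min(a_x, a_y)   # circle: constant curvature & speed
        sense = rng.choice([-1.0, 1.0])
        phi0 = rng.uniform(0, 2 * np.pi)
        phi_r, phi_z, phi_w = rng.uniform(0, 2 * np.pi, size=3)
        z0 = lz / 2 + rng.uniform(-0.2, 0.2)
        az = min(0.15, z0 - margin, lz - margin - z0)

        # angular rate giving the requested mean speed over one lap
        v_mean = rng.uniform(*scene.speed_band)
        ug = np.linspace(0, 2 * np.pi, _FINE, endpoint=False)
        perim = np.trapezoid(
            np.hypot(a_x * np.sin(ug), a_y * np.cos(ug)),
            dx=2 * np.pi / _FINE) + 0.0
        omega = v_mean * 2 * np.pi / perim

        if constant_speed:
            u_t = sense * (omega * t + phi0)
            r_t = np.ones_like(t)
            z_t = np.full_like(t, z0)
        else:
            # slow wobbles, all below ~0.3 Hz so a 10th-order / 5-s
            # polynomial window can follow every coordinate
            f_w = rng.uniform(0.10, 0.20)
            f_r = rng.uniform(0.08, 0.16)
            f_z = rng.uniform(0.15, 0.30)
            u_t = sense * (omega * t + phi0
                           + 0.25 * np.sin(2 * np.pi * f_w * t + phi_w))
            r_t = 1.0 + eps_r * np.sin(2 * np.pi * f_r * t + phi_r)
            z_t = z0 + az * np.sin(2 * np.pi * f_z * t + phi_z)

        xyz = np.column_stack([
            lx / 2 + a_x * r_t * np.cos(u_t),
            ly / 2 + a_y * r_t * np.sin(u_t),
            z_t,
        ])
        out.append(Trajectory(bat_id=b, frame=np.arange(scene.n_frames),
                              t=t, xyz=xyz))
    return out


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Stack trajectories into a tidy table (bat_id, frame, t_s, x_m, y_m, z_m)."""
    rows = []
    for tr in trajs:
        rows.append(pd.DataFrame({
            "bat_id": tr.bat_id, "frame": tr.frame, "t_s": tr.t,
            "x_m": tr.xyz[:, 0], "y_m": tr.xyz[:, 1], "z_m": tr.xyz[:, 2],
        }))
    return pd.concat(rows, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for bat_id, g in df.groupby("bat_id", sort=True):
        g = g.sort_values("frame")
        out.append(Trajectory(
            bat_id=int(bat_id), frame=g["frame"].to_numpy(),
            t=g["t_s"].to_numpy(),
            xyz=g[["x_m", "y_m", "z_m"]].to_numpy()))
    return out


def mean_pairwise_distance(trajs: list[Trajectory]) -> float:
    """Mean over frames and bat pairs of inter-bat Euclidean distance."""
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories")
    dists = []
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            d = np.linalg.norm(trajs[i].xyz - trajs[j].xyz, axis=1)
            dists.append(d)
    return float(np.mean(dists))
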