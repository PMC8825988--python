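"""Trajectory smoothing and Doppler estimation of received pulse frequencies.

Flight paths sampled at the video frame rate are smoothed with 10th-order
polynomials over consecutive 5-s segments (each coordinate fitted on time
rescaled to [-1, 1] per segment).  From the smoothed paths the pipeline
derives, frame by frame:

* flight directions — azimuth ``theta = atan2(dy, dx)`` in the x-y plane
  and inclination ``phi = atan2(dz, dx)`` in the x-z plane, from finite
  differences between consecutive frames, plus speed ``v``;
* inter-bat bearings ``theta_AB = atan2(yB - yA, xB - xA)`` and
  ``phi_AB = atan2(zB - zA, xB - xA)`` and the separation;
* the relative radial velocity of emitter B with respect to listener A,

      v_BA = vB cos(thetaB - thetaAB) cos(phiB - phiAB)
           - vA cos(thetaA - thetaAB) cos(phiA - phiAB),

  positive when the pair separates along the A->B bearing;
* the CF2 of B's pulse as audible to A.  Two modes are provided and the
  choice is always recorded: ``as_printed`` applies
  ``CF2_BA = CF2_B * C / (C - |v_BA|)``, which treats every encounter as
  an up-shift; ``signed`` applies ``C / (C + v_BA)``, which down-shifts
  receding pairs and is the physically directional form.  Neither is
  silently corrected into the other.

The azimuths use the full-quadrant ``atan2`` — a ratio-based arctangent
loses the quadrant, and the cosine-difference terms make quadrants
consequential.  The inclinations keep the dz-over-dx convention (not over
horizontal range) but are computed as ``atan2(dz, |dx|)``: putting the
x-quadrant into phi as well would flip the sign of the cosine product for
westbound planar flight and break the identity that, for z-constant
trajectories, v_BA equals the exact 2-D projection
``(velocity_B - velocity_A) . u_AB``.  The product form is exact for
planar motion and a small-angle approximation otherwise;
``relative_velocity_exact3d`` offers the plain 3-D vector projection
alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import Trajectory

__all__ = [
    "SmoothedTrajectory", "FlightDirection", "InterBatGeometry",
    "fit_polynomials", "flight_directions", "inter_bat_geometry",
    "relative_velocity", "relative_velocity_exact3d", "received_cf2",
    "estimate_received_series",
]

log = logging.getLogger(__name__)


@dataclass
class SmoothedTrajectory:
    """Per-segment polynomial smooth of one bat's flight path."""

    bat_id: int
    frame_rate: float
    t_start: float
    t_end: float
    # per segment: (t0, t1, coeffs with shape (order+1, 3))
    segments: list = field(default_factory=list)
    residual_rms: float = 0.0

    def _segment(self, t: float):
        for t0, t1, coeffs in self.segments:
            if t0 - 1e-9 <= t <= t1 + 1e-9:
                return t0, t1, coeffs
        raise ValueError(f"t={t} outside fitted span "
                         f"[{self.t_start}, {self.t_end}]")

    def position(self, t) -> np.ndarray:
        """Fitted position at time ``t`` (scalar -> (3,), array -> (n, 3))."""
        if np.ndim(t) > 0:
            return np.stack([self.position(float(ti)) for ti in t])
        t0, t1, coeffs = self._segment(float(t))
        x = 2.0 * (t - t0) / (t1 - t0) - 1.0
        return np.polynomial.polynomial.polyval(x, coeffs)

    def position_at_frame(self, n: int) -> np.ndarray:
        return self.position(self.t_start + n / self.frame_rate)

    def velocity(self, t: float) -> np.ndarray:
        """Analytic velocity of the fitted polynomial at time ``t`` (m/s)."""
        t0, t1, coeffs = self._segment(float(t))
        x = 2.0 * (t - t0) / (t1 - t0) - 1.0
        dcoeffs = np.polynomial.polynomial.polyder(coeffs, axis=0)
        return np.polynomial.polynomial.polyval(x, dcoeffs) * 2.0 / (t1 - t0)

    @property
    def n_frames(self) -> int:
        return int(round((self.t_end - self.t_start) * self.frame_rate)) + 1

    def covers(self, t: float) -> bool:
        return self.t_start - 1e-9 <= t <= self.t_end + 1e-9


@dataclass
class FlightDirection:
    """Flight direction and speed of one bat at one frame."""

    bat_id: int
    frame: int
    theta: float    # rad, x-y plane azimuth
    phi: float      # rad, x-z plane inclination (dz over dx)
    v: float        # m/s
    carried: bool = False   # direction carried from previous frame


@dataclass
class InterBatGeometry:
    """Bearing and separation from listener A to emitter B at one frame."""

    frame: int
    theta_ab: float
    phi_ab: float
    separation: float


def fit_polynomials(traj: Trajectory, segment_len_s: float = 5.0,
                    order: int = 10) -> SmoothedTrajectory:
    """Least-squares polynomial smooth per coordinate per segment.

    The flight is cut into consecutive ``segment_len_s`` windows; a short
    final remainder (less than half a window) is merged backward into the
    previous segment.  Each segment needs at least ``order + 1`` frames.
    """
    t = traj.t
    dur = float(t[-1] - t[0])
    n_full = max(1, int(dur // segment_len_s))
    bounds = [float(t[0]) + i * segment_len_s for i in range(n_full + 1)]
    if float(t[-1]) - bounds[-1] > 1e-9:
        bounds.append(float(t[-1]))
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < segment_len_s / 2:
        # merge a short trailing remainder into the previous segment
        del bounds[-2]
    sm = SmoothedTrajectory(bat_id=traj.bat_id, frame_rate=traj.frame_rate,
                            t_start=float(t[0]), t_end=float(t[-1]))
    sq_sum, n_tot = 0.0, 0
    for i in range(len(bounds) - 1):
        t0, t1 = bounds[i], bounds[i + 1]
        m = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        if m.sum() < order + 1:
            raise ValueError(
                f"segment {i} ([{t0:.2f}, {t1:.2f}] s) has {int(m.sum())} "
                f"frames; need at least {order + 1} for order {order}")
        x = 2.0 * (t[m] - t0) / (t1 - t0) - 1.0
        coeffs = np.polynomial.polynomial.polyfit(x, traj.xyz[m], order)
        fit = np.polynomial.polynomial.polyval(x, coeffs).T
        sq_sum += float(((fit - traj.xyz[m]) ** 2).sum())
        n_tot += int(m.sum())
        sm.segments.append((float(t0), float(t1), coeffs))
    sm.residual_rms = math.sqrt(sq_sum / (3 * n_tot))
    return sm


def flight_directions(sm: SmoothedTrajectory, n: int,
                      _prev: FlightDirection | None = None) -> FlightDirection:
    """Direction and speed at frame ``n`` from frames n-1 and n.

    A zero displacement carries the previous frame's direction forward
    (flagged); with no previous direction available both angles are 0.
    """
    if n < 1 or n >= sm.n_frames:
        raise ValueError(f"frame {n} out of range 1..{sm.n_frames - 1}")
    d = sm.position_at_frame(n) - sm.position_at_frame(n - 1)
    v = float(np.linalg.norm(d)) * sm.frame_rate
    if not np.any(np.abs(d) > 0):
        prev = _prev if _prev is not None else (
            flight_directions(sm, n - 1) if n > 1 else None)
        theta = prev.theta if prev else 0.0
        phi = prev.phi if prev else 0.0
        return FlightDirection(sm.bat_id, n, theta, phi, 0.0, carried=True)
    return FlightDirection(sm.bat_id, n,
                           theta=math.atan2(d[1], d[0]),
                           phi=math.atan2(d[2], abs(d[0])), v=v)


def inter_bat_geometry(sm_a: SmoothedTrajectory, sm_b: SmoothedTrajectory,
                       n: int) -> InterBatGeometry:
    """Bearing (full-quadrant) and separation from A to B at frame ``n``."""
    pa = sm_a.position_at_frame(n)
    pb = sm_b.position_at_frame(n)
    d = pb - pa
    sep = float(np.linalg.norm(d))
    if sep < 1e-12:
        raise ValueError(f"bats coincide at frame {n}; bearing undefined")
    return InterBatGeometry(frame=n,
                            theta_ab=math.atan2(d[1], d[0]),
                            phi_ab=math.atan2(d[2], abs(d[0])),
                            separation=sep)


def relative_velocity(dir_a: FlightDirection, dir_b: FlightDirection,
                      geom: InterBatGeometry) -> float:
    """Relative radial velocity of B with respect to A (m/s, as printed)."""
    return (dir_b.v
            * math.cos(dir_b.theta - geom.theta_ab)
            * math.cos(dir_b.phi - geom.phi_ab)
            - dir_a.v
            * math.cos(dir_a.theta - geom.theta_ab)
            * math.cos(dir_a.phi - geom.phi_ab))


def relative_velocity_exact3d(sm_a: SmoothedTrajectory,
                              sm_b: SmoothedTrajectory, n: int) -> float:
    """(velocity_B - velocity_A) projected on the A->B unit vector.

    The exact 3-D radial rate from the same frame differences; coincides
    with the angle-decomposition form whenever the motion is planar.
    """
    fr = sm_a.frame_rate
    va = (sm_a.position_at_frame(n) - sm_a.position_at_frame(n - 1)) * fr
    vb = (sm_b.position_at_frame(n) - sm_b.position_at_frame(n - 1)) * fr
    d = sm_b.position_at_frame(n) - sm_a.position_at_frame(n)
    u = d / np.linalg.norm(d)
    return float((vb - va) @ u)


def received_cf2(cf2_b: float, v_ba: float, sound_speed: float = 343.5,
                 mode: str = "as_printed") -> float:
    """CF2 of B's pulse as audible to A.

    ``as_printed``: ``CF2_B * C / (C - |v_BA|)`` — magnitude only, every
    estimate an up-shift.  ``signed``: ``CF2_B * C / (C + v_BA)`` with
    positive ``v_BA`` receding — directional.
    """
    if cf2_b <= 0:
        raise ValueError("cf2_b must be positive")
    if abs(v_ba) >= sound_speed:
        raise ValueError("|v_BA| must be below the speed of sound")
    if mode == "as_printed":
        return cf2_b * sound_speed / (sound_speed - abs(v_ba))
    if mode == "signed":
        return cf2_b * sound_speed / (sound_speed + v_ba)
    raise ValueError(f"unknown mode {mode!r}")


def estimate_received_series(pulses: pd.DataFrame,
                             smoothed: dict[int, SmoothedTrajectory],
                             sound_speed: float = 343.5,
                             mode: str = "as_printed",
                             velocity_method: str = "angles",
                             subframe: bool = False) -> pd.DataFrame:
    """Estimate, for every ordered (listener, emitter) pair, the received
    CF2 of each focal pulse of the emitter.

    ``pulses`` needs columns ``bat_id``, ``t`` (emission/onset time, s) and
    ``cf2`` (emitted CF2 measured on the emitter's channel, Hz).

    ``velocity_method``: ``"angles"`` uses the cosine-product
    decomposition of the relative velocity (exact for planar motion);
    ``"exact3d"`` projects the velocity difference on the line of sight.
    ``subframe=False`` evaluates geometry at the frame nearest each
    emission; ``subframe=True`` evaluates the fitted polynomials (and
    their analytic derivatives) at the exact emission time, removing the
    half-frame quantisation — this is the configuration used for physical
    validation against waveform-level ground truth.

    Pulses outside trajectory coverage (or in frame 0, which has no finite
    difference) are skipped with a log entry.  Output columns: listener,
    emitter, t, frame, v_ba, cf2_emitted, cf2_received, mode.
    """
    if velocity_method not in ("angles", "exact3d"):
        raise ValueError(f"unknown velocity_method {velocity_method!r}")
    rows = []
    skipped = 0
    bat_ids = sorted(smoothed)
    dirs_cache: dict[tuple[int, int], FlightDirection] = {}

    def _dir(b: int, n: int) -> FlightDirection:
        key = (b, n)
        if key not in dirs_cache:
            dirs_cache[key] = flight_directions(smoothed[b], n)
        return dirs_cache[key]

    def _v_ba(a: int, b: int, n: int, t: float) -> float:
        if subframe:
            va = smoothed[a].velocity(t)
            vb = smoothed[b].velocity(t)
            pa = smoothed[a].position(t)
            pb = smoothed[b].position(t)
            d = pb - pa
            sep = float(np.linalg.norm(d))
            if sep < 1e-12:
                raise ValueError(f"bats coincide at t={t}")
            if velocity_method == "exact3d":
                return float((vb - va) @ (d / sep))
            geom = InterBatGeometry(
                n, math.atan2(d[1], d[0]), math.atan2(d[2], abs(d[0])), sep)
            da = FlightDirection(a, n, math.atan2(va[1], va[0]),
                                 math.atan2(va[2], abs(va[0])),
                                 float(np.linalg.norm(va)))
            db = FlightDirection(b, n, math.atan2(vb[1], vb[0]),
                                 math.atan2(vb[2], abs(vb[0])),
                                 float(np.linalg.norm(vb)))
            return relative_velocity(da, db, geom)
        if velocity_method == "exact3d":
            return relative_velocity_exact3d(smoothed[a], smoothed[b], n)
        geom = inter_bat_geometry(smoothed[a], smoothed[b], n)
        return relative_velocity(_dir(a, n), _dir(b, n), geom)

    for p in pulses.itertuples(index=False):
        b = int(p.bat_id)
        if b not in smoothed or not math.isfinite(p.cf2):
            continue
        sm_b = smoothed[b]
        n = int(round((p.t - sm_b.t_start) * sm_b.frame_rate))
        if n < 1 or n >= sm_b.n_frames or not sm_b.covers(p.t):
            skipped += 1
            continue
        for a in bat_ids:
            if a == b:
                continue
            v_ba = _v_ba(a, b, n, float(p.t))
            rows.append((a, b, float(p.t), n, v_ba, float(p.cf2),
                         received_cf2(float(p.cf2), v_ba, sound_speed, mode),
                         mode))
    if skipped:
        log.info("%d pulses outside trajectory coverage were skipped", skipped)
    return pd.DataFrame(rows, columns=[
        "listener", "emitter", "t", "frame", "v_ba", "cf2_emitted",
        "cf2_received", "mode"])
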