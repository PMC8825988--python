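"""Polynomial smoothing, flight geometry and Doppler estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sonarjam import (make_scene, simulate_trajectories, fit_polynomials,
                      flight_directions, inter_bat_geometry,
                      relative_velocity, relative_velocity_exact3d,
                      received_cf2, estimate_received_series)
from sonarjam.doppler import FlightDirection, InterBatGeometry
from sonarjam.trajectories import Trajectory


def _linear_traj(bat_id, delta, n=40, fps=30.0, origin=(0.0, 0.0, 0.0)):
    t = np.arange(n) / fps
    xyz = np.asarray(origin) + np.outer(np.arange(n), np.asarray(delta))
    return Trajectory(bat_id=bat_id, frame=np.arange(n), t=t, xyz=xyz)


class TestFitting:
    def test_polynomial_input_recovered_exactly(self):
        t = np.arange(150) / 30.0
        xyz = np.stack([0.1 * t**3 - t, 2 + t**2, 0.5 * t], axis=1)
        tr = Trajectory(0, np.arange(150), t, xyz)
        sm = fit_polynomials(tr)
        assert sm.residual_rms < 1e-9

    def test_noiseless_loop_residual_below_one_centimetre(self):
        sc = make_scene("full", n_bats=1, duration=5.0, seed=3)
        tr = simulate_trajectories(sc)[0]
        assert fit_polynomials(tr).residual_rms < 0.01

    def test_ten_second_flight_gives_two_segments(self):
        sc = make_scene("narrow", n_bats=1, duration=10.0, seed=3)
        sm = fit_polynomials(simulate_trajectories(sc)[0])
        assert len(sm.segments) == 2

    def test_twenty_second_flight_gives_four_segments(self):
        sc = make_scene("narrow", n_bats=1, duration=20.0, seed=3)
        sm = fit_polynomials(simulate_trajectories(sc)[0])
        assert len(sm.segments) == 4

    def test_underdetermined_segment_names_itself(self):
        tr = _linear_traj(0, (0.01, 0, 0), n=8)
        with pytest.raises(ValueError, match="segment 0"):
            fit_polynomials(tr)


class TestDirections:
    def test_motion_along_x(self):
        sm = fit_polynomials(_linear_traj(0, (0.05, 0, 0)), order=3)
        d = flight_directions(sm, 5)
        assert d.theta == pytest.approx(0.0, abs=1e-9)
        assert d.phi == pytest.approx(0.0, abs=1e-9)

    def test_motion_along_y_gives_quarter_turn(self):
        sm = fit_polynomials(_linear_traj(0, (0, 0.05, 0)), order=3)
        assert flight_directions(sm, 5).theta == pytest.approx(np.pi / 2)

    def test_hand_evaluated_oblique_motion(self):
        """Delta (1, 1, -1) m/frame: theta pi/4, phi -pi/4, v sqrt(3)*30."""
        sm = fit_polynomials(_linear_traj(0, (1.0, 1.0, -1.0)), order=3)
        d = flight_directions(sm, 5)
        assert d.theta == pytest.approx(np.pi / 4)
        assert d.phi == pytest.approx(-np.pi / 4)
        assert d.v == pytest.approx(math.sqrt(3) * 30.0, rel=1e-9)

    def test_stationary_direction_carried_and_flagged(self):
        from sonarjam import SmoothedTrajectory
        coeffs = np.zeros((4, 3))
        coeffs[0] = (1.0, 2.0, 1.2)   # constant position -> zero motion
        sm = SmoothedTrajectory(bat_id=0, frame_rate=30.0, t_start=0.0,
                                t_end=1.0, segments=[(0.0, 1.0, coeffs)])
        d = flight_directions(sm, 5)
        assert d.carried and d.v == 0.0 and d.theta == 0.0


class TestGeometry:
    def test_emitter_straight_ahead_on_x(self):
        a = fit_polynomials(_linear_traj(0, (0.01, 0, 0)), order=3)
        b = fit_polynomials(_linear_traj(1, (0.01, 0, 0), origin=(2, 0, 0)),
                            order=3)
        g = inter_bat_geometry(a, b, 5)
        assert g.theta_ab == pytest.approx(0.0, abs=1e-9)
        assert g.phi_ab == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_bearing(self):
        """A=(1,1,1), B=(2,3,0): theta atan2(2,1), phi atan2(-1,1), sep sqrt6."""
        a = fit_polynomials(_linear_traj(0, (0.01, 0, 0), origin=(1, 1, 1)),
                            order=3)
        b = fit_polynomials(_linear_traj(1, (0.01, 0, 0), origin=(2, 3, 0)),
                            order=3)
        g = inter_bat_geometry(a, b, 0)
        assert g.theta_ab == pytest.approx(math.atan2(2, 1))
        assert g.phi_ab == pytest.approx(math.atan2(-1, 1))
        assert g.separation == pytest.approx(math.sqrt(6))

    def test_bearing_antisymmetry(self):
        a = fit_polynomials(_linear_traj(0, (0.02, 0.01, 0.005)), order=3)
        b = fit_polynomials(_linear_traj(1, (0.01, -0.02, 0.002),
                                         origin=(1.5, -0.7, 0.4)), order=3)
        g_ab = inter_bat_geometry(a, b, 5)
        g_ba = inter_bat_geometry(b, a, 5)
        dtheta = (g_ab.theta_ab - g_ba.theta_ab) % (2 * np.pi)
        assert dtheta == pytest.approx(np.pi)
        assert g_ab.phi_ab == pytest.approx(-g_ba.phi_ab)
        assert g_ab.separation == pytest.approx(g_ba.separation)

    def test_coincident_positions_rejected(self):
        a = fit_polynomials(_linear_traj(0, (0.01, 0, 0)), order=3)
        with pytest.raises(ValueError, match="coincide"):
            inter_bat_geometry(a, a, 5)


class TestRelativeVelocity:
    def test_both_stationary(self):
        d0 = FlightDirection(0, 1, 0.0, 0.0, 0.0)
        g = InterBatGeometry(1, 0.3, 0.0, 2.0)
        assert relative_velocity(d0, d0, g) == 0.0

    def test_head_on_approach_hand_value(self):
        """A at origin ->+x 1 m/s, B at (2,0,0) -> -x 1 m/s: v_BA = -2."""
        da = FlightDirection(0, 1, 0.0, 0.0, 1.0)
        db = FlightDirection(1, 1, math.pi, 0.0, 1.0)
        g = InterBatGeometry(1, 0.0, 0.0, 2.0)
        assert relative_velocity(da, db, g) == pytest.approx(-2.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_planar_equivalence_with_vector_oracle(self, i):
        """For planar motion the angle form equals the exact projection."""
        rng = np.random.default_rng(i)
        pa, pb = rng.uniform(-5, 5, 2), rng.uniform(-5, 5, 2)
        if np.allclose(pa, pb):
            return
        va, vb = rng.uniform(-4, 4, 2), rng.uniform(-4, 4, 2)
        da = FlightDirection(0, 1, math.atan2(va[1], va[0]), 0.0,
                             float(np.hypot(*va)))
        db = FlightDirection(1, 1, math.atan2(vb[1], vb[0]), 0.0,
                             float(np.hypot(*vb)))
        d = pb - pa
        g = InterBatGeometry(1, math.atan2(d[1], d[0]), 0.0,
                             float(np.hypot(*d)))
        exact = float((vb - va) @ (d / np.hypot(*d)))
        assert relative_velocity(da, db, g) == pytest.approx(exact, abs=1e-9)

    def test_magnitude_bounded_by_speed_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            va, vb = rng.uniform(-4, 4, 3), rng.uniform(-4, 4, 3)
            pa, pb = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
            da = FlightDirection(0, 1, math.atan2(va[1], va[0]),
                                 math.atan2(va[2], abs(va[0])),
                                 float(np.linalg.norm(va)))
            db = FlightDirection(1, 1, math.atan2(vb[1], vb[0]),
                                 math.atan2(vb[2], abs(vb[0])),
                                 float(np.linalg.norm(vb)))
            d = pb - pa
            g = InterBatGeometry(1, math.atan2(d[1], d[0]),
                                 math.atan2(d[2], abs(d[0])),
                                 float(np.linalg.norm(d)))
            v = relative_velocity(da, db, g)
            assert abs(v) <= da.v + db.v + 1e-9


class TestReceivedCF2:
    def test_zero_relative_velocity_is_identity(self):
        for mode in ("as_printed", "signed"):
            assert received_cf2(68_000.0, 0.0, mode=mode) == 68_000.0

    def test_as_printed_hand_value(self):
        got = received_cf2(68_000.0, -2.0, 343.5, "as_printed")
        assert got == pytest.approx(68_000.0 * 343.5 / 341.5)

    def test_as_printed_never_downshifts(self):
        for v in np.linspace(-30, 30, 61):
            assert received_cf2(68_000.0, float(v)) >= 68_000.0

    def test_as_printed_monotone_in_speed_magnitude(self):
        vals = [received_cf2(68_000.0, float(v))
                for v in np.linspace(0, 20, 41)]
        assert np.all(np.diff(vals) > 0)

    def test_signed_mode_downshifts_receding_pairs(self):
        assert received_cf2(68_000.0, 2.0, mode="signed") < 68_000.0

    def test_supersonic_and_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            received_cf2(68_000.0, 400.0)
        with pytest.raises(ValueError):
            received_cf2(68_000.0, 1.0, mode="nope")
        with pytest.raises(ValueError):
            received_cf2(-1.0, 1.0)


class TestSeries:
    def test_single_bat_yields_no_estimates(self):
        sc = make_scene("narrow", n_bats=1, duration=5.0, seed=3)
        sm = {0: fit_polynomials(simulate_trajectories(sc)[0])}
        pulses = pd.DataFrame({"bat_id": [0], "t": [2.0], "cf2": [68_000.0]})
        assert len(estimate_received_series(pulses, sm)) == 0

    def test_ordered_pair_count(self, group_scene):
        """Every pulse of each of 3 bats is heard by the 2 others."""
        sc, trs, em, waves, gt = group_scene
        sm = {tr.bat_id: fit_polynomials(tr) for tr in trs}
        pulses = em.rename(columns={"t_emit": "t", "cf2_emit_hz": "cf2"})
        est = estimate_received_series(pulses[["bat_id", "t", "cf2"]], sm)
        n_skipped = sum(
            int(round(t * sc.frame_rate)) < 1 for t in pulses["t"])
        assert len(est) == 2 * (len(em) - n_skipped)
        assert set(est["mode"]) == {"as_printed"}

    def test_pulse_outside_coverage_skipped(self):
        sc = make_scene("narrow", n_bats=2, duration=5.0, seed=3)
        sm = {tr.bat_id: fit_polynomials(tr)
              for tr in simulate_trajectories(sc)}
        pulses = pd.DataFrame({"bat_id": [0, 0], "t": [2.0, 99.0],
                               "cf2": [68_000.0, 68_000.0]})
        est = estimate_received_series(pulses, sm)
        assert len(est) == 1
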