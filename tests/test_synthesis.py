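"""Vocalization schedules, Doppler-shift compensation and rendering."""

import numpy as np
import pandas as pd
import pytest

from sonarjam import (make_scene, simulate_trajectories,
                      simulate_vocalizations, render_telemetry_waveforms,
                      dsc_emitted_cf2, synth_cf_fm_pulse, VocalProfile)


class TestDSC:
    def test_no_motion_emits_at_reference(self):
        for g in (0.0, 0.5, 1.0):
            assert dsc_emitted_cf2(68_500.0, 0.0, g) == 68_500.0

    def test_full_compensation_round_trip_is_exact(self):
        """Two-way Doppler on the compensated emission returns exactly RF."""
        rf, v, c = 68_500.0, 3.0, 343.5
        emitted = dsc_emitted_cf2(rf, v, 1.0, c)
        assert emitted == pytest.approx(rf * (c - v) / (c + v))
        echo = emitted * (c + v) / (c - v)
        assert abs(echo - rf) < 1e-9

    def test_approach_lowers_the_call(self):
        assert dsc_emitted_cf2(68_500.0, 2.0, 1.0) < 68_500.0

    def test_supersonic_closing_speed_rejected(self):
        with pytest.raises(ValueError):
            dsc_emitted_cf2(68_500.0, 400.0, 1.0, 343.5)


def _fixed_profile(**kw):
    base = dict(pulse_duration=(20.0, 0.0), tfm_duration=(1.8, 0.0),
                tfm_bandwidth=(14_000.0, 0.0), ifm_present=0.0,
                inter_group_interval=(52.0, 0.0),
                intra_group_interval=(20.0, 0.0))
    base.update(kw)
    return VocalProfile(**base)


class TestSchedule:
    def test_fixed_intervals_give_52ms_silent_times(self):
        prof = _fixed_profile(pulses_per_group={1: 1.0})
        sc = make_scene("narrow", n_bats=1, duration=5.0, seed=3,
                        profiles=(prof,))
        em = simulate_vocalizations(sc, simulate_trajectories(sc))
        gaps = np.diff(em.t_emit.to_numpy()) * 1e3 - em.duration_ms.to_numpy()[:-1]
        np.testing.assert_allclose(gaps, 52.0, atol=1e-9)

    def test_doublet_groups_alternate_intra_and_inter_gaps(self):
        prof = _fixed_profile(pulses_per_group={2: 1.0})
        sc = make_scene("narrow", n_bats=1, duration=5.0, seed=3,
                        profiles=(prof,))
        em = simulate_vocalizations(sc, simulate_trajectories(sc))
        gaps = np.diff(em.t_emit.to_numpy()) * 1e3 - em.duration_ms.to_numpy()[:-1]
        np.testing.assert_allclose(gaps[::2], 20.0, atol=1e-9)
        np.testing.assert_allclose(gaps[1::2], 52.0, atol=1e-9)

    def test_same_seed_same_schedule(self):
        sc = make_scene("narrow", n_bats=2, duration=5.0, seed=9)
        trs = simulate_trajectories(sc)
        a = simulate_vocalizations(sc, trs)
        b = simulate_vocalizations(sc, trs)
        pd.testing.assert_frame_equal(a, b)


class TestRendering:
    def test_waveform_length_is_duration_times_fs(self, single_scene):
        sc, trs, em, waves, gt = single_scene
        assert waves.shape == (1, int(sc.duration * sc.sample_rate))

    def test_echo_cf2_follows_two_way_doppler_closed_form(self, single_scene):
        sc, trs, em, waves, gt = single_scene
        c = sc.sound_speed
        ech = gt.arrivals.query("kind == 'own_echo'").merge(
            em, left_on=["source_bat_id", "pulse_id"],
            right_on=["bat_id", "pulse_id"])
        expect = ech.cf2_emit_hz * (c + ech.v_wall_mps) / (c - ech.v_wall_mps)
        np.testing.assert_allclose(ech.cf2_arrival_hz, expect, rtol=1e-12)

    def test_full_dsc_echoes_arrive_at_reference_frequency(self, single_scene):
        sc, trs, em, waves, gt = single_scene
        rf = sc.profiles[0].reference_frequency
        ech = gt.arrivals.query("kind == 'own_echo'")
        # approach-phase echoes (compensated) sit exactly at RF
        on = ech[ech.doppler_factor > 1.0]
        assert len(on) > 10
        np.testing.assert_allclose(on.cf2_arrival_hz, rf, atol=1e-6)

    def test_echo_delay_is_round_trip_distance(self, single_scene):
        sc, trs, em, waves, gt = single_scene
        ech = gt.arrivals.query("kind == 'own_echo'").merge(
            em, left_on=["source_bat_id", "pulse_id"],
            right_on=["bat_id", "pulse_id"])
        delay = ech.t_arrival - ech.t_emit
        assert (delay > 0).all()
        assert delay.max() < 2 * max(sc.chamber_dims) / sc.sound_speed

    def test_no_walls_leaves_only_own_pulses(self):
        sc = make_scene("narrow", n_bats=1, duration=3.0, seed=5,
                        wall_loss_db=float("-inf"))
        trs = simulate_trajectories(sc)
        em = simulate_vocalizations(sc, trs)
        waves, gt = render_telemetry_waveforms(sc, trs, em)
        assert set(gt.arrivals.kind) == {"own_pulse"}

    def test_every_arrival_maps_to_an_emitted_pulse(self, group_scene):
        sc, trs, em, waves, gt = group_scene
        gt.validate()   # raises on orphan arrivals or acausal timing

    def test_rendering_is_deterministic(self):
        out = []
        for _ in range(2):
            sc = make_scene("narrow", n_bats=2, duration=2.0, seed=21)
            trs = simulate_trajectories(sc)
            em = simulate_vocalizations(sc, trs)
            waves, gt = render_telemetry_waveforms(sc, trs, em)
            out.append(waves)
        np.testing.assert_array_equal(out[0], out[1])


class TestPulseSynthesis:
    def test_doppler_factor_scales_frequency_and_duration(self):
        fs = 500_000.0
        q = 1.01
        w1 = synth_cf_fm_pulse(fs, 68_000.0, 20.0, 2.0, 14_000.0)
        w2 = synth_cf_fm_pulse(fs, 68_000.0, 20.0, 2.0, 14_000.0,
                               doppler_factor=q)
        assert len(w2) == pytest.approx(len(w1) / q, abs=1.5)
        # dominant frequency of the CF portion scales by q
        for w, f_expect in ((w1, 68_000.0), (w2, 68_000.0 * q)):
            seg = w[2000:9000] * np.hanning(7000)
            spec = np.abs(np.fft.rfft(seg, 1 << 15))
            f = np.fft.rfftfreq(1 << 15, 1 / fs)
            assert abs(f[np.argmax(spec)] - f_expect) < fs / (1 << 15) * 2
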