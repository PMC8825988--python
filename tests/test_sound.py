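"""Detection, segmentation and acoustic feature measurement."""

import math

import numpy as np
import pytest

from sonarjam import (AnalysisConfig, SoundEvent, bandpass, spectrogram,
                      detect_events, estimate_cf2, classify_events,
                      group_and_silent_times, make_scene,
                      simulate_trajectories, simulate_vocalizations,
                      render_telemetry_waveforms, synth_cf_fm_pulse,
                      events_to_frame)
from conftest import match_focal_to_emissions

FS = 500_000.0


class TestSpectrogram:
    def test_pure_tone_ridge_within_one_bin(self):
        t = np.arange(int(0.05 * FS)) / FS
        f, tt, S = spectrogram(np.sin(2 * np.pi * 68_000 * t), FS)
        ridge = f[np.argmax(S, axis=0)]
        assert np.all(np.abs(ridge - 68_000) <= FS / 1024)

    def test_silence_stays_below_noise_floor(self):
        f, tt, S = spectrogram(np.zeros(int(0.05 * FS)), FS)
        assert S.max() < 1e-12

    def test_linear_sweep_slope_recovered(self):
        """An 80->66 kHz sweep over 2 ms shows a -7 kHz/ms ridge."""
        n = int(0.002 * FS)
        t = np.arange(n) / FS
        freq = 80_000 + (66_000 - 80_000) * t / t[-1]
        wave = np.sin(2 * np.pi * np.cumsum(freq) / FS)
        f, tt, S = spectrogram(wave, FS, window_len=256, overlap=0.875)
        ridge = f[np.argmax(S, axis=0)]
        slope = np.polyfit(tt, ridge, 1)[0] / 1e6   # kHz per ms
        assert slope == pytest.approx(-7.0, abs=0.7)

    def test_window_longer_than_signal_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram(np.zeros(100), FS, window_len=1024)


class TestDetection:
    def test_noise_free_channel_yields_exactly_the_emitted_pulses(self):
        sc = make_scene("narrow", n_bats=1, duration=3.0, seed=31,
                        wall_loss_db=float("-inf"))
        trs = simulate_trajectories(sc)
        em = simulate_vocalizations(sc, trs)
        waves, gt = render_telemetry_waveforms(sc, trs, em)
        events = detect_events(waves[0], sc.sample_rate)
        assert len(events) == len(em)

    def test_pure_noise_gives_no_events(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1e-3, int(FS))
        assert detect_events(x, FS) == []

    def test_half_millisecond_gap_is_bridged(self):
        """Two equal pulses 0.5 ms apart merge into one event."""
        p = synth_cf_fm_pulse(FS, 68_000.0, 5.0, 1.0, 10_000.0)
        gap = np.zeros(int(0.0005 * FS))
        x = np.concatenate([np.zeros(1000), p, gap, p, np.zeros(1000)])
        events = detect_events(x, FS)
        assert len(events) == 1

    def test_weak_tail_splits_from_strong_core(self):
        """A -30 dB continuation (an echo tail) becomes its own event."""
        p = synth_cf_fm_pulse(FS, 68_000.0, 10.0, 1.0, 10_000.0)
        tail = 10 ** (-30 / 20) * synth_cf_fm_pulse(
            FS, 68_400.0, 10.0, 1.0, 10_000.0)
        x = np.concatenate([np.zeros(1000), p, tail[:len(tail) // 2],
                            np.zeros(3000)])
        events = detect_events(x, FS)
        assert len(events) == 2
        assert events[1].peak_level_db < events[0].peak_level_db - 20


class TestCF2:
    def test_bin_width_is_fs_over_16384_regardless_of_length(self):
        for dur in (6.0, 40.0):
            w = synth_cf_fm_pulse(FS, 68_500.0, dur, 1.0, 10_000.0)
            x = np.concatenate([np.zeros(500), w, np.zeros(500)])
            ev = detect_events(x, FS)[0]
            estimate_cf2(ev, x, FS)
            assert ev.cf2_bin_width == FS / 16_384

    def test_pure_tone_event_within_one_bin(self):
        t = np.arange(int(0.02 * FS)) / FS
        ramp = np.minimum(1, np.minimum(t, t[-1] - t) / 0.0002)
        x = np.concatenate([np.zeros(500),
                            ramp * np.sin(2 * np.pi * 68_500 * t),
                            np.zeros(500)])
        ev = detect_events(x, FS)[0]
        estimate_cf2(ev, x, FS)
        assert abs(ev.cf2_raw - 68_500) <= FS / 16_384
        assert "cf_zero_padded" in ev.flags

    def test_no_plateau_is_flagged(self):
        # pure FM sweep, no CF portion
        n = int(0.004 * FS)
        t = np.arange(n) / FS
        freq = 90_000 - 6e6 * t
        x = np.concatenate([np.zeros(500),
                            np.sin(2 * np.pi * np.cumsum(freq) / FS),
                            np.zeros(500)])
        ev = detect_events(x, FS, AnalysisConfig(min_dur_ms=1.0))[0]
        estimate_cf2(ev, x, FS)
        assert math.isnan(ev.cf2)
        assert "no_cf_plateau" in ev.flags


class TestRecovery:
    """Round-trip feature recovery against simulator ground truth."""

    def test_single_bat_counts_and_features(self, single_scene,
                                            single_analysis):
        sc, trs, em, waves, gt = single_scene
        events, groups, silent = single_analysis
        m = match_focal_to_emissions(events, em)
        assert len(m) == len(em)
        cf2_err = (m.cf2 - m.cf2_emit_hz).abs()
        assert (cf2_err <= sc.sample_rate / 16_384).all()
        assert (m.pulse_duration - m.duration_ms).abs().quantile(0.95) <= 0.2
        assert ((m.tfm_bandwidth - m.tfm_bandwidth_hz).abs()
                .quantile(0.95)) <= 500.0
        assert (m.tfm_duration - m.tfm_duration_ms).abs().quantile(0.95) <= 0.2
        assert (m.ifm_detected == m.has_ifm).mean() >= 0.95

    def test_pulse_without_tfm_flagged_zero_duration(self):
        w = synth_cf_fm_pulse(FS, 68_000.0, 15.0, 0.001, 1.0)
        x = np.concatenate([np.zeros(500), w, np.zeros(500)])
        ev = detect_events(x, FS)[0]
        from sonarjam import measure_components
        estimate_cf2(ev, x, FS)
        measure_components(ev, x, FS)
        assert ev.tfm_duration == 0.0
        assert "no_tfm" in ev.flags

    def test_pulse_without_ifm_not_detected_as_ifm(self):
        w = synth_cf_fm_pulse(FS, 68_000.0, 15.0, 2.0, 14_000.0,
                              ifm_duration_ms=0.0)
        x = np.concatenate([np.zeros(500), w, np.zeros(500)])
        ev = detect_events(x, FS)[0]
        from sonarjam import measure_components
        estimate_cf2(ev, x, FS)
        measure_components(ev, x, FS)
        assert not ev.ifm_detected


class TestClassification:
    def test_single_bat_scene_has_no_other_pulse_labels(self,
                                                        single_analysis):
        events, groups, silent = single_analysis
        assert not any(e.kind == "other_pulse" for e in events)

    def test_no_echo_labels_before_first_focal_pulse(self, group_analysis):
        events, groups, silent = group_analysis
        first_focal = {}
        for e in sorted(events, key=lambda e: e.onset):
            if e.kind == "focal_pulse":
                first_focal.setdefault(e.channel_bat_id, e.onset)
        for e in events:
            if e.kind == "own_echo":
                assert e.onset >= first_focal[e.channel_bat_id]

    def test_zero_echo_window_disables_timing_rule(self):
        evs = [SoundEvent(0, 0.0, 0.02, peak_amp=1.0, peak_level_db=0.0),
               SoundEvent(0, 0.05, 0.06, peak_amp=0.01,
                          peak_level_db=-40.0)]
        cfg = AnalysisConfig(echo_window_ms=(0.0, 0.0))
        classify_events(evs, cfg, n_channels=1)
        assert evs[1].kind != "own_echo"


class TestGrouping:
    def _ev(self, on, off):
        return SoundEvent(0, on, off, kind="focal_pulse")

    def test_silent_times_are_inter_group_gaps(self):
        evs = [self._ev(0.0, 0.02), self._ev(0.03, 0.05),  # one group
               self._ev(0.102, 0.122),                     # 52 ms gap
               self._ev(0.174, 0.194)]
        groups, silent = group_and_silent_times(evs, gap_threshold_ms=30.0)
        assert [len(g.events) for g in groups] == [2, 1, 1]
        np.testing.assert_allclose(silent, [52.0, 52.0], atol=1e-9)

    def test_single_group_has_no_silent_times(self):
        evs = [self._ev(0.0, 0.02), self._ev(0.03, 0.05)]
        groups, silent = group_and_silent_times(evs, gap_threshold_ms=30.0)
        assert len(groups) == 1 and len(silent) == 0

    def test_huge_threshold_collapses_to_one_group(self):
        evs = [self._ev(0.0, 0.02), self._ev(0.5, 0.52), self._ev(1.2, 1.22)]
        groups, silent = group_and_silent_times(evs, gap_threshold_ms=1e4)
        assert len(groups) == 1 and len(silent) == 0

    def test_scheduled_silent_times_recovered(self, single_scene,
                                              single_analysis):
        """Mean detected silent time matches the generator's inter-group
        interval distribution (52 +/- 5 ms)."""
        sc, trs, em, waves, gt = single_scene
        events, groups, silent = single_analysis
        assert abs(np.mean(silent[0]) - 52.0) < 3.0
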