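"""Unit and property tests for the lung-sound simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sg

from stethosim import (
    AcousticEvent, CohortConfig, CrackleParams, DeviceProfile, HIFI_PROFILE,
    LOFI_PROFILE, Waveform, WheezeParams, apply_device_profile,
    generate_cohort, render_recording, synth_breath_noise, synth_crackle,
    synth_wheeze, write_wav,
)
from stethosim.errors import InvalidParameterError
from stethosim.simulate import breath_envelope, quantize

from conftest import tiny_config


class TestCrackleSynthesis:
    def test_two_cycle_duration_fixed_by_frequency(self):
        p = CrackleParams(onset_s=0, oscillation_freq_hz=200,
                          total_duration_ms=18)
        assert p.two_cycle_duration_ms == pytest.approx(10.0)

    @pytest.mark.parametrize("bad", [
        dict(oscillation_freq_hz=-5, total_duration_ms=20),
        dict(oscillation_freq_hz=400, total_duration_ms=20, amplitude=0.0),
        dict(oscillation_freq_hz=400, total_duration_ms=4.0),  # total < 2CD
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            synth_crackle(CrackleParams(onset_s=0, **bad), 44100)

    def test_envelope_decays_to_tenth_of_peak_at_total_duration(self):
        p = CrackleParams(onset_s=0, oscillation_freq_hz=400,
                          total_duration_ms=20)
        w = synth_crackle(p, 44100)
        peak = np.max(np.abs(w.samples))
        near_end = w.samples[int(0.0195 * 44100):]
        assert np.max(np.abs(near_end)) <= 0.1 * peak * 1.01
        # output covers the full total duration
        assert w.samples.size >= int(0.020 * 44100)

    def test_initial_deflection_is_unidirectional(self):
        p = CrackleParams(onset_s=0, oscillation_freq_hz=300,
                          total_duration_ms=15,
                          initial_deflection_fraction=0.25)
        w = synth_crackle(p, 44100)
        n_defl = int(0.25 * (2000 / 300) / 1000 * 44100)
        assert np.all(w.samples[:n_defl] >= 0)


class TestWheezeSynthesis:
    def test_periodogram_peak_at_dominant_frequency(self):
        p = WheezeParams(onset_s=0, dominant_freq_hz=400, duration_ms=200)
        w = synth_wheeze(p, 4000)
        f, pxx = sg.periodogram(w.samples, fs=4000)
        assert abs(f[np.argmax(pxx)] - 400) <= f[1] - f[0]

    def test_pure_tone_rms(self):
        p = WheezeParams(onset_s=0, dominant_freq_hz=300, duration_ms=1000,
                         amplitude=0.5, n_harmonics=0)
        w = synth_wheeze(p, 8000)
        rms = np.sqrt(np.mean(w.samples**2))
        assert rms == pytest.approx(0.5 / np.sqrt(2), rel=0.05)

    def test_nyquist_violation_rejected(self):
        p = WheezeParams(onset_s=0, dominant_freq_hz=2500, duration_ms=100)
        with pytest.raises(InvalidParameterError):
            synth_wheeze(p, 4000)

    def test_harmonics_stay_weaker_than_fundamental(self):
        p = WheezeParams(onset_s=0, dominant_freq_hz=250, duration_ms=500,
                         n_harmonics=2)
        w = synth_wheeze(p, 8000)
        f, pxx = sg.periodogram(w.samples, fs=8000)
        assert abs(f[np.argmax(pxx)] - 250) <= f[1] - f[0]


class TestBreathNoise:
    def test_deterministic_from_seed(self):
        a = synth_breath_noise(2.0, 3.0, 8000, seed=7)
        b = synth_breath_noise(2.0, 3.0, 8000, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_envelope_periodicity_and_cycle_count(self):
        env = breath_envelope(20.0, 3.0, 1000.0)
        # envelope repeats every cycle period...
        np.testing.assert_allclose(env[: 17 * 1000], env[3000: 20 * 1000],
                                   atol=1e-9)
        # ...so a 20 s recording holds floor(20/3) = 6 complete cycles:
        # cycle boundaries (envelope minima) fall at t = 0, 3, ..., 18 s
        boundaries = np.arange(0, 20_000, 3000)
        np.testing.assert_allclose(env[boundaries], env.min(), atol=1e-9)
        assert len(boundaries) - 1 == int(20 // 3)
        # mid-cycle the envelope reaches its full-amplitude peak
        assert env[1500] == pytest.approx(1.0)

    def test_spectral_energy_concentrated_above_50_hz(self):
        w = synth_breath_noise(10.0, 3.0, 8000, seed=3)
        f, pxx = sg.periodogram(w.samples, fs=8000)
        assert pxx[f < 50].sum() / pxx.sum() < 0.05


class TestRenderRecording:
    def test_empty_event_list_returns_noise(self):
        noise = synth_breath_noise(3.0, 3.0, 8000, seed=1)
        mix, truth = render_recording([], noise)
        np.testing.assert_array_equal(mix.samples, noise.samples)
        assert truth == []

    def test_truth_events_passed_through(self):
        noise = synth_breath_noise(8.0, 3.0, 44100, seed=1)
        ev = AcousticEvent("crackle", 5.0, 0.02,
                           CrackleParams(onset_s=5.0, oscillation_freq_hz=400,
                                         total_duration_ms=20))
        _, truth = render_recording([ev], noise)
        assert truth == [ev]

    def test_snr_realized_within_one_db(self):
        noise = synth_breath_noise(8.0, 3.0, 8000, seed=2)
        ev = AcousticEvent("wheeze", 3.0, 0.5,
                           WheezeParams(onset_s=3.0, dominant_freq_hz=400,
                                        duration_ms=500))
        mix, _ = render_recording([ev], noise, snr_db=20.0)
        i0, i1 = int(3.0 * 8000), int(3.5 * 8000)
        event_part = mix.samples[i0:i1] - noise.samples[i0:i1]
        ratio = np.mean(event_part**2) / np.mean(noise.samples[i0:i1] ** 2)
        assert 10 * np.log10(ratio) == pytest.approx(20.0, abs=1.0)

    def test_event_past_end_rejected(self):
        noise = synth_breath_noise(1.0, 3.0, 8000, seed=1)
        ev = AcousticEvent("wheeze", 0.9, 0.5,
                           WheezeParams(onset_s=0.9, dominant_freq_hz=300,
                                        duration_ms=500))
        with pytest.raises(InvalidParameterError):
            render_recording([ev], noise)


class TestDeviceProfile:
    def test_identity_profile_roundtrip(self):
        w = synth_breath_noise(1.0, 3.0, 8000, seed=5)
        out = apply_device_profile(w, DeviceProfile("id", 8000, "continuous"))
        np.testing.assert_allclose(out.samples, w.samples)

    @given(st.integers(0, 2**32 - 1))
    def test_16bit_quantization_error_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, size=256)
        q = quantize(x, 16)
        assert np.max(np.abs(q - x)) <= 2**-15
        # quantized values sit on the 2^-15 grid
        np.testing.assert_allclose(q * 32768, np.round(q * 32768), atol=1e-9)

    def test_downsampling_suppresses_tone_above_new_nyquist(self):
        t = np.arange(int(44100 * 1.0)) / 44100
        tone = Waveform(0.5 * np.sin(2 * np.pi * 2500 * t), 44100)
        out = apply_device_profile(tone, LOFI_PROFILE)
        assert out.sample_rate_hz == 4000
        rms_in = np.sqrt(np.mean(tone.samples**2))
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert rms_out < 0.01 * rms_in

    def test_upsampling_rejected(self):
        w = synth_breath_noise(0.5, 3.0, 4000.0, seed=1)
        with pytest.raises(InvalidParameterError):
            apply_device_profile(w, HIFI_PROFILE)


class TestCohortGeneration:
    def test_single_normal_participant_is_event_free(self):
        cfg = CohortConfig(group_sizes={"normal": 1})
        cohort = generate_cohort(cfg, seed=3)
        assert len(cohort.manifest) == 8  # 4 quadrants x 2 devices
        assert all(not r.truth_events for r in cohort.records.values())

    def test_zero_cohort_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortConfig(group_sizes={"normal": 0})

    def test_drawn_events_satisfy_morphology_criteria(self):
        cohort = generate_cohort(CohortConfig(), seed=11)
        n_crackles = n_wheezes = 0
        for rec in cohort.records.values():
            for ev in rec.truth_events:
                if ev.kind == "crackle":
                    n_crackles += 1
                    assert ev.params.two_cycle_duration_ms < 20
                    assert ev.params.total_duration_ms < 25
                else:
                    n_wheezes += 1
                    assert ev.params.duration_ms > 25
                    assert ev.params.dominant_freq_hz > 100
        assert n_crackles > 0 and n_wheezes > 0

    def test_group_event_consistency(self):
        cohort = generate_cohort(CohortConfig(), seed=11)
        for rec in cohort.records.values():
            kinds = {e.kind for e in rec.truth_events}
            if rec.group in ("normal", "cf_clear"):
                assert not kinds
            elif rec.group == "wheeze_only":
                assert "crackle" not in kinds

    def test_manifest_accounting_matches_config(self):
        cfg = tiny_config().cohort
        cohort = generate_cohort(cfg, seed=0)
        n = sum(cfg.group_sizes.values()) * len(cfg.quadrants) * len(cfg.devices)
        assert len(cohort.manifest) == n
        assert (~cohort.manifest["excluded"]).sum() == \
            n - cfg.exclusions_per_device * len(cfg.devices)
        excl = cohort.manifest[cohort.manifest["excluded"]]
        assert (excl["exclusion_reason"] != "").all()

    def test_wav_output_bit_identical_across_runs(self, tmp_path):
        cfg = tiny_config().cohort
        generate_cohort(cfg, seed=4, out_dir=tmp_path / "a")
        generate_cohort(cfg, seed=4, out_dir=tmp_path / "b")
        wavs = sorted((tmp_path / "a" / "audio").glob("*.wav"))
        assert wavs
        for wav in wavs:
            other = tmp_path / "b" / "audio" / wav.name
            assert wav.read_bytes() == other.read_bytes()
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()
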