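"""Call-parameter measurement: spectra, envelopes, notes and the six
Table-style parameters, checked against closed forms and generator truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from acousticniche import (
    MeasurementInconsistencyError,
    NoEnergyError,
    SyntheticCallSpec,
    TooShortError,
    Waveform,
    amplitude_envelope,
    dominant_frequency,
    duration90,
    energy_percentile_frequency,
    gen_call_audio,
    measure_call,
    note_rate,
    peak_time_relative,
    power_spectrum,
    segment_notes,
)
from acousticniche.calls import BIN_WIDTH_HZ, PowerSpectrum, call_bounds_from_envelope

SR = 44100


def sine(freq, duration=1.0, amp=1.0, sr=SR):
    t = np.arange(int(duration * sr)) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t), sr)


class TestPowerSpectrum:
    def test_pure_tone_has_single_dominant_bin(self):
        spec = power_spectrum(sine(1000.0))
        peak = spec.freqs[np.argmax(spec.power)]
        assert abs(peak - 1000.0) <= BIN_WIDTH_HZ

    def test_silent_waveform_signals_no_energy(self):
        with pytest.raises(NoEnergyError):
            power_spectrum(Waveform(np.zeros(SR), SR))

    def test_too_short_waveform_signals_length_error(self):
        with pytest.raises(TooShortError):
            power_spectrum(Waveform(np.ones(100), SR))

    def test_two_tone_energy_ordering_matches_direct_dft(self):
        # 1 kHz at amplitude 1 must beat 3 kHz at amplitude 0.5, and the
        # ordering must agree with a plain rFFT periodogram oracle
        w = Waveform(sine(1000).samples + 0.5 * sine(3000).samples, SR)
        spec = power_spectrum(w)

        def bin_energy(freqs, power, f):
            return power[np.argmin(np.abs(freqs - f))]

        assert bin_energy(spec.freqs, spec.power, 1000) > bin_energy(
            spec.freqs, spec.power, 3000
        )
        # independent oracle: direct DFT of the whole signal
        mags = np.abs(np.fft.rfft(w.samples)) ** 2
        ofreqs = np.fft.rfftfreq(len(w.samples), 1 / SR)
        assert bin_energy(ofreqs, mags, 1000) > bin_energy(ofreqs, mags, 3000)
        assert ofreqs[np.argmax(mags)] == pytest.approx(1000.0, abs=2.0)

    def test_energies_nonnegative_and_positive_total(self):
        spec = power_spectrum(sine(700.0))
        assert np.all(spec.power >= 0) and spec.total > 0


class TestDominantFrequency:
    def test_pure_tone_within_one_bin(self):
        dom = dominant_frequency(power_spectrum(sine(1000.0)))
        assert abs(10**dom - 1000.0) <= BIN_WIDTH_HZ

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.arange(30) * BIN_WIDTH_HZ
        power = np.zeros(30)
        power[10] = power[20] = 1.0
        assert dominant_frequency(PowerSpectrum(freqs, power)) == pytest.approx(
            np.log10(freqs[10])
        )

    def test_flat_zero_spectrum_signals_no_energy(self):
        with pytest.raises(NoEnergyError):
            dominant_frequency(PowerSpectrum(np.arange(10.0) + 1, np.zeros(10)))

    def test_two_tone_dominant_is_louder_tone(self):
        w = Waveform(sine(1000).samples + 0.5 * sine(3000).samples, SR)
        dom = dominant_frequency(power_spectrum(w))
        assert abs(10**dom - 1000.0) <= BIN_WIDTH_HZ


class TestPercentileFrequency:
    def test_single_tone_percentiles_collapse_to_tone_bin(self):
        # bin-centred tone so Hann leakage stays within adjacent bins
        f0 = 23 * BIN_WIDTH_HZ
        spec = power_spectrum(sine(f0))
        f5 = energy_percentile_frequency(spec, 0.05)
        f95 = energy_percentile_frequency(spec, 0.95)
        assert abs(10**f5 - f0) <= BIN_WIDTH_HZ * (1 + 1e-9)
        assert abs(10**f95 - f0) <= BIN_WIDTH_HZ * (1 + 1e-9)

    def test_uniform_spectrum_cumulative_hand_oracle(self):
        # uniform energy over bins 1..100: 5% of total is reached at bin 5
        freqs = np.arange(101.0) * BIN_WIDTH_HZ
        power = np.r_[0.0, np.ones(100)]
        f = energy_percentile_frequency(PowerSpectrum(freqs, power), 0.05)
        assert f == pytest.approx(np.log10(freqs[5]))

    def test_zero_energy_raises(self):
        with pytest.raises(NoEnergyError):
            energy_percentile_frequency(
                PowerSpectrum(np.arange(5.0) + 1, np.zeros(5)), 0.5
            )

    @given(
        power=st.lists(st.floats(0, 1e6), min_size=3, max_size=64).filter(
            lambda p: sum(p) > 0
        ),
        q1=st.floats(0.01, 0.98),
        q2=st.floats(0.01, 0.98),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_q(self, power, q1, q2):
        q1, q2 = sorted((q1, q2))
        freqs = (np.arange(len(power)) + 1.0) * BIN_WIDTH_HZ
        spec = PowerSpectrum(freqs, np.array(power))
        assert energy_percentile_frequency(spec, q2) >= energy_percentile_frequency(
            spec, q1
        )


class TestEnvelope:
    def test_constant_tone_envelope_flat(self):
        env = amplitude_envelope(sine(1000.0))
        core = env[2000:-2000]
        assert np.std(core) / np.mean(core) < 0.05

    def test_silence_gives_zero_envelope(self):
        env = amplitude_envelope(Waveform(np.zeros(1000), SR))
        assert np.all(env == 0)

    def test_ramped_tone_envelope_monotone(self):
        w = sine(1000.0)
        ramp = np.linspace(0.0, 1.0, len(w.samples))
        env = amplitude_envelope(Waveform(w.samples * ramp, SR))
        # compare at coarse grid to avoid within-cycle ripple
        coarse = env[:: SR // 100][1:-1]
        rho, _ = spearmanr(np.arange(len(coarse)), coarse)
        assert rho > 0.99


class TestDuration90:
    def test_rectangular_burst_closed_form(self):
        env = np.zeros(2 * SR)
        env[: SR] = 1.0  # 1 s rectangular burst
        assert duration90(env, SR) == pytest.approx(0.90, abs=2 / SR)

    def test_impulse_is_essentially_instantaneous(self):
        w = Waveform(np.r_[np.zeros(1000), 1.0, np.zeros(1000)], SR)
        env = amplitude_envelope(w)  # 5 ms smoothing frame
        assert duration90(env, SR) <= 2 * 0.005

    def test_two_separated_bursts_span_both(self):
        env = np.zeros(SR)
        env[: int(0.1 * SR)] = 1.0
        env[int(0.9 * SR) :] = 1.0
        # cumulative-energy oracle: each burst holds half the energy, so the
        # 5% instant is at 0.01 s and the 95% instant at 0.99 s -> 0.98 s,
        # spanning the silent middle rather than a single burst
        assert duration90(env, SR) == pytest.approx(0.98, abs=0.001)
        assert duration90(env, SR) > 0.8

    def test_zero_energy_raises(self):
        with pytest.raises(NoEnergyError):
            duration90(np.zeros(100), SR)


class TestPeakTime:
    def test_symmetric_triangle_peaks_at_half(self):
        env = np.r_[np.linspace(0, 1, 500), np.linspace(1, 0, 500)[1:]]
        assert peak_time_relative(env, (0, len(env) - 1)) == pytest.approx(
            0.5, abs=1 / len(env)
        )

    def test_decaying_envelope_peaks_at_zero(self):
        env = np.linspace(1, 0, 1000)
        assert peak_time_relative(env, (0, 999)) == 0.0

    def test_constructed_peak_at_three_quarters(self):
        n = 1000
        env = np.minimum(np.linspace(0, 4 / 3, n), np.linspace(4, 0, n))
        ipk = int(np.argmax(env))
        assert peak_time_relative(env, (0, n - 1)) == pytest.approx(
            0.75, abs=2 / n
        )
        assert abs(ipk / (n - 1) - 0.75) < 0.01

    def test_degenerate_bounds_error(self):
        with pytest.raises(ValueError):
            peak_time_relative(np.ones(10), (5, 5))


class TestNotes:
    @staticmethod
    def burst_train(n_bursts, burst_s, gap_s, sr=SR):
        burst = np.ones(int(burst_s * sr))
        gap = np.zeros(int(gap_s * sr))
        parts = []
        for i in range(n_bursts):
            parts.append(burst)
            if i < n_bursts - 1:
                parts.append(gap)
        return np.concatenate(parts)

    def test_three_separated_bursts_give_three_notes(self):
        env = self.burst_train(3, 0.05, 0.05)
        assert len(segment_notes(env, SR)) == 3

    def test_continuous_tone_is_one_note(self):
        assert len(segment_notes(np.ones(SR), SR)) == 1

    def test_short_gap_merges_notes(self):
        # 5 bursts, four 20 ms gaps, one of them shrunk below min_gap
        sr = SR
        burst = np.ones(int(0.05 * sr))
        wide = np.zeros(int(0.020 * sr))
        narrow = np.zeros(int(0.005 * sr))
        env = np.concatenate(
            [burst, wide, burst, narrow, burst, wide, burst, wide, burst]
        )
        assert len(segment_notes(env, sr, min_gap_s=0.010)) == 4

    def test_silence_yields_no_notes(self):
        assert segment_notes(np.zeros(1000), SR) == []

    def test_note_rate_definition(self):
        notes = [(0.0, 0.1)] * 5
        assert note_rate(notes, 1.0) == 5.0
        assert note_rate(notes[:1], 2.0) == 0.5
        with pytest.raises(ValueError):
            note_rate(notes, 0.0)

    def test_pulse_train_rate_recovered(self):
        spec = SyntheticCallSpec(pulse_rate=12.0, n_notes=18, note_duration=0.04)
        w, truth = gen_call_audio(spec)
        env = amplitude_envelope(w)
        i0, i1 = call_bounds_from_envelope(env)
        notes = segment_notes(env[i0 : i1 + 1], SR)
        rate = note_rate(notes, (i1 - i0 + 1) / SR)
        assert rate == pytest.approx(truth.note_rate, abs=1 / 1.5)


class TestMeasureCall:
    def test_synthetic_call_ground_truth(self):
        spec = SyntheticCallSpec(
            carrier_hz=2000.0, pulse_rate=5.0, n_notes=5, note_duration=0.1,
            peak_position=0.5,
        )
        w, truth = gen_call_audio(spec)
        p = measure_call(w, "sp")
        assert abs(10**p.dom_freq - 2000.0) <= BIN_WIDTH_HZ
        assert p.note_rate == pytest.approx(truth.note_rate, rel=0.10)
        assert p.peak_time_rel == pytest.approx(truth.peak_time_rel, abs=0.05)

    def test_pure_tone_rectangular_envelope_closed_forms(self):
        f0 = 23 * BIN_WIDTH_HZ  # bin-centred carrier
        w = sine(f0, duration=1.0)
        p = measure_call(w, "tone")
        for f in (p.freq5, p.freq95, p.dom_freq):
            assert abs(10**f - f0) <= BIN_WIDTH_HZ * (1 + 1e-9)
        assert p.dur90 == pytest.approx(0.9, abs=0.02)

    def test_silent_input_raises(self):
        with pytest.raises(NoEnergyError):
            measure_call(Waveform(np.zeros(SR), SR), "quiet")

    @pytest.mark.parametrize("c", [2.0, 0.25])
    def test_amplitude_scaling_invariance(self, c):
        w, _ = gen_call_audio(SyntheticCallSpec(peak_position=0.3))
        a = measure_call(w, "sp")
        b = measure_call(w.scaled(c), "sp")
        assert (a.freq5, a.freq95, a.dom_freq) == (b.freq5, b.freq95, b.dom_freq)
        assert (a.dur90, a.peak_time_rel, a.note_rate) == (
            b.dur90, b.peak_time_rel, b.note_rate,
        )

    def test_measurement_is_deterministic(self):
        w, _ = gen_call_audio(SyntheticCallSpec())
        assert measure_call(w, "sp") == measure_call(w, "sp")

    def test_invariant_violation_is_diagnosed(self):
        from acousticniche.calls import CallParams

        bad = CallParams("sp", freq5=3.5, freq95=3.0, dom_freq=3.2,
                         dur90=1.0, peak_time_rel=0.5, note_rate=2.0)
        with pytest.raises(MeasurementInconsistencyError, match="freq5"):
            bad.validate()
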