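"""Band filtering, template matching, detection and PPG synchronisation."""

import numpy as np
import pytest
from scipy import signal as sps

from jvpradar import (
    DisplacementSignal,
    DisplacementTrajectory,
    FilterSpec,
    JVPWaveformSpec,
    PulseTemplate,
    apply_filters,
    common_frequency,
    detect_pulses,
    normalized_db_spectrum,
    select_reference_pulse,
    synth_jvp_trajectory,
    synth_ppg,
)
from jvpradar.errors import (
    InsufficientCyclesError,
    InsufficientLengthError,
)

FS = 250.0


def make_signal(values, fs=FS):
    return DisplacementSignal(np.asarray(values, float), fs, 4.93e-3)


def cascade_response_db(spec, freq):
    """Oracle: steady-state gain of the designed cascade at a frequency."""
    w, h1 = sps.freqz(spec.design_bandpass(), worN=[freq], fs=spec.sample_rate)
    _, h2 = sps.freqz(spec.design_bandstop(), worN=[freq], fs=spec.sample_rate)
    return 20 * np.log10(np.abs(h1[0] * h2[0]) + 1e-300)


class TestFilters:
    def test_combined_group_delay_is_765_samples(self):
        assert FilterSpec().group_delay == 765

    def test_passband_tone_preserved_and_stopband_attenuated(self):
        spec = FilterSpec()
        assert cascade_response_db(spec, 2.0) > -1.0       # passband
        assert cascade_response_db(spec, 0.2) < -40.0      # below band
        assert cascade_response_db(spec, 1.0) < -30.0      # notch centre

    def test_trim_bounds_are_765_each_end(self):
        n = 4000
        sig = make_signal(np.sin(2 * np.pi * 2.0 * np.arange(n) / FS) * 1e-4)
        _, bounds = apply_filters(sig)
        assert bounds == (765, n - 765)

    def test_steady_state_tone_amplitudes_match_frequency_response(self):
        # full settling needs taps_bp + taps_bs - 2 = 1530 samples, beyond
        # the 765-sample group-delay trim
        spec = FilterSpec()
        t = np.arange(8000) / FS
        settle = spec.bandpass_taps + spec.bandstop_taps - 2
        for freq in (2.0, 1.0):
            sig = make_signal(1e-4 * np.sin(2 * np.pi * freq * t))
            filtered, _ = apply_filters(sig, spec)
            interior = filtered.values[settle:]
            gain_db = 20 * np.log10(
                (interior.max() - interior.min()) / 2 / 1e-4 + 1e-300)
            assert gain_db == pytest.approx(cascade_response_db(spec, freq), abs=1.5)

    def test_too_short_signal_names_minimum(self):
        sig = make_signal(np.zeros(1000))
        with pytest.raises(InsufficientLengthError, match="1531"):
            apply_filters(sig)

    def test_linearity_of_cascade(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(3000) * 1e-4
        b = rng.standard_normal(3000) * 1e-4
        fa, _ = apply_filters(make_signal(a))
        fb, _ = apply_filters(make_signal(b))
        fab, _ = apply_filters(make_signal(a + b))
        assert np.allclose(fab.values, fa.values + fb.values, atol=1e-15)

    def test_even_tap_count_rejected(self):
        with pytest.raises(Exception):
            FilterSpec(bandpass_taps=1020)

    def test_notched_fundamental_preserves_harmonics(self):
        # cardiac fundamental inside the 0.9-1.1 Hz notch loses power but
        # harmonic content in 1.8-4 Hz survives the cascade
        spec_wave = JVPWaveformSpec(cardiac_rate=1.0, respiratory_amplitude=0,
                                    noise_sd=0)
        traj = synth_jvp_trajectory(spec_wave, 40, FS, seed=0)
        filtered, (lo, hi) = apply_filters(make_signal(traj.values))

        def band_power(x, f_lo, f_hi):
            f, p = sps.periodogram(x, fs=FS)
            return p[(f >= f_lo) & (f <= f_hi)].sum()

        raw = traj.values[lo:hi]
        out = filtered.values[lo:hi]
        assert band_power(out, 0.9, 1.1) < 0.01 * band_power(raw, 0.9, 1.1)
        assert band_power(out, 1.8, 4.0) > 0.5 * band_power(raw, 1.8, 4.0)


class TestReferencePulse:
    def _periodic_signal(self, period=200, n_cycles=8, fs=FS):
        one = np.sin(2 * np.pi * np.arange(period) / period) + \
            0.3 * np.sin(4 * np.pi * np.arange(period) / period)
        return make_signal(np.tile(one, n_cycles), fs)

    def test_perfectly_periodic_returns_lowest_index_cycle(self):
        sig = self._periodic_signal()
        tpl = select_reference_pulse(sig, (0, len(sig.values)),
                                     cardiac_rate_hint=FS / 200)
        assert tpl.origin_index == 0
        assert tpl.cycle_length == 200

    def test_corrupted_cycle_never_selected(self):
        sig = self._periodic_signal(n_cycles=8)
        values = sig.values.copy()
        values[3 * 200:4 * 200] += np.random.default_rng(1).standard_normal(200) * 2
        sig = make_signal(values)
        tpl = select_reference_pulse(sig, (0, len(values)),
                                     cardiac_rate_hint=FS / 200)
        assert tpl.origin_index // 200 != 3

    def test_template_length_matches_cardiac_period(self):
        traj = synth_jvp_trajectory(JVPWaveformSpec(), 30, FS, seed=2)
        filtered, bounds = apply_filters(make_signal(traj.values))
        tpl = select_reference_pulse(filtered, bounds)
        assert tpl.cycle_length == pytest.approx(FS / 1.13, rel=0.10)

    def test_too_few_cycles_rejected(self):
        sig = self._periodic_signal(n_cycles=3)
        with pytest.raises(InsufficientCyclesError):
            select_reference_pulse(sig, (0, len(sig.values)),
                                   cardiac_rate_hint=FS / 200)


class TestDetectPulses:
    def _template(self, period=150):
        u = np.arange(period) / period
        pulse = np.exp(-0.5 * ((u - 0.3) / 0.08) ** 2) - \
            0.7 * np.exp(-0.5 * ((u - 0.6) / 0.1) ** 2)
        return PulseTemplate(pulse, period, 0)

    def test_tiled_template_all_detected_with_unit_correlation(self):
        tpl = self._template()
        sig = make_signal(np.tile(tpl.samples, 10))
        out = detect_pulses(sig, tpl, threshold=0.8)
        assert out.n_pulses == 10
        assert np.allclose(out.correlations, 1.0, atol=1e-9)

    def test_threshold_above_one_detects_nothing(self):
        tpl = self._template()
        sig = make_signal(np.tile(tpl.samples, 5))
        assert detect_pulses(sig, tpl, threshold=1.01).n_pulses == 0

    def test_detection_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        tpl = self._template()
        sig = make_signal(np.tile(tpl.samples, 12)
                          + 0.3 * rng.standard_normal(12 * 150))
        counts = [detect_pulses(sig, tpl, threshold=th).n_pulses
                  for th in (0.3, 0.5, 0.7, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_noisy_jvp_recall_and_trim_respect(self):
        spec = JVPWaveformSpec(respiratory_amplitude=0)
        traj = synth_jvp_trajectory(spec, 40, FS, seed=4)
        clean = synth_jvp_trajectory(
            JVPWaveformSpec(respiratory_amplitude=0, noise_sd=0), 40, FS, seed=0)
        # 10 dB SNR additive noise on top of the waveform
        p_sig = np.var(clean.values)
        noise = np.sqrt(p_sig / 10) * np.random.default_rng(5).standard_normal(
            len(traj.values))
        sig = make_signal(clean.values + noise)
        filtered, bounds = apply_filters(sig)
        tpl = select_reference_pulse(filtered, bounds, cardiac_rate_hint=1.13)
        out = detect_pulses(filtered, tpl, threshold=0.8, trim_bounds=bounds)
        lo, hi = bounds
        n_true = (hi - lo) // tpl.cycle_length
        assert out.n_pulses >= 0.9 * n_true
        assert np.all(out.starts >= lo)
        assert np.all(out.starts + tpl.cycle_length <= hi)

    def test_accepted_pulses_essentially_non_overlapping(self):
        tpl = self._template()
        rng = np.random.default_rng(6)
        sig = make_signal(np.tile(tpl.samples, 15)
                          + 0.1 * rng.standard_normal(15 * 150))
        out = detect_pulses(sig, tpl, threshold=0.5)
        if out.n_pulses > 1:
            assert np.diff(np.sort(out.starts)).min() >= tpl.cycle_length * 0.95

    def test_peaks_marked_at_segment_maxima(self):
        tpl = self._template()
        sig = make_signal(np.tile(tpl.samples, 6))
        out = detect_pulses(sig, tpl, threshold=0.9)
        for s, pk in zip(out.starts, out.peak_indices):
            seg = sig.values[s:s + tpl.cycle_length]
            assert sig.values[pk] == seg.max()


class TestCommonFrequency:
    def _jvp_displacement(self, rate, seed, duration=30):
        traj = synth_jvp_trajectory(JVPWaveformSpec(cardiac_rate=rate), duration,
                                    FS, seed=seed)
        return make_signal(traj.values)

    @pytest.mark.parametrize("rate", [1.13, 1.5])
    def test_recovers_shared_cardiac_rate(self, rate):
        jvp = self._jvp_displacement(rate, seed=7)
        ppg = synth_ppg(rate, 30, seed=8)
        res = common_frequency(jvp, ppg)
        assert res.frequency_hz == pytest.approx(rate, abs=0.05)
        assert not res.low_confidence

    def test_uncorrelated_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(9)
        jvp = make_signal(rng.standard_normal(30 * int(FS)) * 1e-4)
        ppg = DisplacementTrajectory(273.1, rng.standard_normal(int(30 * 273.1)))
        res = common_frequency(jvp, ppg)
        assert res.low_confidence

    def test_short_record_rejected(self):
        jvp = self._jvp_displacement(1.13, seed=0, duration=30)
        ppg = synth_ppg(1.13, 10, seed=0)
        with pytest.raises(InsufficientLengthError):
            common_frequency(jvp, ppg)


class TestNormalizedSpectrum:
    def test_maximum_is_zero_db(self):
        rng = np.random.default_rng(10)
        _, db = normalized_db_spectrum(rng.standard_normal(1000), FS)
        assert db.max() == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(512)
        _, a = normalized_db_spectrum(x, FS)
        _, b = normalized_db_spectrum(7.3 * x, FS)
        assert np.allclose(a, b)

    def test_pure_tone_line_and_sidelobe_floor(self):
        # integer number of cycles: rectangular-window sidelobes are exact
        # Dirichlet nulls, so everything off the line sits far below 0 dB
        n = 1000
        t = np.arange(n) / FS
        f, db = normalized_db_spectrum(np.sin(2 * np.pi * 10.0 * t), FS)
        on = np.argmin(np.abs(f - 10.0))
        assert db[on] == pytest.approx(0.0, abs=1e-6)
        mask = np.ones(len(db), bool)
        mask[on] = False
        assert db[mask].max() < -40.0
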