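"""EEG preprocessing chain and delta-power computation."""
import numpy as np
import pytest

import neosleep as ns
from neosleep.eeg import DEFAULT_BIPOLAR_PAIRS

from .conftest import SUITE_SEED

FS = 250.0


def white_eeg(rng, n_channels=4, seconds=60.0, labels=None):
    n = int(seconds * FS)
    labels = labels or [f"ch{i}" for i in range(n_channels)]
    return ns.EEGRecording(rng.standard_normal((n_channels, n)), labels, FS)


class TestWelchSpectrum:
    def test_white_noise_parseval_and_flatness(self):
        """PSD of unit-variance white noise integrates to ~1 and is flat."""
        rng = np.random.default_rng(SUITE_SEED)
        eeg = white_eeg(rng, n_channels=1, seconds=120.0)
        ps = ns.welch_spectrum(eeg)
        assert ps.freqs[1] - ps.freqs[0] == pytest.approx(0.5)
        total = np.trapezoid(ps.power[0], ps.freqs)
        assert total == pytest.approx(1.0, rel=0.05)
        interior = ps.power[0][(ps.freqs > 1) & (ps.freqs < 120)]
        assert interior.max() / interior.min() < 3.0

    def test_sinusoid_peaks_at_its_bin(self):
        t = np.arange(0, 60, 1 / FS)
        eeg = ns.EEGRecording(np.sin(2 * np.pi * 2.0 * t)[None, :], ["c"], FS)
        ps = ns.welch_spectrum(eeg)
        assert ps.freqs[np.argmax(ps.power[0])] == pytest.approx(2.0)

    def test_two_equal_sinusoids_equal_peaks(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 10.0 * t)
        ps = ns.welch_spectrum(ns.EEGRecording(x[None, :], ["c"], FS))
        p2 = ps.power[0][ps.freqs == 2.0][0]
        p10 = ps.power[0][ps.freqs == 10.0][0]
        assert p2 == pytest.approx(p10, rel=0.01)

    def test_short_record_errors(self):
        with pytest.raises(ValueError, match="segment"):
            ns.welch_spectrum(ns.EEGRecording(np.zeros((1, 100)), ["c"], FS))


class TestDeltaPower:
    def _ps(self, band_powers, fill=1.0):
        freqs = np.arange(0, 30.5, 0.5)
        power = np.full((1, freqs.size), fill)
        band = (freqs >= 0.5) & (freqs <= 4.0)
        power[0, band] = band_powers
        return ns.PowerSpectrum(freqs, power, ["c"])

    def test_unit_power_gives_zero(self):
        assert ns.delta_power(self._ps(1.0))[0] == 0.0

    def test_e_squared_gives_two(self):
        assert ns.delta_power(self._ps(np.e ** 2))[0] == pytest.approx(2.0)

    def test_median_of_logs_on_geometric_bins(self):
        vals = np.array([1, 2, 4, 8, 16, 32, 64, 128], dtype=float)
        expected = (np.log(8) + np.log(16)) / 2
        assert ns.delta_power(self._ps(vals))[0] == pytest.approx(expected)

    def test_band_has_eight_bins_at_half_hz(self):
        freqs = np.arange(0, 30.5, 0.5)
        assert ((freqs >= 0.5) & (freqs <= 4.0)).sum() == 8

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            ns.delta_power(self._ps(0.0))


class TestGlobalAverage:
    def test_identical_channels_become_zero(self):
        x = np.random.default_rng(SUITE_SEED).standard_normal(2500)
        eeg = ns.EEGRecording(np.vstack([x, x]), ["a", "b"], FS)
        out = ns.subtract_global_average(eeg)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_zero_mean_pair_unchanged(self):
        x = np.random.default_rng(SUITE_SEED).standard_normal(2500)
        eeg = ns.EEGRecording(np.vstack([x, -x]), ["a", "b"], FS)
        out = ns.subtract_global_average(eeg)
        np.testing.assert_allclose(out.data, eeg.data, atol=1e-10)

    def test_equals_time_domain_car_and_zero_mean(self):
        """Frequency-domain subtraction == time-domain common-average
        referencing to 1e-10 relative, and the channel mean vanishes."""
        rng = np.random.default_rng(SUITE_SEED)
        eeg = white_eeg(rng, n_channels=4, seconds=10.0)
        out = ns.subtract_global_average(eeg)
        car = eeg.data - eeg.data.mean(axis=0, keepdims=True)
        scale = np.abs(car).max()
        assert np.max(np.abs(out.data - car)) / scale < 1e-10
        assert np.max(np.abs(out.data.mean(axis=0))) / scale < 1e-10

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ns.subtract_global_average(ns.EEGRecording(np.zeros((1, 100)), ["a"], FS))


class TestBipolarMontage:
    def test_identical_electrodes_cancel(self):
        x = np.random.default_rng(0).standard_normal(500)
        eeg = ns.EEGRecording(np.vstack([x, x]), ["Fp1", "T3"], FS)
        out = ns.to_bipolar(eeg, ns.MontageMap(pairs=(("Fp1", "T3"),)))
        np.testing.assert_allclose(out.data[0], 0.0)

    def test_difference_against_flat_reference(self):
        t = np.arange(500) / FS
        eeg = ns.EEGRecording(np.vstack([np.sin(t), np.zeros(500)]),
                              ["Fp1", "T3"], FS)
        out = ns.to_bipolar(eeg, ns.MontageMap(pairs=(("Fp1", "T3"),)))
        np.testing.assert_allclose(out.data[0], np.sin(t))
        assert out.channel_labels == ["Fp1-T3"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        eeg = ns.EEGRecording(rng.standard_normal((2, 500)), ["Fp1", "T3"], FS)
        fwd = ns.to_bipolar(eeg, ns.MontageMap(pairs=(("Fp1", "T3"),)))
        rev = ns.to_bipolar(eeg, ns.MontageMap(pairs=(("T3", "Fp1"),)))
        np.testing.assert_allclose(fwd.data[0], -rev.data[0])

    def test_full_default_montage(self):
        from neosleep.synthetic import MONOPOLAR_ELECTRODES

        rng = np.random.default_rng(2)
        eeg = ns.EEGRecording(rng.standard_normal((11, 500)),
                              list(MONOPOLAR_ELECTRODES), FS)
        out = ns.to_bipolar(eeg)
        assert out.n_channels == 14
        assert out.channel_labels == [f"{a}-{c}" for a, c in DEFAULT_BIPOLAR_PAIRS]

    def test_unresolvable_label_named_in_error(self):
        eeg = ns.EEGRecording(np.zeros((2, 100)), ["Fp1", "T3"], FS)
        with pytest.raises(KeyError, match="Oz"):
            ns.to_bipolar(eeg, ns.MontageMap(pairs=(("Fp1", "Oz"),)))

    def test_montage_config_parsing(self):
        m = ns.MontageMap.from_config_text(
            "# comment\nPAIR Fp1 T3\nPAIR T3 O1\nMAP Fp1 0\nMAP T3 5\nMAP O1 9\n")
        assert m.pairs == (("Fp1", "T3"), ("T3", "O1"))
        assert m.electrode_lookup["T3"] == 5


class TestEcgInterference:
    def _ecg(self, rng, seconds=60.0):
        from neosleep.synthetic import gen_ecg

        beats = np.arange(0.5, seconds - 0.5, 0.4)
        return gen_ecg(beats, fs=FS, duration=seconds, snr_db=20.0, rng=rng)

    def test_pure_copy_removed(self):
        rng = np.random.default_rng(SUITE_SEED)
        ecg = self._ecg(rng)
        eeg = ns.EEGRecording(ecg.samples[None, :].copy(), ["c"], FS)
        out = ns.attenuate_ecg_interference(eeg, ecg)
        assert np.mean(out.data ** 2) < 0.01 * np.mean(eeg.data ** 2)

    def test_independent_noise_untouched(self):
        rng = np.random.default_rng(SUITE_SEED + 1)
        ecg = self._ecg(rng)
        eeg = ns.EEGRecording(rng.standard_normal((2, ecg.samples.size)),
                              ["a", "b"], FS)
        out = ns.attenuate_ecg_interference(eeg, ecg)
        for ch in range(2):
            before = np.mean(eeg.data[ch] ** 2)
            after = np.mean(out.data[ch] ** 2)
            assert abs(after - before) / before < 0.05

    def test_residual_orthogonal_to_ecg(self):
        rng = np.random.default_rng(SUITE_SEED + 2)
        ecg = self._ecg(rng, seconds=180.0)
        brain = rng.standard_normal(ecg.samples.size)
        eeg = ns.EEGRecording((brain + 0.5 * ecg.samples)[None, :], ["c"], FS)
        out = ns.attenuate_ecg_interference(eeg, ecg)
        r = np.corrcoef(out.data[0], ecg.samples)[0, 1]
        assert abs(r) < 0.05

    def test_misaligned_lengths_rejected(self):
        rng = np.random.default_rng(0)
        ecg = self._ecg(rng)
        eeg = ns.EEGRecording(np.zeros((1, 1000)), ["c"], FS)
        with pytest.raises(ValueError, match="align"):
            ns.attenuate_ecg_interference(eeg, ecg)


class TestCleanSegmentSelection:
    def test_burst_excluded(self):
        rng = np.random.default_rng(SUITE_SEED)
        eeg = white_eeg(rng, n_channels=2, seconds=240.0)
        burst = slice(int(100 * FS), int(110 * FS))
        eeg.data[:, burst] += 40.0
        out = ns.select_clean_segment(eeg, duration=120.0)
        # locate the chosen window within the record and check it avoids the burst
        assert out.n_samples == int(120 * FS)
        assert np.abs(out.data).max() < 30.0

    def test_clean_record_returns_first_window(self):
        rng = np.random.default_rng(SUITE_SEED)
        eeg = ns.EEGRecording(np.ones((1, int(240 * FS))), ["c"], FS)
        out = ns.select_clean_segment(eeg, duration=120.0)
        np.testing.assert_array_equal(out.data, eeg.data[:, : int(120 * FS)])

    def test_exact_length_returned_whole(self):
        rng = np.random.default_rng(SUITE_SEED)
        eeg = white_eeg(rng, n_channels=1, seconds=120.0)
        out = ns.select_clean_segment(eeg, duration=120.0)
        np.testing.assert_array_equal(out.data, eeg.data)

    def test_too_short_errors(self):
        eeg = ns.EEGRecording(np.zeros((1, int(60 * FS))), ["c"], FS)
        with pytest.raises(ValueError, match="shorter"):
            ns.select_clean_segment(eeg, duration=120.0)
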