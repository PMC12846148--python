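import logging

import numpy as np
import pytest

from conftest import FS, WINDOW_SAMPLES, make_epoch, sine_epoch
from swblab.exceptions import DegenerateSignalError, ParameterError
from swblab.io_core import BANDS, N_CHANNELS, Recording, band
from swblab.spectral_features import (
    band_power,
    bandpass,
    compute_faa,
    extract_epochs,
    relative_power,
)

ALPHA = band("alpha")


def _recording(rng, duration_s=120.0, report_times=(30.0, 60.0, 90.0), swb=(5, 6, 5)):
    n = int(duration_s * FS) + 1
    return Recording(
        participant_id="P1",
        samples=rng.normal(size=(14, n)),
        fs=FS,
        report_times=np.array(report_times),
        swb=np.array(swb),
    )


class TestEpochs:
    def test_window_has_1281_samples_ending_at_report(self, rng):
        rec = _recording(rng)
        epochs = extract_epochs(rec, 10.0)
        assert len(epochs) == 3
        for ep, t in zip(epochs, rec.report_times):
            assert ep.samples.shape == (14, WINDOW_SAMPLES)
            end = int(round(t * FS))
            np.testing.assert_array_equal(ep.samples[:, -1], rec.samples[:, end])

    def test_early_report_skipped_with_warning(self, rng, caplog):
        rec = _recording(rng, report_times=(5.0, 30.0), swb=(5, 6))
        with caplog.at_level(logging.WARNING, logger="swblab"):
            epochs = extract_epochs(rec, 10.0)
        assert len(epochs) == 1
        assert any("skipped" in r.message for r in caplog.records)
        # kept + skipped = number of reports
        assert len(epochs) + 1 == rec.n_reports


class TestBandpass:
    def test_passband_and_stopband_gains(self):
        t = np.arange(WINDOW_SAMPLES) / FS
        inside = np.sin(2 * np.pi * 10 * t)
        outside = np.sin(2 * np.pi * 40 * t)
        mid = slice(200, -200)  # ignore filter edge transients
        assert np.ptp(bandpass(inside, ALPHA, FS)[mid]) / np.ptp(inside[mid]) >= 0.9
        assert np.ptp(bandpass(outside, ALPHA, FS)[mid]) / np.ptp(outside[mid]) <= 0.1

    def test_zero_in_zero_out_and_length(self):
        x = np.zeros(500)
        y = bandpass(x, ALPHA, FS)
        assert y.shape == x.shape and np.allclose(y, 0)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(500), band("gamma"), 100.0)


class TestBandPower:
    def test_sinusoid_power_concentrates_in_its_band(self):
        ep = sine_epoch([10.0])
        powers = np.array([band_power(ep.samples[0], b, FS) for b in BANDS])
        assert powers[2] / powers.sum() >= 0.95

    def test_quadratic_scaling(self, rng):
        x = rng.normal(size=WINDOW_SAMPLES)
        p1 = band_power(x, ALPHA, FS)
        p2 = band_power(2 * x, ALPHA, FS)
        assert abs(p2 - 4 * p1) / (4 * p1) < 1e-6

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        # flat spectrum: integral over a band ~ bandwidth * noise level
        acc = np.zeros(len(BANDS))
        for _ in range(100):
            x = rng.normal(size=WINDOW_SAMPLES)
            acc += [band_power(x, b, FS) for b in BANDS]
        widths = np.array([b.hi - b.lo for b in BANDS])
        ratio = (acc / 100) / widths
        assert np.all(np.abs(ratio / ratio.mean() - 1) < 0.15)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ParameterError):
            band_power(np.zeros(100), ALPHA, FS)  # < 2 s at 128 Hz


class TestRelativePower:
    def test_pure_alpha_tone_dominates_every_channel(self):
        feat = relative_power(sine_epoch([10.0]))
        assert np.all(feat.rp[2, :] >= 0.9)

    def test_two_line_spectrum_splits_evenly(self):
        feat = relative_power(sine_epoch([2.0, 20.0]))
        assert abs(feat.rp[0, 0] - 0.5) < 0.05  # delta
        assert abs(feat.rp[3, 0] - 0.5) < 0.05  # beta
        assert np.all(feat.rp[[1, 2, 4], :] <= 0.05)

    def test_columns_sum_to_one_and_scale_invariance(self, rng):
        samples = rng.normal(size=(N_CHANNELS, WINDOW_SAMPLES))
        feat = relative_power(make_epoch(samples))
        np.testing.assert_allclose(feat.rp.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(feat.rp >= 0)
        scaled = relative_power(make_epoch(3.7 * samples))
        np.testing.assert_allclose(scaled.rp, feat.rp, atol=1e-9)

    def test_dead_channel_is_named(self, rng):
        samples = rng.normal(size=(N_CHANNELS, WINDOW_SAMPLES))
        samples[4] = 0.0  # T7
        with pytest.raises(DegenerateSignalError, match="T7"):
            relative_power(make_epoch(samples))


class TestFaa:
    def _epoch_with_frontals(self, rng, left, right):
        samples = rng.normal(size=(N_CHANNELS, WINDOW_SAMPLES))
        samples[0] = left  # AF3
        samples[13] = right  # AF4
        return make_epoch(samples)

    def test_identical_frontals_give_zero(self, rng):
        wave = rng.normal(size=WINDOW_SAMPLES)
        ep = self._epoch_with_frontals(rng, wave, wave.copy())
        assert compute_faa(ep).faa == pytest.approx(0.0, abs=1e-12)

    def test_doubled_right_amplitude_gives_ln4(self, rng):
        wave = rng.normal(size=WINDOW_SAMPLES)
        ep = self._epoch_with_frontals(rng, wave, 2 * wave)
        assert compute_faa(ep).faa == pytest.approx(np.log(4), abs=1e-6)

    def test_antisymmetry_and_common_scale_invariance(self, rng):
        left = rng.normal(size=WINDOW_SAMPLES)
        right = rng.normal(size=WINDOW_SAMPLES)
        base = compute_faa(self._epoch_with_frontals(rng, left, right)).faa
        swapped = compute_faa(self._epoch_with_frontals(rng, right, left)).faa
        assert swapped == pytest.approx(-base, abs=1e-12)
        scaled = compute_faa(self._epoch_with_frontals(rng, 5 * left, 5 * right)).faa
        assert scaled == pytest.approx(base, abs=1e-9)
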