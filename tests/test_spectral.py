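import warnings

import numpy as np
import pytest

import tremorkit as tk
from tremorkit.exceptions import ConfigurationError, InputError
from tremorkit.spectral import (
    concatenate_clean,
    motion_power_ratio,
    peak_frequency,
    reject_artifacts,
    select_tremor_band,
    summed_spectrogram,
    welch_psd,
    welch_window_and_nfft,
)
from tremorkit.types import BandDefinition, PSDEstimate, TriaxSegment


def _segment(data, fs=500.0, start=0.0, sid="s"):
    return TriaxSegment(channels=data, sampling_rate=fs, start_time=start,
                        segment_id=sid)


class TestSummedSpectrogram:
    def test_sum_over_axes(self, rng):
        x = rng.normal(size=5000)
        triax = _segment(np.vstack([x, x, x]))
        single = _segment(np.vstack([x, np.zeros_like(x), np.zeros_like(x)]))
        s3 = summed_spectrogram(triax)
        s1 = summed_spectrogram(single)
        assert np.allclose(s3.power, 3 * s1.power)

    def test_window_count_and_times(self, rng):
        seg = _segment(rng.normal(size=(3, 30000)), start=50.0)  # 60 s
        spec = summed_spectrogram(seg)
        assert spec.n_windows == 60
        assert spec.window_times[0] == pytest.approx(50.5)
        assert np.allclose(np.diff(spec.window_times), 1.0)

    def test_tone_power_concentrated(self):
        # pure 10 Hz tone: Hamming leakage keeps >=90% of power within
        # one bin of the tone frequency in every window
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        seg = _segment(np.vstack([x, np.zeros_like(x), np.zeros_like(x)]),
                       fs=fs)
        spec = summed_spectrogram(seg)
        near = np.abs(spec.freq_bins - 10.0) <= 1.0
        frac = spec.power[:, near].sum(axis=1) / spec.power.sum(axis=1)
        assert (frac >= 0.90).all()

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            summed_spectrogram(_segment(np.zeros((3, 100))))


class TestRejectArtifacts:
    def _spec(self, window_powers, sid="s"):
        p = np.asarray(window_powers, dtype=float)[:, None]
        return tk.SummedSpectrogram(
            window_times=np.arange(len(p)) + 0.5,
            freq_bins=np.array([0.0]), power=p, source_segment_id=sid)

    def test_equal_powers_all_kept(self):
        mask = reject_artifacts([self._spec([5.0] * 6)])
        assert mask.keep["s"].all()  # MAD 0, deviation 0 is not > 0

    def test_single_outlier_excluded(self):
        # powers [1,1,1,1,100]: median 1, MAD 0 -> only the 100 dropped
        mask = reject_artifacts([self._spec([1, 1, 1, 1, 100])])
        assert mask.keep["s"].tolist() == [True] * 4 + [False]
        assert mask.session_median_power == 1.0
        assert mask.session_mad_power == 0.0

    def test_statistics_pooled_across_segments(self):
        # the outlier is only an outlier relative to the whole session
        a = self._spec([10.0] * 50, "a")
        b = self._spec([10.0] * 49 + [100.0], "b")
        mask = reject_artifacts([a, b])
        assert mask.keep["a"].all()
        assert mask.keep["b"].tolist() == [True] * 49 + [False]

    def test_inflated_windows_detected(self, rng):
        # N(10,1) powers with 5% inflated x10: all inflated excluded,
        # false-exclusion < 5%
        powers = rng.normal(10, 1, size=2000)
        bad = rng.choice(2000, size=100, replace=False)
        powers[bad] *= 10
        mask = reject_artifacts([self._spec(powers)])
        keep = mask.keep["s"]
        assert not keep[bad].any()
        clean = np.setdiff1d(np.arange(2000), bad)
        assert (~keep[clean]).mean() < 0.05

    def test_scale_invariance(self, rng):
        powers = rng.normal(10, 1, size=500)
        m1 = reject_artifacts([self._spec(powers)])
        m2 = reject_artifacts([self._spec(powers * 7.3)])
        assert np.array_equal(m1.keep["s"], m2.keep["s"])


class TestConcatenateClean:
    def test_all_kept_preserves_length(self, rng):
        seg = _segment(rng.normal(size=(3, 5000)))
        out = concatenate_clean(seg, np.ones(10, dtype=bool))
        assert out.shape == (3, 5000)

    def test_alternating_mask_halves_duration(self, rng):
        seg = _segment(rng.normal(size=(3, 5000)))
        keep = np.tile([True, False], 5)
        out = concatenate_clean(seg, keep)
        assert out.shape == (3, 2500)

    def test_detrending_bounds_junction_jump(self):
        # step of height 10 across a dropped window: per-window detrending
        # keeps the junction delta well below the raw step size
        fs = 500.0
        x = np.zeros(int(3 * fs))
        x[int(2 * fs):] = 10.0
        seg = _segment(np.vstack([x, x, x]), fs=fs)
        out = concatenate_clean(seg, np.array([True, False, True]))
        junction = abs(out[0, int(fs)] - out[0, int(fs) - 1])
        assert junction < 1.0  # raw step is 10

    def test_empty_mask_gives_empty_result(self, rng):
        seg = _segment(rng.normal(size=(3, 1000)))
        out = concatenate_clean(seg, np.zeros(2, dtype=bool))
        assert out.shape == (3, 0)


class TestWelch:
    @pytest.mark.parametrize("fs,expected_nfft,expected_res", [
        (617.0, 4096, 0.1506),
        (500.0, 2048, 0.2441),
        (1017.3, 4096, 0.2484),
    ])
    def test_frequency_resolution(self, fs, expected_nfft, expected_res, rng):
        nperseg, nfft = welch_window_and_nfft(fs)
        assert nfft == expected_nfft
        psd = welch_psd(rng.normal(size=(3, int(8 * fs))), fs)
        assert round(psd.resolution, 4) == expected_res
        assert psd.resolution == fs / nfft

    def test_parseval(self, rng):
        x = rng.normal(size=(3, 30000))
        psd = welch_psd(x, 500.0)
        total = np.trapezoid(psd.power_density, psd.freqs)
        assert total == pytest.approx(x.var(axis=1).sum(), rel=0.05)

    def test_too_short_rejected(self, rng):
        with pytest.raises(InputError):
            welch_psd(rng.normal(size=(3, 100)), 500.0)


class TestPeakFrequency:
    def _psd(self, freqs, power):
        return PSDEstimate(freqs=np.asarray(freqs, float),
                           power_density=np.asarray(power, float), nfft=0)

    def test_single_maximum(self):
        freqs = np.arange(0, 20, 0.1)
        power = np.ones_like(freqs)
        power[np.argmin(np.abs(freqs - 12.1))] = 10.0
        assert peak_frequency(self._psd(freqs, power)) == pytest.approx(12.1)

    def test_flat_psd_tie_breaks_low(self):
        freqs = np.arange(0, 30, 0.5)
        p = peak_frequency(self._psd(freqs, np.ones_like(freqs)), (10, 14))
        assert p == 10.0

    def test_synthetic_tone_end_to_end(self):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 11.0 * t)
        psd = welch_psd(np.vstack([x, x, x]), fs)
        assert abs(peak_frequency(psd) - 11.0) <= psd.resolution

    def test_empty_band_rejected(self):
        with pytest.raises(ConfigurationError):
            peak_frequency(self._psd([0.0, 1.0], [1.0, 1.0]), (10, 14))


class TestMotionPowerRatio:
    def test_flat_spectrum_equal_band_widths(self):
        freqs = np.arange(0, 25, 1.0)
        mpr = motion_power_ratio(np.ones_like(freqs), freqs,
                                 BandDefinition())
        assert mpr == 1.0

    def test_hand_computed_ratio(self):
        freqs = np.arange(0, 25, 1.0)
        power = np.zeros_like(freqs)
        power[[10, 11, 12, 13]] = 2.0
        power[[17, 18, 19, 20]] = 1.0
        assert motion_power_ratio(power, freqs, BandDefinition()) == 2.0

    def test_scale_invariance(self, rng):
        freqs = np.arange(0, 25, 1.0)
        power = rng.uniform(0.5, 2.0, freqs.size)
        base = motion_power_ratio(power, freqs, BandDefinition())
        # power-of-two rescaling is lossless: equality is exact
        assert motion_power_ratio(8.0 * power, freqs,
                                  BandDefinition()) == base
        assert motion_power_ratio(7.3 * power, freqs, BandDefinition()) \
            == pytest.approx(base, rel=1e-12)

    def test_zero_reference_power_flagged(self):
        freqs = np.arange(0, 25, 1.0)
        power = np.zeros_like(freqs)
        power[12] = 1.0
        assert np.isnan(motion_power_ratio(power, freqs, BandDefinition()))

    def test_half_open_bands_do_not_double_count(self):
        bands = BandDefinition(tremor_band=(10, 14), reference_band=(14, 18))
        freqs = np.arange(0, 25, 1.0)
        power = np.ones_like(freqs)
        power[14] = 100.0  # belongs to the reference band only
        mpr = motion_power_ratio(power, freqs, bands)
        assert mpr == pytest.approx(4 / 103)


class TestSelectTremorBand:
    def _psd_with_peak(self, center, fs=500.0, t_mid=1200.0, height=50.0):
        freqs = np.arange(0, 30, 0.25)
        power = np.ones_like(freqs)
        power += height * np.exp(-0.5 * ((freqs - center) / 0.4) ** 2)
        return PSDEstimate(freqs=freqs, power_density=power, nfft=0,
                           segment_midpoint_time=t_mid)

    def test_unanimous_peaks_centre_band(self):
        psds = [self._psd_with_peak(10.0) for _ in range(5)]
        band = select_tremor_band(psds)
        assert band.tremor_band == (8.0, 12.0)
        assert not band.fallback

    def test_bimodal_session_returns_secondary_band(self):
        freqs = np.arange(0, 30, 0.25)
        power = np.ones_like(freqs)
        power += 50 * np.exp(-0.5 * ((freqs - 14.0) / 0.4) ** 2)
        power += 25 * np.exp(-0.5 * ((freqs - 6.0) / 0.8) ** 2)
        psds = [PSDEstimate(freqs=freqs, power_density=power, nfft=0,
                            segment_midpoint_time=1200.0)] * 4
        band = select_tremor_band(psds)
        assert band.tremor_band == (12.0, 16.0)
        assert band.secondary_band is not None
        lo, hi = band.secondary_band
        assert lo <= 6.0 <= hi

    def test_noise_only_falls_back_with_warning(self, rng):
        freqs = np.arange(0, 30, 0.25)
        psds = [PSDEstimate(freqs=freqs,
                            power_density=1 + 0.01 * rng.random(freqs.size),
                            nfft=0, segment_midpoint_time=1500.0)
                for _ in range(4)]
        with pytest.warns(UserWarning, match="noise floor"):
            band = select_tremor_band(psds)
        assert band.tremor_band == (10.0, 14.0)
        assert band.fallback


def test_mpr_series_flat_noise_median_near_band_ratio(noise_session,
                                                      fast_config):
    """White-noise MPR with equal-width bands has median ~= 1."""
    from tremorkit.pipeline import _segment_and_preprocess

    segs = _segment_and_preprocess(noise_session, fast_config)
    specs = [summed_spectrogram(s) for s in segs]
    mask = reject_artifacts(specs)
    series = tk.mpr_series(specs, mask, BandDefinition())
    assert np.median(series.mpr) == pytest.approx(1.0, abs=0.05)
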