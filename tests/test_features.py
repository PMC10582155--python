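import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avfsound.features import (
    TOP5_PARAMS,
    SampEnParams,
    UndefinedEntropyError,
    banded_sample_entropy,
    bandpass,
    extract_features,
    sample_entropy,
    spectrogram_to_image,
    stft,
)
from avfsound.preprocess import CardiacCycle

from conftest import sampen_bruteforce

FS = 22050.0


def three_tone_signal():
    """Piecewise signal: 150 Hz on (0, 0.5], 100 Hz on (0.5, 1],
    50 Hz on (1, 1.5]."""
    t = np.arange(1, int(1.5 * FS) + 1) / FS
    return np.where(
        t <= 0.5, np.cos(2 * np.pi * 150 * t),
        np.where(t <= 1.0, np.cos(2 * np.pi * 100 * t), np.cos(2 * np.pi * 50 * t)),
    )


def dominant_freq_in_segment(spec, lo_s, hi_s):
    starts = spec.times_s - spec.width_samples / FS / 2
    ends = starts + spec.width_samples / FS
    sel = (starts >= lo_s) & (ends <= hi_s)
    assert sel.any(), "no frame lies entirely within the segment"
    return spec.freqs_hz[np.argmax(spec.magnitudes[:, sel].mean(axis=1))]


class TestSTFT:
    def test_three_tone_dominant_frequencies(self):
        spec = stft(three_tone_signal(), FS, window="hann",
                    width_samples=1024, hop_samples=512)
        bin_width = FS / 1024
        for lo, hi, expected in [(0.0, 0.5, 150.0), (0.5, 1.0, 100.0), (1.0, 1.5, 50.0)]:
            assert abs(dominant_freq_in_segment(spec, lo, hi) - expected) <= bin_width

    def test_all_zero_input(self):
        spec = stft(np.zeros(4096), FS)
        assert np.all(spec.magnitudes == 0)

    def test_single_rectangular_frame_is_plain_dft(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        spec = stft(x, FS, window="rectangular", width_samples=256, hop_samples=256)
        assert spec.n_frames == 1
        np.testing.assert_allclose(spec.magnitudes[:, 0], np.abs(np.fft.rfft(x)), atol=1e-10)

    def test_axes_invariants(self):
        spec = stft(np.random.default_rng(1).standard_normal(8000), FS)
        assert np.all(np.diff(spec.freqs_hz) > 0)
        assert spec.freqs_hz[0] == 0 and spec.freqs_hz[-1] == FS / 2
        assert np.all(np.diff(spec.times_s) > 0)
        assert np.all(spec.magnitudes >= 0)

    def test_parseval_rectangular_nonoverlapping(self):
        rng = np.random.default_rng(2)
        width = 128
        x = rng.standard_normal(width * 8)
        spec = stft(x, FS, window="rectangular", width_samples=width, hop_samples=width)
        mags2 = spec.magnitudes**2
        # one-sided spectrum: double interior bins (DC and Nyquist appear once)
        frame_energy = (mags2[0] + 2 * mags2[1:-1].sum(axis=0) + mags2[-1]) / width
        assert np.sum(frame_energy) == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_width_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="width"):
            stft(np.zeros(100), FS, width_samples=200)


class TestSpectrogramImage:
    def _spec(self, x=None):
        x = x if x is not None else np.random.default_rng(0).standard_normal(8000)
        return stft(x, FS, width_samples=512, hop_samples=256)

    def test_shape_and_range(self):
        img = spectrogram_to_image(self._spec(), size_px=64)
        assert img.shape == (64, 64, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0
        # three identical channels
        np.testing.assert_array_equal(img[..., 0], img[..., 2])

    def test_constant_magnitude_maps_to_zero(self):
        spec = self._spec()
        spec.magnitudes = np.ones_like(spec.magnitudes)
        assert np.all(spectrogram_to_image(spec, size_px=16) == 0)

    def test_global_scale_invariance_without_log(self):
        spec1 = self._spec()
        spec2 = self._spec()
        spec2.magnitudes = 7.5 * spec1.magnitudes
        img1 = spectrogram_to_image(spec1, 32, log_scale=False)
        img2 = spectrogram_to_image(spec2, 32, log_scale=False)
        np.testing.assert_allclose(img1, img2, atol=1e-12)


class TestBandpass:
    def _tone(self, f_hz, n=22050):
        t = np.arange(n) / FS
        return np.sin(2 * np.pi * f_hz * t)

    def test_passband_tone_preserved(self):
        x = self._tone(400)
        y = bandpass(x, FS, 10, 700)
        assert np.sum(y**2) >= 0.99 * np.sum(x**2)

    def test_stopband_tone_removed(self):
        x = self._tone(1200)
        y = bandpass(x, FS, 10, 700)
        assert np.sum(y**2) <= 0.01 * np.sum(x**2)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(self._tone(100), FS, 700, 700)

    def test_idempotent(self):
        x = np.random.default_rng(3).standard_normal(4096)
        y = bandpass(x, FS, 50, 900)
        np.testing.assert_allclose(bandpass(y, FS, 50, 900), y, atol=1e-9)


class TestSampleEntropy:
    def test_printed_worked_examples(self):
        a = [1, 2, 1, 2, 1, 2, 1, 2, 1, 2]
        b = [1, 1, 2, 1, 2, 2, 2, 1, 1, 2]
        assert sample_entropy(np.array(a, float), m=2, r=0.2) == pytest.approx(0.0, abs=1e-12)
        assert sample_entropy(np.array(b, float), m=2, r=0.2) == pytest.approx(1.386294, abs=1e-6)

    def test_series_b_counts_match_enumeration(self):
        # ln 4 comes from B=4 matched m-pairs and A=1 matched (m+1)-pair
        b = np.array([1, 1, 2, 1, 2, 2, 2, 1, 1, 2], float)
        assert sample_entropy(b, 2, 0.2) == pytest.approx(np.log(4))

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, m):
        rng = np.random.default_rng(100 + m)
        checked = 0
        for _ in range(25):
            n = int(rng.integers(m + 3, 51))
            z = rng.standard_normal(n)
            r = float(rng.uniform(0.1, 0.5))
            expected = sampen_bruteforce(z, m, r)
            if expected is None:
                with pytest.raises(UndefinedEntropyError):
                    sample_entropy(z, m, r)
            else:
                assert sample_entropy(z, m, r) == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked == 25

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(0.1, 50).flatmap(lambda v: st.sampled_from([v, -v])),
           b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        z = np.random.default_rng(5).standard_normal(60)
        base = sample_entropy(z, 2, 0.25)
        assert sample_entropy(a * z + b, 2, 0.25) == pytest.approx(base, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sample_entropy(np.ones(20), 2, 0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2, r=0.2)


class TestBandedSampleEntropy:
    def test_full_band_equals_plain_entropy(self):
        # odd length keeps the Nyquist bin out of play; removing DC is a
        # shift, to which the statistic is invariant
        z = np.random.default_rng(6).standard_normal(501)
        p = SampEnParams(0, FS / 2, 2, 0.2)
        assert banded_sample_entropy(z, FS, p) == pytest.approx(
            sample_entropy(z - z.mean(), 2, 0.2), abs=1e-9
        )

    def test_tone_more_regular_than_noise(self):
        rng = np.random.default_rng(7)
        n = 2048
        t = np.arange(n) / FS
        tone = np.sin(2 * np.pi * 300 * t)
        noise = rng.standard_normal(n)
        p = SampEnParams(10, 700, 2, 0.2)
        assert banded_sample_entropy(tone, FS, p) < banded_sample_entropy(noise, FS, p)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SampEnParams(700, 700, 2, 0.2)

    def test_decimation_is_alias_free_for_banded_signal(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(22050)
        p = SampEnParams(10, 700, 2, 0.2)
        full = bandpass(x, FS, 10, 700)
        np.testing.assert_allclose(full[::10], bandpass(full[::10], 2205.0, 10, 700),
                                   atol=1e-9)


class TestExtractFeatures:
    def _cycle(self, seed=0, n=22050):
        rng = np.random.default_rng(seed)
        return CardiacCycle(samples=rng.standard_normal(n), fs=FS, start_index=0,
                            cycle_period_s=1.0, label="normal")

    def test_default_vector_has_five_values(self):
        fv = extract_features(self._cycle())
        assert fv.values.shape == (5,)
        assert fv.params_list == TOP5_PARAMS
        assert np.all(np.isfinite(fv.values))

    def test_single_quadruple(self):
        fv = extract_features(self._cycle(), [SampEnParams(10, 700, 4, 0.2)])
        assert fv.values.shape == (1,)

    def test_duplicate_quadruples_identical(self):
        p = SampEnParams(10, 700, 4, 0.2)
        fv = extract_features(self._cycle(), [p, p])
        assert fv.values[0] == fv.values[1]
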