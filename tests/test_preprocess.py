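"""Spectrogram computation, frequency masking, normalization, assembly."""

import numpy as np
import pytest
from scipy.stats import skew

import sleephmm as sh
from sleephmm.errors import AlignmentError, ValidationError
from sleephmm.preprocess import DEFAULT_EXCLUDE_BANDS

FS = 256.0


class TestComputeSpectrogram:
    def test_zero_trace_gives_zero_power(self):
        spec = sh.compute_spectrogram(np.zeros(int(10 * FS)), FS)
        assert spec.power.shape[1] == 10
        assert np.allclose(spec.power, 0.0)

    def test_pure_sine_peaks_at_its_frequency_matching_periodogram(self):
        t = np.arange(int(20 * FS)) / FS
        trace = np.sin(2 * np.pi * 10 * t)
        spec = sh.compute_spectrogram(trace, FS, epoch_s=1.0)
        # multitaper argmax per epoch at 10 Hz
        peak = spec.frequencies_hz[np.argmax(spec.power, axis=0)]
        assert np.all(peak == 10.0)
        # oracle: plain FFT periodogram of each epoch peaks at the same bin
        segs = trace.reshape(20, int(FS))
        per = np.abs(np.fft.rfft(segs, axis=1)) ** 2
        per[:, 0] = 0.0
        assert np.all(np.fft.rfftfreq(int(FS), 1 / FS)[np.argmax(per, axis=1)] == 10.0)

    def test_epoch_count_is_duration_over_epoch_length(self):
        spec = sh.compute_spectrogram(np.zeros(int(3600 * FS)), FS, epoch_s=1.0)
        assert spec.power.shape[1] == 3600
        assert spec.frequencies_hz[0] == 0.0 and spec.frequencies_hz[-1] == FS / 2

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            sh.compute_spectrogram(np.zeros(100), FS, epoch_s=1.0)

    def test_missing_samples_flag_overlapping_epochs(self):
        mask = np.zeros(int(10 * FS), dtype=bool)
        mask[: int(2.5 * FS)] = True
        spec = sh.compute_spectrogram(np.ones(int(10 * FS)), FS, missing_mask=mask)
        assert list(spec.excluded) == [True, True, True] + [False] * 7


class TestFrequencyMask:
    def test_empty_exclusion_is_identity(self):
        spec = sh.compute_spectrogram(np.random.default_rng(0).standard_normal(2560), FS)
        masked = sh.apply_frequency_mask(spec, ())
        np.testing.assert_array_equal(masked.power, spec.power)

    def test_default_masks_retain_78_of_129_bins(self):
        spec = sh.compute_spectrogram(np.random.default_rng(0).standard_normal(2560), FS)
        masked = sh.apply_frequency_mask(spec, DEFAULT_EXCLUDE_BANDS)
        assert masked.power.shape[0] == 78
        assert masked.power.shape[1] == spec.power.shape[1]
        # oracle: enumerate the integer grid and count survivors
        f = np.arange(129.0)
        keep = ~((f <= 0.5) | ((f >= 45) & (f <= 55)) | (f >= 90))
        assert keep.sum() == 78

    def test_excluding_everything_is_an_error(self):
        spec = sh.compute_spectrogram(np.ones(2560), FS)
        with pytest.raises(ValidationError, match="entire grid"):
            sh.apply_frequency_mask(spec, ((0.0, None),))


class TestLogZNormalize:
    def _spec(self, power):
        power = np.asarray(power, dtype=float)
        return sh.Spectrogram(
            frequencies_hz=np.arange(power.shape[0], dtype=float),
            epoch_times_s=np.arange(power.shape[1], dtype=float),
            power=power,
            channel="eeg",
        )

    def test_zero_power_maps_to_minus_mean_over_sd(self):
        power = np.array([[0.0, 1.0, 2.0, 3.0]])
        X = sh.log_z_normalize(self._spec(power))
        logged = np.log1p(power[0])
        expected = (0.0 - logged.mean()) / logged.std()
        assert X.values[0, 0] == pytest.approx(expected)

    def test_constant_row_maps_to_zeros(self):
        X = sh.log_z_normalize(self._spec(np.full((2, 5), 3.0)))
        assert np.all(X.values == 0.0)

    def test_log1p_reduces_skewness_of_exponential_power(self):
        x = np.random.default_rng(42).exponential(scale=1.0, size=100_000)
        assert abs(skew(np.log1p(x))) < abs(skew(x))

    def test_negative_power_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            sh.log_z_normalize(self._spec(np.array([[-1.0, 1.0]])))

    def test_normalization_is_idempotent(self):
        rng = np.random.default_rng(3)
        power = rng.exponential(size=(10, 200))
        X1 = sh.log_z_normalize(self._spec(power))
        # z-scoring already-standardized values changes nothing
        v = X1.values
        z2 = (v - v.mean(axis=0)) / v.std(axis=0)
        np.testing.assert_allclose(z2, v, atol=1e-9)

    def test_columns_standardized_over_non_excluded_epochs(self):
        rng = np.random.default_rng(4)
        power = rng.exponential(size=(5, 500))
        excl = np.zeros(500, dtype=bool)
        excl[:50] = True
        X = sh.log_z_normalize(self._spec(power), exclude_epochs=excl)
        sub = X.values[~excl]
        np.testing.assert_allclose(sub.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(sub.var(axis=0), 1.0, atol=1e-6)


class TestAssemble:
    def _block(self, n_epochs, n_feat, name, excluded=None):
        return sh.FeatureMatrix(
            values=np.zeros((n_epochs, n_feat)),
            feature_names=[f"{name}:{i}" for i in range(n_feat)],
            excluded=excluded,
        )

    def test_three_channels_of_78_bins_give_234_features(self):
        blocks = [self._block(100, 78, c) for c in ("a", "p", "e")]
        X = sh.assemble_features(blocks)
        assert X.values.shape == (100, 234)
        assert X.feature_names[0] == "a:0" and X.feature_names[-1] == "e:77"

    def test_single_block_is_identity(self):
        b = self._block(10, 5, "a")
        X = sh.assemble_features([b])
        np.testing.assert_array_equal(X.values, b.values)

    def test_mismatched_epoch_counts_raise_alignment_error(self):
        with pytest.raises(AlignmentError, match="epoch count"):
            sh.assemble_features([self._block(100, 5, "a"), self._block(99, 5, "b")])

    def test_exclusion_masks_are_or_combined(self):
        e1 = np.array([True, False, False])
        e2 = np.array([False, False, True])
        X = sh.assemble_features(
            [self._block(3, 2, "a", e1), self._block(3, 2, "b", e2)]
        )
        assert list(X.excluded) == [True, False, True]


def test_white_noise_power_is_flat_across_retained_bins():
    """Parseval-style sanity: flat spectrum in, flat mean power out.

    Bins within the taper half-bandwidth (4 Hz) of the DC edge carry a
    known downward bias of the one-sided multitaper estimate, so flatness
    to <10% is asserted away from the edge and the edge bins are only
    required to stay within ~15%.
    """
    rng = np.random.default_rng(7)
    trace = rng.standard_normal(10_000 * int(FS))  # 10k 1-s epochs
    spec = sh.compute_spectrogram(trace, FS, epoch_s=1.0)
    masked = sh.apply_frequency_mask(spec, DEFAULT_EXCLUDE_BANDS)
    mean_power = masked.power.mean(axis=1)
    interior = masked.frequencies_hz >= 4.0
    ref = mean_power[interior].mean()
    rel_dev = np.abs(mean_power - ref) / ref
    assert rel_dev[interior].max() < 0.10
    assert rel_dev.max() < 0.15
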