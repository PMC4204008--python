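import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remsef.features import (BandConfig, EpochFeatures, SubepochSpectrum,
                             compute_ap_epoch, compute_rp_epoch,
                             compute_sef, compute_sefd_epoch,
                             compute_spectrum, extract_features, smooth_sefd)
from remsef.preprocessing import EpochGrid

BAND = BandConfig(8.0, 16.0)
FREQ = np.arange(257) * 0.5


def spectrum_from_mags(mags):
    return SubepochSpectrum(mag=np.asarray(mags, dtype=float), freq=FREQ)


def brute_force_sef(mag, fraction, band):
    """Independent cumulative-sum oracle over the band bins."""
    idx = [i for i, f in enumerate(FREQ) if band.f1 <= f <= band.f2]
    power = [mag[i] ** 2 for i in idx]
    total = sum(power)
    cum = 0.0
    for i, p in zip(idx, power):
        cum += p
        if cum >= fraction * total - 1e-12 * total:
            return FREQ[i]
    return FREQ[idx[-1]]


class TestSpectrum:
    def test_zero_signal(self):
        spec = compute_spectrum(np.zeros(512))
        assert np.all(spec.mag == 0)
        assert len(spec.mag) == 257

    def test_bin_aligned_tone_is_single_bin(self):
        t = np.arange(512) / 256.0
        spec = compute_spectrum(np.cos(2 * np.pi * 12.0 * t))
        k = int(12.0 / 0.5)
        assert np.argmax(spec.mag) == k
        others = np.delete(spec.mag, [k - 1, k, k + 1])
        assert np.all(others < 1e-10 * spec.mag[k])

    def test_parseval(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 10, 512)
        spec = compute_spectrum(x)
        xc = x - x.mean()
        assert np.isclose((spec.mag ** 2).sum(), (xc ** 2).sum(),
                          rtol=1e-6)

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            compute_spectrum(np.zeros(100))


class TestSEF:
    def test_all_power_in_one_bin(self):
        mag = np.zeros(257)
        mag[int(12 / 0.5)] = 3.0
        spec = spectrum_from_mags(mag)
        assert compute_sef(spec, 0.5, BAND) == 12.0
        assert compute_sef(spec, 0.95, BAND) == 12.0

    def test_uniform_band_median(self):
        mag = np.zeros(257)
        mag[BAND.slice] = 1.0
        spec = spectrum_from_mags(mag)
        # 17 equal bins: 50% first reached at the 9th bin (12.0 Hz),
        # 95% at the 17th (16.0 Hz)
        assert compute_sef(spec, 0.5, BAND) == 12.0
        assert compute_sef(spec, 0.95, BAND) == 16.0

    def test_zero_band_power_is_error(self):
        with pytest.raises(ValueError):
            compute_sef(spectrum_from_mags(np.zeros(257)), 0.5, BAND)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=17, max_size=17),
           st.sampled_from([0.25, 0.5, 0.75, 0.95]))
    def test_matches_brute_force_oracle(self, band_mags, fraction):
        mag = np.zeros(257)
        mag[BAND.slice] = band_mags
        if (mag ** 2).sum() == 0:
            return
        spec = spectrum_from_mags(mag)
        assert compute_sef(spec, fraction, BAND) == \
            brute_force_sef(mag, fraction, BAND)

    def test_sef50_below_sef95(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mag = np.zeros(257)
            mag[BAND.slice] = rng.uniform(0, 1, 17)
            spec = spectrum_from_mags(mag)
            assert compute_sef(spec, 0.5, BAND) <= \
                compute_sef(spec, 0.95, BAND)

    def test_adding_high_power_never_decreases_sef(self):
        rng = np.random.default_rng(3)
        mag = np.zeros(257)
        mag[BAND.slice] = rng.uniform(0.1, 1.0, 17)
        spec = spectrum_from_mags(mag)
        before = compute_sef(spec, 0.5, BAND)
        bump = mag.copy()
        bin_above = int(before / 0.5) + 2
        bump[bin_above] += 5.0
        after = compute_sef(spectrum_from_mags(bump), 0.5, BAND)
        assert after >= before


class TestSEFd:
    def test_constant_differences(self):
        pairs = [(10.0, 12.0)] * 15
        assert compute_sefd_epoch(pairs) == 2.0

    def test_alternating_differences(self):
        diffs = [0.5, 1.0] * 7 + [0.5]   # 8 halves + 7 ones
        pairs = [(10.0, 10.0 + d) for d in diffs]
        assert np.isclose(compute_sefd_epoch(pairs), 11.0 / 15.0)

    def test_wrong_count(self):
        with pytest.raises(ValueError):
            compute_sefd_epoch([(1.0, 2.0)] * 14)


class TestSmoothing:
    def test_constant_preserved(self):
        out = smooth_sefd(np.full(30, 3.7))
        np.testing.assert_allclose(out, 3.7)

    def test_impulse_response(self):
        x = np.zeros(50)
        x[25] = 1.0
        out = smooth_sefd(x)
        np.testing.assert_allclose(out[21:30], np.full(9, 1 / 9))
        assert out[20] == 0 and out[30] == 0

    def test_length_one(self):
        np.testing.assert_array_equal(smooth_sefd([4.2]), [4.2])

    def test_length_preserved(self):
        assert len(smooth_sefd(np.arange(13.0))) == 13

    def test_invalid_entries_skipped(self):
        x = np.array([1.0, np.nan, 1.0, 1.0, 1.0])
        valid = np.array([True, False, True, True, True])
        out = smooth_sefd(x, valid)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[valid], 1.0)


class TestBandPower:
    def _uniform_epoch(self, band_mag, n_band_bins=17, out_mag=0.0):
        mag = np.full(257, out_mag)
        mag[0] = 0.0
        mag[BAND.slice] = band_mag
        return [spectrum_from_mags(mag)] * 15

    def test_ap_single_bin(self):
        mag = np.zeros(257)
        mag[int(10 / 0.5)] = 10.0
        assert np.isclose(
            compute_ap_epoch([spectrum_from_mags(mag)] * 15, BAND), 20.0)

    def test_ap_uniform_band(self):
        spectra = self._uniform_epoch(1.0)
        assert np.isclose(compute_ap_epoch(spectra, BAND),
                          20 * np.log10(17))

    def test_ap_zero_is_error(self):
        with pytest.raises(ValueError):
            compute_ap_epoch([spectrum_from_mags(np.zeros(257))] * 15, BAND)

    def test_rp_all_power_in_band(self):
        spectra = self._uniform_epoch(2.0, out_mag=0.0)
        assert np.isclose(compute_rp_epoch(spectra, BAND), 0.0)

    def test_rp_half_power(self):
        # out-of-band magnitude chosen so band sum is half the total sum
        mag = np.zeros(257)
        mag[BAND.slice] = 1.0          # band sum 17
        mag[100:117] = 1.0             # another 17 out of band
        spectra = [spectrum_from_mags(mag)] * 15
        assert np.isclose(compute_rp_epoch(spectra, BAND),
                          20 * np.log10(0.5))

    def test_rp_nonpositive(self):
        rng = np.random.default_rng(9)
        mag = np.zeros(257)
        mag[1:] = rng.uniform(0, 1, 256)
        spectra = [spectrum_from_mags(mag)] * 15
        assert compute_rp_epoch(spectra, BAND) <= 0.0

    def test_rp_zero_spectrum_is_error(self):
        with pytest.raises(ValueError):
            compute_rp_epoch([spectrum_from_mags(np.zeros(257))] * 15, BAND)


class TestExtractFeatures:
    def test_identical_epochs_identical_rows(self):
        rng = np.random.default_rng(2)
        epoch = rng.normal(0, 20, 7680)
        grid = EpochGrid(np.tile(epoch, (3, 1)))
        feats = extract_features(grid)
        assert all(f.valid for f in feats)
        assert feats[0].sefd == feats[1].sefd == feats[2].sefd
        assert feats[0].ap == feats[2].ap

    def test_rem_sefd_exceeds_n2(self, synthetic_features):
        feats, stages = synthetic_features
        rem = [f.sefd for f, s in zip(feats, stages) if s == "REM"]
        n2 = [f.sefd for f, s in zip(feats, stages) if s == "N2"]
        assert np.median(rem) > np.median(n2)

    def test_zero_epoch_flagged_invalid(self):
        rng = np.random.default_rng(4)
        good = rng.normal(0, 20, 7680)
        grid = EpochGrid(np.stack([good, np.zeros(7680), good]))
        feats = extract_features(grid)
        assert [f.valid for f in feats] == [True, False, True]
        assert not np.isnan(feats[0].ap)

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            extract_features(EpochGrid(np.empty((0, 7680))))


class TestBandConfig:
    def test_bin_count(self):
        assert BAND.n_bins == 17

    @pytest.mark.parametrize("f1,f2", [(8, 8), (16, 8), (-1, 16), (8, 200),
                                       (8.1, 16)])
    def test_invalid_bands_rejected(self, f1, f2):
        with pytest.raises(ValueError):
            BandConfig(f1, f2)
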