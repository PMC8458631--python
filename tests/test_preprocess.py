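import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gagprofiler import Composition, Spectrum, calibrate, denoise, merge_peaks
from gagprofiler.compositions import expand_ions
from gagprofiler.simulate import FixtureSpec, generate_spectrum


def spectrum_of(*pairs):
    mz, inten = zip(*pairs)
    return Spectrum(mz=np.array(mz), intensity=np.array(inten))


class TestMergePeaks:
    def test_symmetric_group_merges_to_weighted_centroid(self):
        s = spectrum_of((100.000, 10), (100.005, 20), (100.010, 10))
        m = merge_peaks(s, max_gap=0.02)
        assert len(m) == 1
        assert m.intensity[0] == 40.0
        assert m.mz[0] == pytest.approx(100.005, abs=1e-9)

    def test_local_minimum_closes_the_group(self):
        # rise-fall run {10,20,10} then a new rise {15,5}: two groups
        s = spectrum_of(
            (100.000, 10), (100.005, 20), (100.010, 10), (100.015, 15), (100.020, 5)
        )
        m = merge_peaks(s, max_gap=0.02)
        assert len(m) == 2
        assert list(m.intensity) == [40.0, 20.0]
        assert m.mz[0] == pytest.approx(100.005)
        assert m.mz[1] == pytest.approx((100.015 * 15 + 100.020 * 5) / 20)

    def test_distant_peaks_not_merged(self):
        s = spectrum_of((100.0, 10), (200.0, 10))
        m = merge_peaks(s, max_gap=0.02)
        assert len(m) == 2

    def test_empty_spectrum_passes_through(self):
        s = Spectrum(mz=np.array([]), intensity=np.array([]))
        assert len(merge_peaks(s)) == 0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_conserves_intensity_and_is_idempotent_on_oversegmented_envelopes(self, seed):
        spec = FixtureSpec(
            components=[(Composition(1, 1, 2, 0, 5, 0, 0), 1e6)],
            charges=(2, 3),
            oversegment=True,
            seed=seed,
        )
        s = generate_spectrum(spec)
        once = merge_peaks(s, max_gap=0.01)
        assert once.intensity.sum() == pytest.approx(s.intensity.sum(), rel=1e-12)
        assert len(once) <= len(s)
        twice = merge_peaks(once, max_gap=0.01)
        np.testing.assert_array_equal(twice.mz, once.mz)
        np.testing.assert_array_equal(twice.intensity, once.intensity)


class TestDenoise:
    def test_low_relative_intensity_removed(self):
        s = spectrum_of((100.0, 1_000_000), (200.0, 900))
        out = denoise(s, abs_threshold=500, rel_threshold=0.001, repeat_count=1000)
        assert list(out.mz) == [100.0]

    def test_below_absolute_threshold_removed(self):
        s = spectrum_of((100.0, 1_000_000), (200.0, 400), (300.0, 1500))
        out = denoise(s, abs_threshold=500, rel_threshold=0.001, repeat_count=1000)
        assert list(out.mz) == [100.0, 300.0]

    def test_repeated_intensity_value_treated_as_instrumental_noise(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 1100, size=1300))
        inten = np.full(1300, 17.0)
        inten = np.concatenate([inten, [1e6]])
        mz = np.concatenate([mz, [1150.0]])
        out = denoise(
            Spectrum(mz=mz, intensity=inten),
            abs_threshold=500,
            rel_threshold=0.001,
            repeat_count=1000,
        )
        assert len(out) == 1
        assert out.intensity[0] == 1e6

    def test_output_is_subset_and_second_pass_is_stable(self):
        rng = np.random.default_rng(1)
        s = Spectrum(
            mz=np.sort(rng.uniform(100, 1000, 500)),
            intensity=np.exp(rng.uniform(0, 15, 500)),
        )
        once = denoise(s)
        assert set(once.mz) <= set(s.mz)
        twice = denoise(once)
        np.testing.assert_array_equal(twice.mz, once.mz)


class TestCalibrate:
    @pytest.fixture
    def ion_index(self):
        ions = expand_ions(Composition(1, 1, 2, 0, 5, 0, 0), max_charge=3, max_losses=1)
        return np.array([ion.mono_mz for ion in ions])

    def _noiseless(self, ion_index, offset=0.0):
        mz = np.sort(ion_index) + offset
        inten = np.linspace(1e6, 1e5, mz.size)
        return Spectrum(mz=mz, intensity=inten)

    def test_already_calibrated_spectrum_gets_zero_shift(self, ion_index):
        _, result = calibrate(self._noiseless(ion_index), ion_index)
        assert result.shift == pytest.approx(0.0, abs=1e-9)

    def test_known_offset_recovered_and_corrected(self, ion_index):
        spectrum = self._noiseless(ion_index, offset=-0.005)
        calibrated, result = calibrate(spectrum, ion_index)
        assert result.shift == pytest.approx(0.005, abs=1e-4)
        for mz in calibrated.mz:
            nearest = ion_index[np.argmin(np.abs(ion_index - mz))]
            assert abs(mz - nearest) / nearest * 1e6 < 2.0  # ppm

    def test_median_of_anchor_differences(self):
        ion_index = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        diffs = [0.004, 0.005, 0.006, 0.005, 0.005]
        mz = ion_index - np.array(diffs)
        spectrum = Spectrum(mz=mz, intensity=np.full(5, 1e6))
        _, result = calibrate(spectrum, ion_index)
        assert result.shift == pytest.approx(0.005, abs=1e-9)
        assert result.n_anchor_peaks == 5

    @pytest.mark.parametrize("delta", [-0.02, -0.005, 0.0, 0.003, 0.02])
    def test_inverse_consistency_for_constant_offsets(self, ion_index, delta):
        spectrum = self._noiseless(ion_index, offset=delta)
        _, result = calibrate(spectrum, ion_index, prematch_window=0.05)
        assert result.shift == pytest.approx(-delta, abs=1e-4)

    def test_no_anchor_match_returns_identity(self, ion_index):
        spectrum = spectrum_of((150.0, 1e6), (151.0, 1e5))
        calibrated, result = calibrate(spectrum, ion_index, prematch_window=0.01)
        assert result.shift == 0.0
        assert result.n_anchor_peaks == 0
        np.testing.assert_array_equal(calibrated.mz, spectrum.mz)

    def test_empty_ion_index_is_an_error(self):
        with pytest.raises(ValueError):
            calibrate(spectrum_of((100.0, 1.0)), np.array([]))
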