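"""Alignment, baseline, peak detection/integration and spectrum filtering."""

import numpy as np
import pytest

from lpica.preprocess import (
    AlignmentError,
    PeakBinSet,
    PeakHistogram,
    RawSpectrum,
    align_spectrum,
    baseline_correct,
    detect_peak_bins,
    filter_spectra,
    integrate_peaks,
)


def gaussian_peaks(mz, centers, areas, sigma=0.5):
    y = np.zeros_like(mz)
    dx = mz[1] - mz[0]
    for c, a in zip(centers, areas):
        y += a * dx / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return y


@pytest.fixture()
def peak_spectrum():
    mz = np.arange(650.0, 850.0, 0.1)
    y = gaussian_peaks(mz, [700.0, 750.0, 800.0], [500.0, 300.0, 800.0])
    return RawSpectrum(mz, y, "ref", 0)


class TestAlign:
    def test_identity_gives_zero_shift(self, peak_spectrum):
        aligned, shift = align_spectrum(peak_spectrum, peak_spectrum, max_shift=2.0)
        assert shift == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(aligned.intensity, peak_spectrum.intensity, rtol=1e-9)

    @pytest.mark.parametrize("steps", [2, -3])
    def test_integer_shift_recovered(self, peak_spectrum, steps):
        """A spectrum displaced by a whole number of axis steps comes back
        with the opposite correction and matches the reference."""
        dx = peak_spectrum.step
        shifted = RawSpectrum(peak_spectrum.mz + steps * dx, peak_spectrum.intensity)
        aligned, shift = align_spectrum(shifted, peak_spectrum, max_shift=1.0)
        assert shift == pytest.approx(-steps * dx, abs=0.05 * dx)
        # interior samples recover the reference within interpolation error
        sel = slice(50, -50)
        np.testing.assert_allclose(
            aligned.intensity[sel], peak_spectrum.intensity[sel], atol=1e-6 * 800
        )

    def test_subbin_shift_recovered(self, peak_spectrum):
        dx = peak_spectrum.step
        shifted = RawSpectrum(peak_spectrum.mz + 0.5 * dx, peak_spectrum.intensity)
        _, shift = align_spectrum(shifted, peak_spectrum, max_shift=1.0)
        assert abs(-shift - 0.5 * dx) <= 0.25 * dx

    def test_total_intensity_conserved(self, peak_spectrum):
        dx = peak_spectrum.step
        shifted = RawSpectrum(peak_spectrum.mz + 1.3 * dx, peak_spectrum.intensity)
        aligned, _ = align_spectrum(shifted, peak_spectrum, max_shift=1.0)
        assert aligned.intensity.sum() == pytest.approx(
            peak_spectrum.intensity.sum(), rel=1e-3
        )

    def test_disjoint_ranges_raise(self, peak_spectrum):
        other = RawSpectrum(peak_spectrum.mz + 500.0, peak_spectrum.intensity)
        with pytest.raises(AlignmentError):
            align_spectrum(other, peak_spectrum, max_shift=1.0)

    def test_flat_spectrum_warns_zero_shift(self, peak_spectrum):
        flat = RawSpectrum(peak_spectrum.mz, np.zeros_like(peak_spectrum.mz))
        with pytest.warns(UserWarning):
            _, shift = align_spectrum(flat, peak_spectrum, max_shift=1.0)
        assert shift == 0.0


class TestBaseline:
    def test_constant_offset_removed(self):
        mz = np.arange(650.0, 850.0, 0.1)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 2.0, mz.size)
        spec = RawSpectrum(mz, 40.0 + noise)
        out = baseline_correct(spec, smoothness=10.0)
        assert abs(out.intensity.mean()) < 3 * 2.0 / np.sqrt(mz.size)

    def test_ramp_plus_peaks_preserves_areas(self):
        mz = np.arange(650.0, 850.0, 0.1)
        areas = [500.0, 300.0, 800.0]
        peaks = gaussian_peaks(mz, [700.0, 750.0, 800.0], areas, sigma=0.5)
        ramp = 0.5 * (mz - 650.0)
        out = baseline_correct(RawSpectrum(mz, ramp + peaks), smoothness=8.0)
        # a sampled Gaussian of area `a` sums to `a` (the dx factors cancel)
        for c, a in zip([700.0, 750.0, 800.0], areas):
            sel = np.abs(out.mz - c) < 3.0
            assert out.intensity[sel].sum() == pytest.approx(a, rel=0.05)

    def test_all_zero_stays_zero(self):
        mz = np.arange(0.0, 10.0, 0.1)
        out = baseline_correct(RawSpectrum(mz, np.zeros_like(mz)), smoothness=2.0)
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_negative_residuals_retained(self):
        mz = np.arange(0.0, 100.0, 0.1)
        rng = np.random.default_rng(1)
        out = baseline_correct(RawSpectrum(mz, 10 + rng.normal(0, 1, mz.size)), 5.0)
        assert (out.intensity < 0).any()

    def test_too_narrow_smoothness_raises(self):
        mz = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            baseline_correct(RawSpectrum(mz, np.ones_like(mz)), smoothness=0.05)


class TestDetectAndIntegrate:
    def test_noise_only_corpus_empty_binset(self):
        mz = np.arange(650.0, 850.0, 0.1)
        rng = np.random.default_rng(2)
        corpus = [RawSpectrum(mz, rng.normal(0, 1, mz.size)) for _ in range(5)]
        bins = detect_peak_bins(corpus, (650.0, 850.0), significance=5.0)
        assert len(bins) == 0

    def test_three_peaks_three_bins(self, peak_spectrum):
        rng = np.random.default_rng(3)
        corpus = [
            RawSpectrum(
                peak_spectrum.mz,
                peak_spectrum.intensity + rng.normal(0, 1.0, peak_spectrum.mz.size),
            )
            for _ in range(6)
        ]
        bins = detect_peak_bins(corpus, (650.0, 850.0), significance=5.0)
        assert len(bins) == 3
        for apex in [700.0, 750.0, 800.0]:
            assert ((bins.low <= apex) & (bins.high > apex)).any()

    def test_integration_recovers_analytic_areas(self, peak_spectrum):
        bins = PeakBinSet(
            np.array([697.0, 747.0, 797.0]),
            np.array([703.0, 753.0, 803.0]),
            np.array([700.0, 750.0, 800.0]),
            window=(650.0, 850.0),
        )
        h1 = integrate_peaks(peak_spectrum, bins, gain=1.0)
        # a sampled Gaussian of area `a` sums to `a` inside a +-6 sigma bin
        np.testing.assert_allclose(h1.counts, [500.0, 300.0, 800.0], rtol=1e-3)
        h5 = integrate_peaks(peak_spectrum, bins, gain=5.0)
        np.testing.assert_allclose(h5.counts, h1.counts / 5.0, rtol=1e-12)

    def test_zero_spectrum_zero_histogram(self, peak_spectrum):
        bins = PeakBinSet(
            np.array([699.0]), np.array([701.0]), np.array([700.0]), (650.0, 850.0)
        )
        zero = RawSpectrum(peak_spectrum.mz, np.zeros_like(peak_spectrum.mz))
        assert integrate_peaks(zero, bins).counts.sum() == 0.0

    def test_bins_outside_range_raise(self, peak_spectrum):
        bins = PeakBinSet(
            np.array([100.0]), np.array([105.0]), np.array([102.0]), (90.0, 900.0)
        )
        with pytest.raises(ValueError):
            integrate_peaks(peak_spectrum, bins)

    def test_shift_then_preprocess_commutes(self, peak_spectrum):
        """Preprocessing a globally shifted spectrum yields the same
        histogram as preprocessing the original (within interpolation)."""
        bins = PeakBinSet(
            np.array([697.0, 747.0, 797.0]),
            np.array([703.0, 753.0, 803.0]),
            np.array([700.0, 750.0, 800.0]),
            window=(650.0, 850.0),
        )
        direct = integrate_peaks(peak_spectrum, bins)
        dx = peak_spectrum.step
        shifted = RawSpectrum(peak_spectrum.mz + 1.7 * dx, peak_spectrum.intensity)
        aligned, _ = align_spectrum(shifted, peak_spectrum, max_shift=1.0)
        roundtrip = integrate_peaks(aligned, bins)
        np.testing.assert_allclose(roundtrip.counts, direct.counts, rtol=0.01)


class TestFilter:
    def make(self, total):
        return PeakHistogram(np.array([1.0]), np.array([float(total)]))

    def test_three_way_partition(self):
        hists = [self.make(t) for t in (50, 500, 20000)]
        kept, lo, hi = filter_spectra(hists, 100, 10000)
        assert [h.total for h in kept] == [500]
        assert [h.total for h in lo] == [50]
        assert [h.total for h in hi] == [20000]

    def test_unbounded_keeps_all(self):
        hists = [self.make(t) for t in (1, 10, 100)]
        kept, lo, hi = filter_spectra(hists, 0, float("inf"))
        assert len(kept) == 3 and not lo and not hi

    def test_88_to_80_partition_exhaustive(self):
        rng = np.random.default_rng(4)
        totals = rng.uniform(1000, 9000, 88)
        totals[:6] = rng.uniform(1, 99, 6)       # pushed below threshold
        totals[6:8] = rng.uniform(10001, 20000, 2)  # pushed above
        hists = [self.make(t) for t in totals]
        kept, lo, hi = filter_spectra(hists, 100, 10000)
        assert (len(kept), len(lo), len(hi)) == (80, 6, 2)
        assert len(kept) + len(lo) + len(hi) == len(hists)

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            filter_spectra([], 10, 10)
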