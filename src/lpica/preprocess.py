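"""Spectrum conditioning: alignment, baseline removal, peak binning, filtering.

The downstream mixture model assumes that each spectrum is a histogram of
(approximately) independent Poisson bins.  Raw MALDI-ToF profile spectra
violate this in three ways: peak positions drift between acquisitions, a
slowly varying chemical-noise baseline sits under the peaks, and intensity
between peaks carries no class information.  This module removes those
nuisances and reduces each profile to a vector of per-peak ion counts:

1. :func:`align_spectrum` removes a global m/z shift by cross-correlation
   against a reference spectrum, with parabolic sub-bin refinement.
2. :func:`baseline_correct` subtracts a smooth lower envelope estimated by a
   wide rolling median, leaving background noise zero-mean (negative
   residuals are deliberately retained).
3. :func:`detect_peak_bins` finds significant peaks in a corpus-mean
   spectrum and turns them into disjoint integration bins, discarding
   inter-peak gaps.
4. :func:`integrate_peaks` sums intensity inside each bin and divides by
   the detector gain (intensity units per ion event) so that bin values are
   on a Poisson counting scale.
5. :func:`filter_spectra` rejects spectra whose total count is too low
   (poor signal-to-noise) or too high (saturated peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, grey_opening, median_filter, uniform_filter1d

__all__ = [
    "RawSpectrum",
    "PeakBinSet",
    "PeakHistogram",
    "AlignmentError",
    "align_spectrum",
    "baseline_correct",
    "detect_peak_bins",
    "integrate_peaks",
    "filter_spectra",
]


class AlignmentError(ValueError):
    """Raised when two spectra cannot be brought onto a common axis."""


@dataclass(frozen=True)
class RawSpectrum:
    """A profile spectrum: intensity sampled on a strictly increasing m/z axis.

    Intensities of freshly acquired spectra are non-negative; baseline-corrected
    spectra may dip below zero in background regions (zero-mean noise is kept
    zero-mean, not clipped), so only finiteness is enforced here.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or intensity.ndim != 1 or mz.size != intensity.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    @property
    def step(self) -> float:
        """Median axis spacing in Da."""
        return float(np.median(np.diff(self.mz)))


@dataclass(frozen=True)
class PeakBinSet:
    """Disjoint half-open integration bins ``[low, high)`` inside an analysis window."""

    low: np.ndarray
    high: np.ndarray
    centroid: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        low = np.asarray(self.low, dtype=float)
        high = np.asarray(self.high, dtype=float)
        centroid = np.asarray(self.centroid, dtype=float)
        if not (low.size == high.size == centroid.size):
            raise ValueError("low, high and centroid must have equal length")
        if low.size:
            if not np.all(high > low):
                raise ValueError("each bin needs high > low")
            if not np.all(low[1:] >= high[:-1]):
                raise ValueError("bins must be sorted and pairwise disjoint")
            if not (np.all(low >= self.window[0]) and np.all(high <= self.window[1])):
                raise ValueError("bins must lie inside the analysis window")
            if not np.all((centroid >= low) & (centroid <= high)):
                raise ValueError("centroid must fall inside its bin")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)
        object.__setattr__(self, "centroid", centroid)

    def __len__(self) -> int:
        return int(self.low.size)


@dataclass(frozen=True)
class PeakHistogram:
    """Per-peak ion counts for one spectrum.

    ``counts`` is intensity integrated over each peak bin divided by ``gain``
    (intensity units per ion event), so each entry is on a Poisson counting
    scale.  This is the histogram the Linear Poisson Model fits.
    """

    centroids: np.ndarray
    counts: np.ndarray
    gain: float = 1.0
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        centroids = np.asarray(self.centroids, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if centroids.ndim != 1 or counts.ndim != 1 or centroids.size != counts.size:
            raise ValueError("centroids and counts must be 1-D arrays of equal length")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _shifted(y: np.ndarray, s: int) -> np.ndarray:
    """``y`` displaced by ``s`` samples with zero padding (no wrap-around)."""
    out = np.zeros_like(y)
    if s >= 0:
        out[: y.size - s] = y[s:]
    else:
        out[-s:] = y[: y.size + s]
    return out


def align_spectrum(
    spectrum: RawSpectrum, reference: RawSpectrum, max_shift: float
) -> tuple[RawSpectrum, float]:
    """Remove a global m/z shift relative to ``reference``.

    The spectrum is resampled onto the reference axis, the displacement is
    estimated by maximising the cross-correlation over integer axis steps
    within ``±max_shift`` Da, and a parabolic fit through the correlation
    maximum refines the estimate to sub-bin precision.

    Returns the aligned spectrum (on the reference axis) and the applied
    correction ``shift`` in Da: a spectrum whose peaks sit ``d`` Da above the
    reference comes back with ``shift = -d``.  Total resampled intensity is
    conserved.  A flat (all-zero) spectrum is returned unshifted with a
    warning.
    """
    if max_shift <= 0:
        raise ValueError("max_shift must be positive")
    if spectrum.mz[-1] < reference.mz[0] or spectrum.mz[0] > reference.mz[-1]:
        raise AlignmentError("spectrum and reference m/z ranges do not overlap")

    ref_mz = reference.mz
    dx = reference.step
    y = np.interp(ref_mz, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    r = reference.intensity

    if not np.any(y != 0) or not np.any(r != 0):
        warnings.warn("flat spectrum: alignment skipped, zero shift returned")
        aligned = RawSpectrum(ref_mz, y, spectrum.sample_id, spectrum.replicate)
        return aligned, 0.0

    max_steps = max(1, int(np.floor(max_shift / dx)))
    steps = np.arange(-max_steps, max_steps + 1)
    cc = np.array([float(np.dot(r, _shifted(y, int(s)))) for s in steps])
    k = int(np.argmax(cc))

    delta = 0.0
    if 0 < k < cc.size - 1:
        denom = cc[k - 1] - 2.0 * cc[k] + cc[k + 1]
        if denom < 0:  # genuine local maximum
            delta = 0.5 * (cc[k - 1] - cc[k + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))

    displacement = (steps[k] + delta) * dx  # spectrum sits this far above reference
    shift = float(np.clip(-displacement, -max_shift, max_shift))

    aligned_y = np.interp(ref_mz - shift, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    tot_before, tot_after = y.sum(), aligned_y.sum()
    if tot_after > 0 and tot_before > 0:
        aligned_y = aligned_y * (tot_before / tot_after)

    aligned = RawSpectrum(ref_mz, aligned_y, spectrum.sample_id, spectrum.replicate)
    return aligned, shift


def baseline_correct(spectrum: RawSpectrum, smoothness: float) -> RawSpectrum:
    """Subtract a smooth baseline estimated by a wide rolling median.

    ``smoothness`` is the median window width in Da and must exceed the width
    of the widest peak (peaks occupying less than half the window leave the
    median untouched).  Because the median of zero-mean background noise
    tracks the baseline itself, background regions come out with mean ≈ 0;
    negative residuals are retained so the background stays zero-mean.
    """
    dx = spectrum.step
    if smoothness <= dx:
        raise ValueError("smoothness must exceed the axis spacing")
    w = int(round(smoothness / dx))
    w = max(3, w | 1)  # odd window
    y = spectrum.intensity
    # peak mask from a morphological opening: erosion followed by dilation
    # removes features narrower than the window exactly, even on a sloped or
    # curved background, so the full peak (tails included) stands out in the
    # residual.  The opening itself hugs the lower noise envelope, so the
    # baseline is instead re-estimated as a rolling median with the peak
    # samples bridged by interpolated background — the median of zero-mean
    # background noise tracks the baseline, keeping the background zero-mean.
    opened = grey_opening(y, size=w)
    resid = y - opened  # >= 0 by construction
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    peaky = resid > np.median(resid) + 3.0 * noise
    # the opening under-reports flank tails on sloped backgrounds, so grow
    # the mask outward past them (an eighth of the window each side); the
    # occasional bridged background point is harmless to the median
    peaky = binary_dilation(peaky, iterations=max(1, w // 8))
    if peaky.any() and not peaky.all():
        masked = y.copy()
        masked[peaky] = np.interp(
            spectrum.mz[peaky], spectrum.mz[~peaky], y[~peaky]
        )
    else:
        masked = y
    base = median_filter(masked, size=w, mode="nearest")
    # light smoothing so the baseline is a smooth function, not a staircase
    base = uniform_filter1d(base, size=max(3, (w // 2) | 1), mode="nearest")
    return RawSpectrum(
        spectrum.mz, y - base, spectrum.sample_id, spectrum.replicate
    )


def detect_peak_bins(
    corpus: list[RawSpectrum],
    window: tuple[float, float],
    significance: float = 5.0,
    edge_fraction: float = 0.2,
) -> PeakBinSet:
    """Locate significant peaks in the corpus mean and convert them to bins.

    The corpus mean spectrum (all spectra must share one m/z axis and be
    aligned and baseline-corrected) is thresholded at ``significance`` times
    a robust (MAD-based) noise estimate.  Each above-threshold run is grown
    outwards while the mean stays above ``edge_fraction`` of the threshold,
    which captures peak tails without admitting background.  Runs that touch
    are merged; inter-peak gaps are excluded.  Bin centroids are
    intensity-weighted means.  A corpus with no significant peaks yields an
    empty (valid) bin set.
    """
    if not corpus:
        raise ValueError("corpus must contain at least one spectrum")
    mz = corpus[0].mz
    for s in corpus[1:]:
        if s.mz.size != mz.size or not np.allclose(s.mz, mz):
            raise ValueError("all corpus spectra must share a common m/z axis")

    mean_spec = np.mean([s.intensity for s in corpus], axis=0)
    dx = corpus[0].step
    sel = (mz >= window[0]) & (mz < window[1])
    if not np.any(sel):
        raise ValueError("analysis window contains no samples")
    x = mean_spec[sel]
    wmz = mz[sel]

    med = float(np.median(x))
    sigma = 1.4826 * float(np.median(np.abs(x - med)))
    if sigma == 0.0:
        sigma = float(np.std(x)) or np.finfo(float).tiny
    hi = med + significance * sigma
    lo = med + max(edge_fraction * significance, 1.0) * sigma

    core = x >= hi
    if not np.any(core):
        return PeakBinSet(np.array([]), np.array([]), np.array([]), window)

    # grow every core run outwards while above the low threshold
    above = x >= lo
    keep = np.zeros(x.size, dtype=bool)
    idx = np.flatnonzero(core)
    for i in idx:
        if keep[i]:
            continue
        a = i
        while a > 0 and above[a - 1]:
            a -= 1
        b = i
        while b < x.size - 1 and above[b + 1]:
            b += 1
        keep[a : b + 1] = True

    # contiguous kept runs -> bins
    edges = np.diff(np.concatenate(([0], keep.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    lows, highs, cents = [], [], []
    for a, b in zip(starts, ends):
        low = max(window[0], wmz[a] - dx / 2)
        high = min(window[1], wmz[b] + dx / 2)
        wgt = np.clip(x[a : b + 1] - med, 0.0, None)
        if wgt.sum() > 0:
            c = float(np.sum(wmz[a : b + 1] * wgt) / wgt.sum())
        else:
            c = float(0.5 * (low + high))
        lows.append(low)
        highs.append(high)
        cents.append(min(max(c, low), high))
    return PeakBinSet(np.array(lows), np.array(highs), np.array(cents), window)


def integrate_peaks(
    spectrum: RawSpectrum, bins: PeakBinSet, gain: float = 1.0
) -> PeakHistogram:
    """Sum intensity inside each bin and convert to counts via the gain.

    ``counts[j] = max(0, sum of intensity over bin j) / gain``; intensity in
    inter-peak gaps contributes nothing.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if len(bins):
        dx = spectrum.step
        if bins.low[0] < spectrum.mz[0] - dx or bins.high[-1] > spectrum.mz[-1] + dx:
            raise ValueError("bins extend outside the spectrum m/z range")
    counts = np.empty(len(bins))
    for j in range(len(bins)):
        sel = (spectrum.mz >= bins.low[j]) & (spectrum.mz < bins.high[j])
        counts[j] = max(0.0, float(spectrum.intensity[sel].sum())) / gain
    return PeakHistogram(
        bins.centroid.copy(), counts, gain, spectrum.sample_id, spectrum.replicate
    )


def filter_spectra(
    histograms: list[PeakHistogram], low_total: float, high_total: float
) -> tuple[list[PeakHistogram], list[PeakHistogram], list[PeakHistogram]]:
    """Partition spectra into (kept, rejected_low, rejected_high) by total counts.

    Low totals indicate poor signal-to-noise; high totals indicate saturated
    peaks.  The partition is exhaustive and disjoint.
    """
    if not low_total < high_total:
        raise ValueError("low_total must be below high_total")
    kept, rej_lo, rej_hi = [], [], []
    for h in histograms:
        t = h.total
        if t < low_total:
            rej_lo.append(h)
        elif t > high_total:
            rej_hi.append(h)
        else:
            kept.append(h)
    return kept, rej_lo, rej_hi
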