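"""Synthetic binary-mixture corpora with the statistical structure of MALDI data.

No public MALDI mixture dataset accompanies this problem, so the generators
here emulate the experimental design the method targets: two lipid-rich
classes mixed in 11 proportions from 0% to 100% of class A in 10% steps,
8 replicate depositions per proportion (88 spectra), uncontrolled
per-spectrum total signal, a contamination sub-spectrum uncorrelated with
the mixing proportion, class-dependent detection efficiency, gain-scaled
Poisson counting noise, and — for the profile renderer — a smooth baseline
with zero-mean Gaussian noise plus sub-bin peak-position jitter.

Every generator is a pure function of its seed.

Default study conditions: 80 m/z bins over a 650–850 Da lipid window,
24 peaks per class sharing 30% of their positions, detection efficiency of
class B half that of class A, 5% contamination, and 2 000–20 000 total ion
events per spectrum (per-peak counts of order 10²–10³, typical of summed
MALDI peak statistics at desk-top runtimes).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .lpm import ComponentPMF
from .preprocess import PeakHistogram, RawSpectrum
from .quantify import MixtureTruth

__all__ = [
    "make_class_pmfs",
    "generate_corpus",
    "add_profile_artifacts",
    "DEFAULT_PROPORTIONS",
    "default_centroids",
]

#: the 11-step binary mixture design: 0% to 100% class A in 10% increments
DEFAULT_PROPORTIONS = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))

#: analysis window emulating the milk lipid range (Da)
WINDOW = (650.0, 850.0)


def default_centroids(n_bins: int) -> np.ndarray:
    """Bin centroid m/z values spread evenly over the lipid window."""
    edges = np.linspace(WINDOW[0], WINDOW[1], n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def make_class_pmfs(
    n_bins: int = 80,
    n_peaks_per_class: int = 24,
    overlap_fraction: float = 0.3,
    seed: int = 0,
    n_contamination_peaks: int = 6,
) -> tuple[ComponentPMF, ComponentPMF, ComponentPMF]:
    """Two class sub-spectra sharing a fraction of peak positions, plus contamination.

    ``overlap_fraction`` of each class's peak positions are common to both
    classes (with independent intensities) — the shared molecular
    constituents that make single-peak analysis ambiguous.  The remaining
    positions are exclusive.  The contamination PMF occupies its own
    positions.  Peak intensities are log-normal.  Deterministic in ``seed``.

    Peak positions are drawn from ``n_bins`` candidate locations, and —
    mirroring preprocessed histograms, which keep only significant-peak
    bins with inter-peak gaps removed — bins occupied by no component are
    dropped, so the returned PMFs span exactly the retained peaks.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_peaks_per_class < 1:
        raise ValueError("need at least one peak per class")
    n_shared = int(round(overlap_fraction * n_peaks_per_class))
    n_excl = n_peaks_per_class - n_shared
    n_total = n_shared + 2 * n_excl + n_contamination_peaks
    if n_total > n_bins:
        raise ValueError("peak positions exceed the number of bins")

    rng = np.random.default_rng(seed)
    pos = rng.choice(n_bins, size=n_total, replace=False)
    shared = pos[:n_shared]
    only_A = pos[n_shared : n_shared + n_excl]
    only_B = pos[n_shared + n_excl : n_shared + 2 * n_excl]
    contam = pos[n_shared + 2 * n_excl :]

    def raw_pmf(positions: np.ndarray) -> np.ndarray:
        p = np.zeros(n_bins)
        p[positions] = rng.lognormal(mean=0.0, sigma=1.0, size=positions.size)
        return p / p.sum()

    raw = [
        raw_pmf(np.concatenate([shared, only_A])),
        raw_pmf(np.concatenate([shared, only_B])),
        raw_pmf(contam),
    ]
    occupied = np.flatnonzero(np.any(np.stack(raw) > 0, axis=0))
    labels = ("class_A", "class_B", "contamination")
    pmf_A, pmf_B, pmf_C = (
        ComponentPMF(p[occupied] / p[occupied].sum(), label=lab)
        for p, lab in zip(raw, labels)
    )
    return pmf_A, pmf_B, pmf_C


def generate_corpus(
    pmfs: tuple[ComponentPMF, ComponentPMF, ComponentPMF],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    replicates: int = 8,
    total_events_range: tuple[float, float] = (2_000.0, 20_000.0),
    gain: float = 1.0,
    contamination_level: float = 0.05,
    efficiency_B: float = 0.5,
    seed: int = 0,
) -> tuple[list[PeakHistogram], list[MixtureTruth]]:
    """Draw a corpus of Poisson peak histograms over the binary mixture design.

    For each (proportion p, replicate) the total event budget N is uniform
    over ``total_events_range`` and the expected histogram is

        N · [(1−c) · (p·pmf_A + (1−p)·e_B·pmf_B) / (p + (1−p)·e_B) + c·pmf_C]

    with contamination level ``c`` and class-B detection efficiency ``e_B``
    (class A detects at efficiency 1).  Observed counts are independent
    Poisson draws; the recorded ``gain`` states how many intensity units
    each event is worth, so rendered intensities are ``gain × counts``.
    """
    if len(proportions) == 0:
        raise ValueError("proportions must be non-empty")
    if any(p < 0 or p > 1 for p in proportions):
        raise ValueError("proportions must lie in [0, 1]")
    if replicates < 1 or gain <= 0:
        raise ValueError("replicates must be >= 1 and gain positive")

    pmf_A, pmf_B, pmf_C = (np.asarray(p.probs, dtype=float) for p in pmfs)
    centroids = default_centroids(pmf_A.size)
    rng = np.random.default_rng(seed)
    c = contamination_level
    corpus: list[PeakHistogram] = []
    truth: list[MixtureTruth] = []
    for p in proportions:
        for rep in range(1, replicates + 1):
            N = rng.uniform(*total_events_range)
            norm = p + (1.0 - p) * efficiency_B
            class_mix = (p * pmf_A + (1.0 - p) * efficiency_B * pmf_B) / norm
            expected = N * ((1.0 - c) * class_mix + c * pmf_C)
            counts = rng.poisson(expected).astype(float)
            sid = f"p{p:.2f}_r{rep}"
            corpus.append(
                PeakHistogram(centroids, counts, gain=gain, sample_id=sid, replicate=rep)
            )
            truth.append(MixtureTruth(sample_id=sid, fraction_A=float(p)))
    return corpus, truth


def add_profile_artifacts(
    histogram: PeakHistogram,
    baseline_amplitude: float = 0.0,
    baseline_noise_sd: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    axis_step: float = 0.05,
    peak_sigma: float = 0.3,
    pad: float = 10.0,
) -> RawSpectrum:
    """Render a peak histogram as a raw profile spectrum with acquisition artifacts.

    Each peak becomes a Gaussian of standard deviation ``peak_sigma`` Da
    whose sampled intensity integrates to ``count × gain``.  A smooth
    baseline (half-period sinusoid of height ``baseline_amplitude``) plus
    zero-mean Gaussian noise of ``baseline_noise_sd`` is added, and the
    whole spectrum is displaced by a global m/z shift drawn with standard
    deviation ``jitter_sd`` — the artifacts the preprocessing stage must
    undo.
    """
    if min(baseline_amplitude, baseline_noise_sd, jitter_sd) < 0:
        raise ValueError("artifact parameters must be non-negative")
    rng = np.random.default_rng(seed)
    lo = histogram.centroids.min() - pad
    hi = histogram.centroids.max() + pad
    mz = np.arange(lo, hi + axis_step / 2, axis_step)

    shift = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
    intensity = np.zeros_like(mz)
    for c, n in zip(histogram.centroids, histogram.counts):
        if n <= 0:
            continue
        area = n * histogram.gain
        intensity += (
            area
            * axis_step
            / (peak_sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((mz - (c + shift)) / peak_sigma) ** 2)
        )
    if baseline_amplitude > 0:
        intensity += baseline_amplitude * np.sin(np.pi * (mz - lo) / (hi - lo))
    if baseline_noise_sd > 0:
        intensity += rng.normal(0.0, baseline_noise_sd, size=mz.size)
    return RawSpectrum(mz, intensity, histogram.sample_id, histogram.replicate)
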