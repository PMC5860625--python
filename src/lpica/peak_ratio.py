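"""Single-peak benchmark: peak ratios calibrated against ground truth.

The classical way to quantify a binary mixture from mass spectra: normalise
every peak to the largest (reference) peak, find the peak whose ratio
correlates best with the known mixing proportions, and use the fitted line
as a linear predictor.  The in-sample standard deviation of calibrated
predictions around the truth estimates the precision attainable from that
single peak — the benchmark the full mixture model is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import PeakHistogram

__all__ = [
    "PeakRatioCalibration",
    "RatioTable",
    "RatioPrediction",
    "compute_ratios",
    "rank_and_calibrate",
    "predict_from_ratio",
]


@dataclass(frozen=True)
class PeakRatioCalibration:
    """Linear predictor proportion = slope · (peak / reference) + intercept."""

    reference_centroid: float
    peak_centroid: float
    slope: float
    intercept: float
    precision: float

    def __post_init__(self) -> None:
        if self.reference_centroid == self.peak_centroid:
            raise ValueError("peak must differ from the reference peak")
        if self.precision < 0:
            raise ValueError("precision must be non-negative")


@dataclass
class RatioTable:
    """Per-spectrum peak ratios relative to the reference peak.

    Spectra with zero reference count cannot be normalised: they are
    excluded and flagged in ``excluded_ids``; ``kept`` marks survivors in
    the original order.
    """

    ratios: np.ndarray
    centroids: np.ndarray
    sample_ids: list[str]
    kept: np.ndarray
    excluded_ids: list[str]
    reference_centroid: float
    reference_index: int


@dataclass(frozen=True)
class RatioPrediction:
    proportion: float
    unclipped: float
    clipped: bool


def compute_ratios(
    histograms: Sequence[PeakHistogram], reference_centroid: float | None = None
) -> RatioTable:
    """Divide every peak by the reference peak, spectrum by spectrum.

    By default the reference is the largest mean peak across the corpus
    (in MALDI lipid windows typically the dominant phosphocholine peak);
    an explicit centroid overrides it (nearest-centroid match).
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    centroids = histograms[0].centroids
    C = np.stack([h.counts for h in histograms])
    if reference_centroid is None:
        ref_idx = int(np.argmax(C.mean(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(centroids - reference_centroid)))
    kept = C[:, ref_idx] > 0
    excluded = [h.sample_id for h, k in zip(histograms, kept) if not k]
    ratios = C[kept] / C[kept, ref_idx][:, None]
    return RatioTable(
        ratios=ratios,
        centroids=centroids,
        sample_ids=[h.sample_id for h, k in zip(histograms, kept) if k],
        kept=kept,
        excluded_ids=excluded,
        reference_centroid=float(centroids[ref_idx]),
        reference_index=ref_idx,
    )


def rank_and_calibrate(
    table: RatioTable, truth
) -> tuple[PeakRatioCalibration, list[PeakRatioCalibration]]:
    """Per-peak least-squares calibration against truth, ranked by precision.

    ``truth`` aligns with the original histogram order (entries for excluded
    spectra are dropped).  For each peak, truth is regressed on the ratio;
    the residual standard deviation of the resulting predictor is its
    precision.  An uninformative peak degrades gracefully to predicting the
    mean proportion with precision ≈ std(truth).  Returns the best
    calibration and the full ranking (ascending precision, reference peak
    excluded).
    """
    from .quantify import _truth_array  # shared truth coercion

    t_all = _truth_array(truth)
    if t_all.size != table.kept.size:
        raise ValueError("truth must align with the original histogram order")
    t = t_all[table.kept]
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct ground-truth proportions")

    ranking = []
    for j in range(table.centroids.size):
        if j == table.reference_index:
            continue
        r = table.ratios[:, j]
        if np.ptp(r) < 1e-12:
            slope, intercept = 0.0, float(t.mean())
        else:
            slope, intercept = (float(v) for v in np.polyfit(r, t, 1))
        resid = slope * r + intercept - t
        precision = float(np.std(resid, ddof=1))
        ranking.append(
            PeakRatioCalibration(
                reference_centroid=table.reference_centroid,
                peak_centroid=float(table.centroids[j]),
                slope=slope,
                intercept=intercept,
                precision=precision,
            )
        )
    ranking.sort(key=lambda c: c.precision)
    return ranking[0], ranking


def predict_from_ratio(ratio: float, calibration: PeakRatioCalibration) -> RatioPrediction:
    """Apply the linear predictor; proportions are clipped to [0, 1]."""
    unclipped = calibration.slope * ratio + calibration.intercept
    p = float(np.clip(unclipped, 0.0, 1.0))
    return RatioPrediction(proportion=p, unclipped=float(unclipped), clipped=p != unclipped)
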