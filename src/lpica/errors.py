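"""Error theory: weight covariances, pull distributions, Bland–Altman noise fits.

Three validation instruments for a Poisson mixture analysis:

* :func:`propagate_weight_errors` — the covariance of fitted component
  weights, taken as the inverse observed Fisher information of the Poisson
  likelihood at the solution, inflated by the model chi-squared per degree
  of freedom when the fit is worse than pure Poisson noise allows.
* :func:`pull_statistics` — standardised residuals (prediction − truth) /
  predicted error.  Unbiased estimates with correctly predicted errors give
  a pull distribution with mean 0 and width 1.
* :func:`bland_altman_points` / :func:`fit_power_law` — residual-versus-
  expected scatter and a power-law fit ``Var(residual) = a · expected^b``
  to it.  Poisson counting noise gives ``b = 1`` with ``a`` equal to the
  detector gain (intensity units per ion event); uniform Gaussian noise
  gives ``b = 0``.  This is the empirical check that a Poisson likelihood
  is the right noise model for the data at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .lpm import (
    LPMModel,
    SpectrumFit,
    ComponentPMF,
    _as_counts,
    _component_matrix,
    _covariance_from_information,
    _fisher_information,
)
from .preprocess import PeakHistogram

__all__ = [
    "PullStats",
    "PowerLawFit",
    "BlandAltmanPoints",
    "propagate_weight_errors",
    "pull_statistics",
    "bland_altman_points",
    "fit_power_law",
]


@dataclass(frozen=True)
class PullStats:
    """Mean and width (n−1 sample convention) of a pull distribution."""

    mean: float
    std: float
    n: int


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted residual-variance law ``Var(x) = a · x^b`` with 1σ uncertainties."""

    a: float
    b: float
    a_err: float
    b_err: float
    band_centers: np.ndarray = None
    band_variances: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("power-law scale a must be positive")


@dataclass(frozen=True)
class BlandAltmanPoints:
    """Paired (expected bin value, observed − expected residual), intensity units."""

    expected: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.expected, dtype=float)
        r = np.asarray(self.residual, dtype=float)
        if e.shape != r.shape:
            raise ValueError("expected and residual must be paired, equal length")
        object.__setattr__(self, "expected", e)
        object.__setattr__(self, "residual", r)

    def __len__(self) -> int:
        return int(self.expected.size)


def propagate_weight_errors(
    histogram,
    components: Sequence[ComponentPMF],
    weights: np.ndarray,
    chi2_scale: float | None = None,
) -> np.ndarray:
    """Weight covariance at a likelihood stationary point (events²).

    The covariance is the inverse of the observed Fisher information
    ``I_kl = sum_i h_i P(i|k) P(i|l) / m_i²`` evaluated at the fitted
    weights (pseudo-inverse with a warning when singular).  When
    ``chi2_scale`` (the model chi-squared per degree of freedom) exceeds 1,
    the covariance is inflated by it — imperfect models under-predict their
    own noise; covariances are never deflated below the Poisson floor.
    """
    h = _as_counts(histogram)
    P = _component_matrix(components)
    Q = np.asarray(weights, dtype=float)
    cov = _covariance_from_information(_fisher_information(h, P, Q))
    if chi2_scale is not None and chi2_scale > 1.0:
        cov = cov * chi2_scale
    return cov


def pull_statistics(
    predicted: np.ndarray, truth: np.ndarray, predicted_errors: np.ndarray
) -> PullStats:
    """Pulls ``(predicted − truth) / predicted_error``: mean, width, count."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    e = np.asarray(predicted_errors, dtype=float)
    if not (p.shape == t.shape == e.shape):
        raise ValueError("predicted, truth and predicted_errors must align")
    if np.any(e <= 0):
        raise ValueError("predicted errors must be strictly positive")
    pulls = (p - t) / e
    n = int(pulls.size)
    std = float(np.std(pulls, ddof=1)) if n >= 2 else float("nan")
    return PullStats(mean=float(pulls.mean()), std=std, n=n)


def bland_altman_points(
    corpus: Sequence[PeakHistogram],
    model: LPMModel,
    fits: Sequence[SpectrumFit],
    min_events: float = 0.5,
) -> BlandAltmanPoints:
    """One (expected, residual) point per spectrum bin with expected > 0.

    Model predictions serve as the expected bin values; both axes are in
    intensity units (counts × gain) so the fitted power law reads the gain
    directly.  Bins expecting fewer than ``min_events`` ion events are
    excluded: far below one event the empirical residual spread no longer
    measures the Poisson variance (almost every draw is zero), and such
    points act as pure leverage on the power-law fit.
    """
    corpus = list(corpus)
    fits = list(fits)
    if len(corpus) != len(fits):
        raise ValueError("fits must correspond to corpus")
    exp_all, res_all = [], []
    for h, f in zip(corpus, fits):
        gain = h.gain if isinstance(h, PeakHistogram) else 1.0
        counts = _as_counts(h)
        mask = f.expected > max(min_events, 0.0)
        exp_all.append(f.expected[mask] * gain)
        res_all.append((counts[mask] - f.expected[mask]) * gain)
    return BlandAltmanPoints(np.concatenate(exp_all), np.concatenate(res_all))


def fit_power_law(points: BlandAltmanPoints, n_bands: int = 20) -> PowerLawFit:
    """Fit ``Var(residual) = a · expected^b`` over quantile bands.

    Points are split into ``n_bands`` equal-count bands by expected value;
    within each band the residual sample variance is paired with the mean
    expected value, and ``log variance`` is regressed on ``log centre``.
    ``b = 1`` indicates Poisson-style growth of noise with signal;
    uncertainties come from the regression.
    """
    if len(points) < n_bands * 10:
        raise ValueError(f"need at least {n_bands * 10} points for {n_bands} bands")
    order = np.argsort(points.expected)
    centers, variances = [], []
    for idx in np.array_split(order, n_bands):
        if idx.size < 2:
            continue
        c = float(points.expected[idx].mean())
        v = float(np.var(points.residual[idx], ddof=1))
        if c > 0 and v > 0:
            centers.append(c)
            variances.append(v)
    if len(centers) < 3:
        raise ValueError("fewer than 3 non-degenerate bands")
    centers = np.asarray(centers)
    variances = np.asarray(variances)
    reg = stats.linregress(np.log(centers), np.log(variances))
    a = float(np.exp(reg.intercept))
    return PowerLawFit(
        a=a,
        b=float(reg.slope),
        a_err=float(a * reg.intercept_stderr),
        b_err=float(reg.stderr),
        band_centers=centers,
        band_variances=variances,
    )
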