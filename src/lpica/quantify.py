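"""Mapping components to sample classes and predicting mixture proportions.

A binary mixture corpus (class A : class B by mass) is modelled by K
component PMFs, but the components are ion-count signatures, not masses:
fragmentation, ionisation efficiency and spectral windowing mean each
component converts mass to detected events with its own efficiency.  This
module closes that gap against ground truth:

* :func:`assign_components` labels each component A, B or rejected
  (contamination / ambiguity — its share of the spectrum does not track the
  mixing proportion).
* :func:`calibrate` finds per-component efficiency weights ``w_k > 0`` and
  an affine map such that the weighted class fraction

      f = sum_{k in A} w_k Q_k / sum_{k in A∪B} w_k Q_k

  tracks the ground-truth mass proportion as linearly as possible
  (least squares); the residual standard deviation is the achievable
  measurement precision.
* :func:`predict_proportion` applies the calibration to a fitted spectrum
  and propagates the Poisson weight covariance through the ratio and the
  affine map (first order) to a per-spectrum predicted error.
* :func:`ensemble_predict` averages predictions over many locally optimal
  models (LP-ICA restarts) to reduce solution-to-solution variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .lpm import LPMModel, SpectrumFit, fit_weights

__all__ = [
    "MixtureTruth",
    "ClassCalibration",
    "Prediction",
    "EnsemblePrediction",
    "NoValidAssignmentError",
    "assign_components",
    "calibrate",
    "predict_proportion",
    "ensemble_predict",
    "swap_classes",
]


class NoValidAssignmentError(ValueError):
    """No component labelling with both classes present could be found."""


@dataclass(frozen=True)
class MixtureTruth:
    """Ground-truth proportion of class A (by weight) for one sample."""

    sample_id: str
    fraction_A: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_A <= 1.0:
            raise ValueError("fraction_A must lie in [0, 1]")


@dataclass
class ClassCalibration:
    """Component→class assignment plus efficiency weights and affine map.

    ``efficiency[k]`` is the mass-per-event factor for component k (NaN for
    rejected components); ``slope``/``intercept`` map the weighted class-A
    fraction to a proportion; ``precision`` is the 1σ residual of calibrated
    predictions against ground truth, in proportion units.
    """

    assignment: list[str]
    efficiency: np.ndarray
    slope: float
    intercept: float
    precision: float
    correlations: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = set(self.assignment)
        if not labels <= {"A", "B", "rejected"}:
            raise ValueError("assignment labels must be 'A', 'B' or 'rejected'")
        if "A" not in labels or "B" not in labels:
            raise ValueError("at least one component must be assigned to each class")
        eff = np.asarray(self.efficiency, dtype=float)
        for k, lab in enumerate(self.assignment):
            if lab != "rejected" and not eff[k] > 0:
                raise ValueError("efficiency must be positive for class components")
        object.__setattr__(self, "efficiency", eff)

    @property
    def idx_A(self) -> np.ndarray:
        return np.array([k for k, a in enumerate(self.assignment) if a == "A"], dtype=int)

    @property
    def idx_B(self) -> np.ndarray:
        return np.array([k for k, a in enumerate(self.assignment) if a == "B"], dtype=int)


@dataclass(frozen=True)
class Prediction:
    """A calibrated proportion with its propagated 1σ error."""

    proportion: float
    error: float
    unclipped: float
    clipped: bool


@dataclass(frozen=True)
class EnsemblePrediction:
    """Summary of predictions across an ensemble of calibrated models."""

    mean: float
    spread: float
    median: float
    best: Prediction
    predictions: list[Prediction] = field(default_factory=list)


def _truth_array(truth) -> np.ndarray:
    if len(truth) and isinstance(truth[0], MixtureTruth):
        return np.array([t.fraction_A for t in truth], dtype=float)
    return np.asarray(truth, dtype=float)


def _weight_matrix(fits: Sequence[SpectrumFit]) -> np.ndarray:
    return np.stack([f.weights for f in fits])


def _class_fraction(
    Q: np.ndarray, w: np.ndarray, idx_A: np.ndarray, idx_B: np.ndarray
) -> np.ndarray:
    num = Q[:, idx_A] @ w[idx_A]
    den = num + Q[:, idx_B] @ w[idx_B]
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def _affine_fit(f: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
    """OLS of truth on fraction; returns (slope, intercept, ssr)."""
    ok = np.isfinite(f)
    f, t = f[ok], t[ok]
    if f.size < 3 or np.ptp(f) < 1e-12:
        inter = float(t.mean()) if t.size else 0.5
        return 0.0, inter, float(np.sum((t - inter) ** 2))
    slope, intercept = np.polyfit(f, t, 1)
    resid = slope * f + intercept - t
    return float(slope), float(intercept), float(np.sum(resid**2))


def _optimise_efficiencies(
    Q: np.ndarray,
    t: np.ndarray,
    idx_A: np.ndarray,
    idx_B: np.ndarray,
    n_starts: int,
    seed: int,
) -> tuple[np.ndarray, float, float, float]:
    """Least-squares efficiency weights via seeded multistart over log w.

    The weighted fraction is scale-invariant in w, so the first class
    component's efficiency is pinned at 1 and the remaining log-efficiencies
    are free.  Returns (w over A∪B order [idx_A, idx_B], slope, intercept,
    ssr)."""
    sel = np.concatenate([idx_A, idx_B])
    nfree = sel.size - 1
    selA = np.arange(idx_A.size)
    selB = np.arange(idx_A.size, sel.size)
    Qsel = Q[:, sel]

    def unpack(theta: np.ndarray) -> np.ndarray:
        return np.exp(np.concatenate(([0.0], theta)))

    def objective(theta: np.ndarray) -> float:
        w = unpack(theta)
        num = Qsel[:, selA] @ w[selA]
        den = Qsel @ w
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return _affine_fit(f, t)[2]

    rng = np.random.default_rng(seed)
    starts = [np.zeros(nfree)] + [rng.normal(0.0, 1.0, nfree) for _ in range(n_starts - 1)]
    best_theta, best_val = starts[0], objective(starts[0])
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun
    w = unpack(np.atleast_1d(best_theta))
    num = Qsel[:, selA] @ w[selA]
    den = Qsel @ w
    f = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    slope, intercept, ssr = _affine_fit(f, t)
    return w, slope, intercept, ssr


def assign_components(
    fits: Sequence[SpectrumFit],
    truth,
    corr_threshold: float = 0.2,
    seed: int = 0,
    max_exhaustive: int = 10,
) -> list[str]:
    """Label each component 'A', 'B' or 'rejected'.

    Components whose fractional weight across the corpus is uncorrelated
    with the ground-truth proportion (|Pearson r| below ``corr_threshold``)
    are rejected as contamination or ambiguity.  The remaining components
    are assigned by exhaustive search over A/B labellings (when at most
    ``max_exhaustive`` candidates), scoring each labelling by the residual
    of a quick efficiency calibration; beyond that, by the sign of the
    correlation (positive → A).
    """
    Q = _weight_matrix(fits)
    t = _truth_array(truth)
    if Q.shape[0] != t.size:
        raise ValueError("fits and truth must align")
    K = Q.shape[1]
    if K < 2:
        raise NoValidAssignmentError("need at least 2 components")

    totals = Q.sum(axis=1)
    frac = Q / np.where(totals > 0, totals, 1.0)[:, None]
    corrs = np.zeros(K)
    for k in range(K):
        if np.ptp(frac[:, k]) > 1e-12 and np.ptp(t) > 0:
            corrs[k] = float(np.corrcoef(frac[:, k], t)[0, 1])
    candidates = [k for k in range(K) if abs(corrs[k]) >= corr_threshold]
    if len(candidates) < 2:
        raise NoValidAssignmentError(
            "fewer than 2 components correlate with the ground truth"
        )

    if len(candidates) <= max_exhaustive:
        best_assign, best_ssr = None, np.inf
        for labels in itertools.product("AB", repeat=len(candidates)):
            if "A" not in labels or "B" not in labels:
                continue
            idx_A = np.array([c for c, l in zip(candidates, labels) if l == "A"])
            idx_B = np.array([c for c, l in zip(candidates, labels) if l == "B"])
            try:
                _, _, _, ssr = _optimise_efficiencies(Q, t, idx_A, idx_B, 2, seed)
            except Exception:
                continue
            if ssr < best_ssr:
                best_ssr = ssr
                best_assign = dict(zip(candidates, labels))
        if best_assign is None:
            raise NoValidAssignmentError("no labelling with both classes succeeded")
        chosen = best_assign
    else:
        chosen = {k: ("A" if corrs[k] > 0 else "B") for k in candidates}
        if "A" not in chosen.values() or "B" not in chosen.values():
            raise NoValidAssignmentError("greedy assignment left one class empty")

    # orientation: the A/B labelling is a symmetry of the calibrated fit
    # (the affine map absorbs a sign flip), so anchor class A to the side
    # whose weight fraction rises with the ground-truth proportion of A
    corr_A = np.mean([corrs[k] for k, l in chosen.items() if l == "A"])
    corr_B = np.mean([corrs[k] for k, l in chosen.items() if l == "B"])
    if corr_A < corr_B:
        chosen = {k: ("A" if l == "B" else "B") for k, l in chosen.items()}
    return [chosen.get(k, "rejected") for k in range(K)]


def calibrate(
    fits: Sequence[SpectrumFit],
    truth,
    assignment: list[str],
    n_starts: int = 10,
    seed: int = 0,
) -> ClassCalibration:
    """Fit efficiency weights and the affine map against ground truth.

    Optimises log-efficiencies (positivity by construction) with seeded
    Nelder–Mead multistarts to minimise the squared residual between the
    affine-mapped weighted class fraction and the true proportions.
    Residuals use unclipped predictions; ``precision`` is their sample
    standard deviation.  Degenerate ground truth (a single proportion)
    makes the calibration unidentifiable and raises.
    """
    Q = _weight_matrix(fits)
    t = _truth_array(truth)
    if np.ptp(t) == 0:
        raise ValueError("degenerate ground truth: calibration unidentifiable")
    idx_A = np.array([k for k, a in enumerate(assignment) if a == "A"], dtype=int)
    idx_B = np.array([k for k, a in enumerate(assignment) if a == "B"], dtype=int)
    if idx_A.size == 0 or idx_B.size == 0:
        raise NoValidAssignmentError("assignment must contain both classes")

    w_sel, slope, intercept, _ = _optimise_efficiencies(
        Q, t, idx_A, idx_B, n_starts, seed
    )
    efficiency = np.full(len(assignment), np.nan)
    efficiency[np.concatenate([idx_A, idx_B])] = w_sel

    f = _class_fraction(Q, np.nan_to_num(efficiency), idx_A, idx_B)
    resid = slope * f + intercept - t
    resid = resid[np.isfinite(resid)]
    precision = float(np.std(resid, ddof=1)) if resid.size >= 2 else float("nan")

    totals = Q.sum(axis=1)
    frac = Q / np.where(totals > 0, totals, 1.0)[:, None]
    corrs = np.array(
        [
            float(np.corrcoef(frac[:, k], t)[0, 1]) if np.ptp(frac[:, k]) > 1e-12 else 0.0
            for k in range(len(assignment))
        ]
    )
    return ClassCalibration(
        assignment=list(assignment),
        efficiency=efficiency,
        slope=slope,
        intercept=intercept,
        precision=precision,
        correlations=corrs,
    )


def predict_proportion(fit: SpectrumFit, calibration: ClassCalibration) -> Prediction:
    """Calibrated proportion for one spectrum with first-order error propagation.

    The weight covariance is pushed through the gradient of the weighted
    class fraction and scaled by the affine slope; the proportion is clipped
    to [0, 1] with the unclipped value retained.
    """
    w = np.nan_to_num(calibration.efficiency)
    idx_A, idx_B = calibration.idx_A, calibration.idx_B
    Q = fit.weights
    a = float(Q[idx_A] @ w[idx_A])
    b = float(Q[idx_B] @ w[idx_B])
    den = a + b
    if den <= 0:
        raise ValueError("total non-rejected weight is zero: proportion undefined")
    f = a / den
    unclipped = calibration.slope * f + calibration.intercept
    proportion = float(np.clip(unclipped, 0.0, 1.0))

    grad = np.zeros_like(Q)
    grad[idx_A] = w[idx_A] * b / den**2
    grad[idx_B] = -w[idx_B] * a / den**2
    var = calibration.slope**2 * float(grad @ fit.covariance @ grad)
    return Prediction(
        proportion=proportion,
        error=float(np.sqrt(max(var, 0.0))),
        unclipped=float(unclipped),
        clipped=bool(proportion != unclipped),
    )


def swap_classes(calibration: ClassCalibration) -> ClassCalibration:
    """Exchange the A and B labels; predictions map exactly to ``1 − p``."""
    swapped = ["B" if a == "A" else "A" if a == "B" else a for a in calibration.assignment]
    return ClassCalibration(
        assignment=swapped,
        efficiency=calibration.efficiency.copy(),
        slope=calibration.slope,
        intercept=1.0 - calibration.slope - calibration.intercept,
        precision=calibration.precision,
        correlations=None
        if calibration.correlations is None
        else -calibration.correlations,
    )


def build_ensemble(
    corpus,
    truth,
    K: int,
    n_models: int = 50,
    seed: int = 0,
    corr_threshold: float = 0.2,
    n_starts: int = 4,
) -> list[tuple[LPMModel, ClassCalibration]]:
    """Train and calibrate an ensemble of independent LP-ICA solutions.

    The likelihood surface has local optima; each member is trained from its
    own seeded start (derived deterministically from ``seed``), separated
    with MAX SEP and calibrated against the same ground truth.  The default
    of 50 members matches the restart count used to assess the spread of
    local solutions in this study design.  Members whose component
    assignment fails (no labelling with both classes) are skipped.
    """
    from .lpm import fit_corpus, train_components
    from .maxsep import max_sep

    child_seeds = np.random.SeedSequence(seed).generate_state(n_models) % (2**31)
    ensemble: list[tuple[LPMModel, ClassCalibration]] = []
    for s in child_seeds:
        model = train_components(corpus, K, seed=int(s))
        fits = fit_corpus(model, corpus)
        totals = np.stack([f.weights for f in fits]).sum(axis=0)
        model.components = max_sep(model.components, weights=totals)
        fits = fit_corpus(model, corpus)
        try:
            assignment = assign_components(
                fits, truth, corr_threshold=corr_threshold, seed=int(s)
            )
            cal = calibrate(fits, truth, assignment, n_starts=n_starts, seed=int(s))
        except NoValidAssignmentError:
            continue
        ensemble.append((model, cal))
    if not ensemble:
        raise NoValidAssignmentError("no ensemble member produced a valid calibration")
    return ensemble


def ensemble_predict(
    models: Sequence[tuple[LPMModel, ClassCalibration]], histogram
) -> EnsemblePrediction:
    """Predict one spectrum's proportion from an ensemble of calibrated models.

    Each model fits its own weights to the histogram and predicts; the
    ensemble answer is the mean across models, with the across-model
    standard deviation as the spread.  The median and the single prediction
    from the model with the best (smallest) calibration precision are also
    reported.
    """
    if not models:
        raise ValueError("ensemble must contain at least one model")
    preds = []
    for model, cal in models:
        fit = fit_weights(histogram, model.components)
        preds.append(predict_proportion(fit, cal))
    values = np.array([p.proportion for p in preds])
    spread = float(np.std(values, ddof=1)) if len(preds) > 1 else 0.0
    best_i = int(np.argmin([cal.precision for _, cal in models]))
    return EnsemblePrediction(
        mean=float(values.mean()),
        spread=spread,
        median=float(np.median(values)),
        best=preds[best_i],
        predictions=preds,
    )
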