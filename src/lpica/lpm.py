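"""Linear Poisson Models: EM estimation of PMF components and mixture weights.

A Linear Poisson Model describes a peak histogram ``h`` as a non-negative
weighted sum of probability mass functions (sub-spectra):

    m_i = sum_k Q_k P(i|k),     h_i ~ Poisson(m_i)

where ``P(i|k)`` is the probability that an ion from component ``k`` lands in
bin ``i`` and ``Q_k`` is the number of ion events attributed to component
``k``.  Unlike PCA/ICA on unit vectors, components are PMFs and weights are
positive — the natural parameterisation for counting data.

Estimation is maximum likelihood by expectation-maximisation.  With
responsibilities ``r_ik = Q_k P(i|k) / m_i`` the updates are

    Q_k     <- sum_i h_i r_ik                       (per spectrum)
    P(i|k)  <- sum_s h_si r_sik, renormalised       (training only)

which never decrease the Poisson log-likelihood ``sum_i [h_i ln m_i - m_i]``.
Learning the components themselves from a corpus of spectra
(:func:`train_components`) is a Poisson-compatible analogue of independent
component analysis (LP-ICA).  Model order is chosen by the behaviour of the
chi-squared per degree of freedom as a function of K: the smallest K on the
goodness-of-fit plateau (:func:`select_model_order`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .preprocess import PeakHistogram

__all__ = [
    "ComponentPMF",
    "LPMModel",
    "SpectrumFit",
    "expected_histogram",
    "poisson_loglik",
    "fit_weights",
    "fit_corpus",
    "train_components",
    "train_best",
    "chi2_per_dof",
    "select_model_order",
    "ModelOrderResult",
]

#: probabilities below this are floored during EM to avoid -inf likelihoods
PMF_FLOOR = 1e-12
#: probabilities below this are snapped to exact zero after training,
#: so that zero-structure criteria (MAX SEP) are meaningful
PMF_HARD_ZERO = 1e-9
#: denominator floor in the chi-squared statistic
CHI2_FLOOR = 1e-3


@dataclass(frozen=True)
class ComponentPMF:
    """One sub-spectrum: a probability mass function over histogram bins."""

    probs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1:
            raise ValueError("probs must be a 1-D array")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return int(self.probs.size)


@dataclass
class LPMModel:
    """A trained Linear Poisson Model: K component PMFs over shared bins."""

    components: list[ComponentPMF]
    centroids: np.ndarray
    K: int
    chi2_per_dof: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K != len(self.components):
            raise ValueError("K must equal the number of components")
        dims = {len(c) for c in self.components}
        if len(dims) > 1:
            raise ValueError("components must share one bin dimension")
        if self.chi2_per_dof < 0:
            raise ValueError("chi2_per_dof must be non-negative")
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        """Components stacked as a (K, bins) array."""
        return np.stack([c.probs for c in self.components])


@dataclass
class SpectrumFit:
    """Fitted non-negative weights for one spectrum, with propagated errors.

    ``weights[k]`` is the number of ion events attributed to component k;
    ``covariance`` is the inverse observed Fisher information at the solution
    (units events^2).
    """

    weights: np.ndarray
    expected: np.ndarray
    loglik: float
    covariance: np.ndarray
    chi2_per_dof: float

    @property
    def errors(self) -> np.ndarray:
        """One-sigma weight uncertainties (events)."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def _component_matrix(components: Sequence[ComponentPMF]) -> np.ndarray:
    if not components:
        raise ValueError("at least one component is required")
    P = np.stack([np.asarray(c.probs, dtype=float) for c in components])
    return P


def expected_histogram(
    weights: np.ndarray, components: Sequence[ComponentPMF]
) -> np.ndarray:
    """Model-predicted counts per bin: ``m_i = sum_k Q_k P(i|k)``.

    Because every component sums to one, ``sum_i m_i == sum_k Q_k`` exactly.
    """
    Q = np.asarray(weights, dtype=float)
    P = _component_matrix(components)
    if Q.shape != (P.shape[0],):
        raise ValueError("weights length must match number of components")
    if np.any(Q < 0):
        raise ValueError("weights must be non-negative")
    return Q @ P


def poisson_loglik(counts: np.ndarray, expected: np.ndarray) -> float:
    """Poisson log-likelihood ``sum_i [h_i ln m_i - m_i]`` (0·ln 0 = 0).

    A bin with ``m_i = 0`` but ``h_i > 0`` has zero probability under the
    model: the function returns ``-inf`` rather than raising.
    """
    h = np.asarray(counts, dtype=float)
    m = np.asarray(expected, dtype=float)
    if h.shape != m.shape:
        raise ValueError("counts and expected must have the same shape")
    if np.any((m == 0) & (h > 0)):
        return float("-inf")
    pos = h > 0
    return float(np.sum(h[pos] * np.log(m[pos])) - m.sum())


def _fisher_information(h: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Observed Fisher information of the Poisson likelihood in the weights.

    ``I_kl = sum_i h_i P(i|k) P(i|l) / m_i^2`` (the negative Hessian of the
    log-likelihood; the ``-sum m`` term is linear in Q and drops out).
    """
    m = Q @ P
    # only bins with observed counts contribute; guard m**2 underflow
    mask = (h > 0) & (m > 1e-100)
    if not np.any(mask):
        return np.zeros((P.shape[0], P.shape[0]))
    Pm = P[:, mask]
    w = h[mask] / m[mask] ** 2
    return (Pm * w) @ Pm.T


def _covariance_from_information(info: np.ndarray) -> np.ndarray:
    """Invert the information matrix, falling back to a pseudo-inverse."""
    try:
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned information matrix")
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("singular Fisher information: using pseudo-inverse covariance")
        cov = np.linalg.pinv(info)
    return 0.5 * (cov + cov.T)


def _spectrum_chi2(h: np.ndarray, m: np.ndarray, floor: float = CHI2_FLOOR) -> float:
    return float(np.sum((h - m) ** 2 / np.maximum(m, floor)))


def _as_counts(histogram) -> np.ndarray:
    if isinstance(histogram, PeakHistogram):
        return histogram.counts
    return np.asarray(histogram, dtype=float)


def fit_weights(
    histogram,
    components: Sequence[ComponentPMF],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> SpectrumFit:
    """Maximum-likelihood non-negative weights for one histogram, fixed components.

    Multiplicative EM updates keep the weights non-negative and the
    log-likelihood non-decreasing; iteration stops when the relative
    log-likelihood change drops below ``tol``.  An all-zero histogram yields
    all-zero weights.
    """
    h = _as_counts(histogram)
    P = _component_matrix(components)
    K, B = P.shape
    if h.shape != (B,):
        raise ValueError("histogram length must match component bin dimension")
    if np.any(P.sum(axis=1) <= 0):
        raise ValueError("component with zero probability everywhere")

    total = h.sum()
    if total == 0:
        return SpectrumFit(
            weights=np.zeros(K),
            expected=np.zeros(B),
            loglik=0.0,
            covariance=np.zeros((K, K)),
            chi2_per_dof=0.0,
        )

    Q = np.full(K, total / K)
    ll_prev = -np.inf
    for _ in range(max_iter):
        m = Q @ P
        msafe = np.maximum(m, 1e-300)
        ratio = np.where(h > 0, h / msafe, 0.0)
        Q = Q * (P @ ratio)
        ll = float(np.sum(h[h > 0] * np.log(msafe[h > 0])) - Q.sum())
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            ll_prev = ll
            break
        ll_prev = ll

    # snap numerically dead components to exact zero: EM approaches the
    # non-negativity boundary geometrically and stalls at sub-event dust
    Q = np.where(Q < 1e-9 * total, 0.0, Q)
    m = Q @ P
    cov = _covariance_from_information(_fisher_information(h, P, Q))
    chi2 = _spectrum_chi2(h, m)
    dof = max(B - K, 1)
    return SpectrumFit(
        weights=Q,
        expected=m,
        loglik=poisson_loglik(h, m),
        covariance=cov,
        chi2_per_dof=chi2 / dof,
    )


def fit_corpus(
    model: LPMModel, corpus: Sequence[PeakHistogram], tol: float = 1e-8
) -> list[SpectrumFit]:
    """Fit per-spectrum weights of a trained model to every corpus histogram."""
    return [fit_weights(h, model.components, tol=tol) for h in corpus]


def train_components(
    corpus: Sequence[PeakHistogram],
    K: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> LPMModel:
    """Learn K component PMFs from a corpus by alternating EM (LP-ICA).

    Components are initialised from the corpus-mean PMF with seeded
    multiplicative gamma jitter; weights start as equal shares of each
    spectrum total.  Joint EM updates of weights and components maximise the
    summed Poisson likelihood; the result is a deterministic function of the
    seed.  Probabilities are floored at ``PMF_FLOOR`` during EM and snapped
    to exact zero below ``PMF_HARD_ZERO`` afterwards.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    H = np.stack([_as_counts(h) for h in corpus])
    S, B = H.shape
    if not 1 <= K <= B:
        raise ValueError("model order K must satisfy 1 <= K <= number of bins")
    centroids = (
        corpus[0].centroids
        if isinstance(corpus[0], PeakHistogram)
        else np.arange(B, dtype=float)
    )

    rng = np.random.default_rng(seed)
    base = H.sum(axis=0)
    base = base / base.sum() if base.sum() > 0 else np.full(B, 1.0 / B)
    P = np.maximum(base, PMF_FLOOR) * rng.gamma(5.0, 1.0, size=(K, B))
    P /= P.sum(axis=1, keepdims=True)
    Q = np.tile(H.sum(axis=1)[:, None] / K, (1, K))

    trace: list[float] = []
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        M = Q @ P
        Msafe = np.maximum(M, 1e-300)
        ll = float(np.sum(np.where(H > 0, H * np.log(Msafe), 0.0)) - M.sum())
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            break
        ll_prev = ll

        A = np.where(H > 0, H / Msafe, 0.0)  # (S, B)
        Q_new = Q * (A @ P.T)
        C = P * (Q.T @ A)  # (K, B) component numerators
        P = np.maximum(C, 0.0)
        P = np.maximum(P, PMF_FLOOR)
        P /= P.sum(axis=1, keepdims=True)
        Q = Q_new

    # hard-zero pass so downstream zero-structure criteria are meaningful
    P = np.where(P < PMF_HARD_ZERO, 0.0, P)
    P /= P.sum(axis=1, keepdims=True)

    components = [ComponentPMF(P[k], label=f"comp{k}") for k in range(K)]
    model = LPMModel(
        components=components,
        centroids=centroids,
        K=K,
        chi2_per_dof=0.0,
        training_meta={
            "seed": int(seed),
            "tol": tol,
            "max_iter": max_iter,
            "n_iter": n_iter,
            "loglik": trace[-1] if trace else float("-inf"),
            "loglik_trace": np.asarray(trace),
        },
    )
    fits = fit_corpus(model, corpus)
    model.chi2_per_dof = chi2_per_dof(corpus, model, fits)
    model.training_meta["corpus_loglik"] = float(sum(f.loglik for f in fits))
    return model


def train_best(
    corpus: Sequence[PeakHistogram],
    K: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> LPMModel:
    """Best-of-``restarts`` training: highest corpus log-likelihood wins.

    LP-ICA likelihoods have local optima; repeated seeded starts explore
    them.  Child seeds are derived deterministically from ``seed``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best = None
    for s in child_seeds:
        model = train_components(corpus, K, seed=int(s), tol=tol, max_iter=max_iter)
        if best is None or (
            model.training_meta["corpus_loglik"] > best.training_meta["corpus_loglik"]
        ):
            best = model
    return best


def chi2_per_dof(
    corpus: Sequence[PeakHistogram],
    model: LPMModel,
    fits: Sequence[SpectrumFit],
    floor: float = CHI2_FLOOR,
) -> float:
    """Corpus chi-squared per degree of freedom of a fitted model.

    ``sum_{s,i} (h_si - m_si)^2 / max(m_si, floor)`` divided by
    ``dof = S·B - [K·(B-1) shared component parameters + K weights per
    spectrum]``.  For pure Poisson counts at the true order this converges
    to ≈ 1.
    """
    corpus = list(corpus)
    fits = list(fits)
    if len(corpus) != len(fits):
        raise ValueError("fits must correspond one-to-one with corpus")
    S = len(corpus)
    B = len(model.components[0])
    K = model.K
    dof = S * B - (K * (B - 1) + K * S)
    if dof <= 0:
        raise ValueError("over-parameterised model: non-positive degrees of freedom")
    chi2 = sum(
        _spectrum_chi2(_as_counts(h), f.expected, floor) for h, f in zip(corpus, fits)
    )
    return chi2 / dof


@dataclass
class ModelOrderResult:
    """Outcome of model-order selection: chosen K and the full fit curve."""

    k_star: int
    curve: list[tuple[int, float]]
    models: dict[int, LPMModel]


def select_model_order(
    corpus: Sequence[PeakHistogram],
    K_range: Iterable[int],
    restarts: int = 5,
    seed: int = 0,
    plateau_tol: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ModelOrderResult:
    """Choose the model order from the chi-squared plateau.

    For each K the best of ``restarts`` seeded trainings is scored by
    chi-squared per degree of freedom.  The selected order is the smallest K
    whose score is within ``plateau_tol`` (relative) of the best score over
    the range — i.e. the first K that reaches the minimum or its plateau.
    """
    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise ValueError("K_range must be non-empty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(Ks)) % (2**31)
    curve: list[tuple[int, float]] = []
    models: dict[int, LPMModel] = {}
    for K, s in zip(Ks, child_seeds):
        model = train_best(corpus, K, restarts=restarts, seed=int(s), tol=tol, max_iter=max_iter)
        models[K] = model
        curve.append((K, model.chi2_per_dof))
    best_chi2 = min(c for _, c in curve)
    k_star = next(k for k, c in curve if c <= best_chi2 * (1.0 + plateau_tol))
    return ModelOrderResult(k_star=k_star, curve=curve, models=models)
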