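"""Linear Poisson Model core: expected histograms, likelihood, EM fits, order selection."""

import numpy as np
import pytest

from lpica.lpm import (
    ComponentPMF,
    LPMModel,
    chi2_per_dof,
    expected_histogram,
    fit_corpus,
    fit_weights,
    poisson_loglik,
    select_model_order,
    train_best,
    train_components,
)
from lpica.preprocess import PeakHistogram
from lpica.synthetic import generate_corpus, make_class_pmfs


def hist(counts):
    counts = np.asarray(counts, dtype=float)
    return PeakHistogram(np.arange(counts.size, dtype=float), counts)


class TestExpectedHistogram:
    def test_zero_weights_zero_vector(self, disjoint_pair):
        out = expected_histogram(np.zeros(2), list(disjoint_pair))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_component_scaling(self):
        c = ComponentPMF(np.array([0.5, 0.5]))
        np.testing.assert_allclose(expected_histogram(np.array([10.0]), [c]), [5.0, 5.0])

    def test_two_component_hand_sum(self):
        comps = [ComponentPMF(np.array([1.0, 0.0])), ComponentPMF(np.array([0.25, 0.75]))]
        np.testing.assert_allclose(
            expected_histogram(np.array([4.0, 8.0]), comps), [6.0, 6.0]
        )

    def test_total_conservation_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        comps = [ComponentPMF(p / p.sum()) for p in rng.random((3, 6))]
        Q = rng.uniform(0, 100, 3)
        m = expected_histogram(Q, comps)
        assert m.sum() == pytest.approx(Q.sum(), rel=1e-12)
        perm = [2, 0, 1]
        m2 = expected_histogram(Q[perm], [comps[i] for i in perm])
        np.testing.assert_allclose(m2, m)

    def test_negative_weight_raises(self, disjoint_pair):
        with pytest.raises(ValueError):
            expected_histogram(np.array([-1.0, 1.0]), list(disjoint_pair))


class TestPoissonLoglik:
    def test_hand_value(self):
        # independent hand computation: 2 ln 2 + 3 ln 3 - 5
        expected = 2 * np.log(2) + 3 * np.log(3) - 5
        assert poisson_loglik([2, 3], [2, 3]) == pytest.approx(expected, rel=1e-12)

    def test_empty_convention(self):
        assert poisson_loglik([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_zero_model_positive_count_is_minus_inf(self):
        assert poisson_loglik([1.0, 0.0], [0.0, 1.0]) == float("-inf")

    def test_ml_property_h_equals_m_maximal(self):
        """Among models of equal total, m = h maximises the likelihood."""
        h = np.array([30.0, 50.0, 20.0])
        best = poisson_loglik(h, h)
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.dirichlet(np.ones(3)) * h.sum()
            assert poisson_loglik(h, m) <= best + 1e-9

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            poisson_loglik([1.0], [1.0, 2.0])


def brute_force_weights(h, comps, grid):
    """Independent oracle: exhaustive likelihood search on a weight grid."""
    best, best_ll = None, -np.inf
    for q1 in grid:
        for q2 in grid:
            m = q1 * comps[0].probs + q2 * comps[1].probs
            ll = poisson_loglik(h, m)
            if ll > best_ll:
                best, best_ll = (q1, q2), ll
    return np.array(best)


class TestFitWeights:
    def test_exact_single_component(self):
        c = ComponentPMF(np.array([0.2, 0.3, 0.5]))
        fit = fit_weights(hist(100 * c.probs), [c])
        assert fit.weights[0] == pytest.approx(100.0, abs=1e-6)

    def test_disjoint_supports_separable(self, disjoint_pair):
        a, b = disjoint_pair
        h = hist(60 * a.probs + 40 * b.probs)
        fit = fit_weights(h, [a, b])
        np.testing.assert_allclose(fit.weights, [60.0, 40.0], atol=1e-6)

    def test_matches_brute_force_grid(self):
        comps = [
            ComponentPMF(np.array([0.6, 0.4, 0.0])),
            ComponentPMF(np.array([0.0, 0.5, 0.5])),
        ]
        h = np.array([30.0, 50.0, 20.0])
        oracle = brute_force_weights(h, comps, np.arange(0.0, 120.0, 0.1))
        fit = fit_weights(hist(h), comps)
        np.testing.assert_allclose(fit.weights, oracle, atol=0.1)

    def test_all_zero_histogram_zero_weights(self, disjoint_pair):
        fit = fit_weights(hist([0, 0, 0, 0]), list(disjoint_pair))
        np.testing.assert_array_equal(fit.weights, 0.0)
        assert fit.loglik == 0.0

    def test_expected_total_equals_weight_total(self, disjoint_pair):
        fit = fit_weights(hist([13, 5, 8, 21]), list(disjoint_pair))
        assert fit.expected.sum() == pytest.approx(fit.weights.sum(), rel=1e-6)

    def test_covariance_symmetric_nonneg_diag(self, disjoint_pair):
        fit = fit_weights(hist([13, 5, 8, 21]), list(disjoint_pair))
        np.testing.assert_allclose(fit.covariance, fit.covariance.T)
        assert (np.diag(fit.covariance) >= 0).all()

    def test_scaling_covariance_property(self):
        """Multiplying counts by c scales fitted weights by c."""
        comps = [
            ComponentPMF(np.array([0.6, 0.4, 0.0])),
            ComponentPMF(np.array([0.0, 0.5, 0.5])),
        ]
        h = np.array([30.0, 50.0, 20.0])
        w1 = fit_weights(hist(h), comps).weights
        w7 = fit_weights(hist(7 * h), comps).weights
        np.testing.assert_allclose(w7, 7 * w1, rtol=1e-4)


class TestTrain:
    def test_recovers_single_generator_pmf(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(12) * 2)
        corpus = [hist(rng.poisson(5000 * p)) for _ in range(40)]
        model = train_components(corpus, K=1, seed=0)
        # Monte-Carlo standard error of each recovered bin probability
        total = sum(h.total for h in corpus)
        se = np.sqrt(p * (1 - p) / total)
        assert (np.abs(model.components[0].probs - p) < 3 * se + 1e-3).all()

    def test_recovers_two_disjoint_pmfs(self, disjoint_pair):
        a, b = disjoint_pair
        rng = np.random.default_rng(6)
        corpus = []
        for frac in np.linspace(0, 1, 20):
            m = 4000 * (frac * a.probs + (1 - frac) * b.probs)
            corpus.append(hist(rng.poisson(m)))
        model = train_best(corpus, K=2, restarts=3, seed=0)
        P = np.stack([c.probs for c in model.components])
        G = np.stack([a.probs, b.probs])
        tv = 0.5 * np.abs(P[:, None, :] - G[None, :, :]).sum(-1)
        # best assignment up to permutation
        assert min(tv[0, 0] + tv[1, 1], tv[0, 1] + tv[1, 0]) < 2 * 0.05

    def test_determinism_bitwise(self, default_corpus):
        corpus, _ = default_corpus
        m1 = train_components(corpus[:20], K=2, seed=42)
        m2 = train_components(corpus[:20], K=2, seed=42)
        np.testing.assert_array_equal(m1.matrix, m2.matrix)
        assert m1.chi2_per_dof == m2.chi2_per_dof

    def test_em_monotone_loglik(self, default_corpus):
        corpus, _ = default_corpus
        model = train_components(corpus[:30], K=3, seed=7)
        trace = model.training_meta["loglik_trace"]
        diffs = np.diff(trace)
        assert (diffs >= -1e-7 * np.abs(trace[:-1])).all()

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            train_components([hist([1, 2])], K=3)


class TestChi2:
    def make_model(self, comps, B):
        return LPMModel(
            components=comps, centroids=np.arange(B, dtype=float),
            K=len(comps), chi2_per_dof=0.0,
        )

    def test_perfect_fit_zero(self, disjoint_pair):
        a, b = disjoint_pair
        model = self.make_model(list(disjoint_pair), 4)
        corpus = [hist(60 * a.probs + 40 * b.probs)] * 5  # dof = 20 - 16 > 0
        fits = fit_corpus(model, corpus)
        assert chi2_per_dof(corpus, model, fits) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluation_of_formula(self):
        # single spectrum h=(4,1), m=(2,2): chi2 = (4-2)^2/2 + (1-2)^2/2 = 2.5
        from lpica.lpm import _spectrum_chi2

        assert _spectrum_chi2(np.array([4.0, 1.0]), np.array([2.0, 2.0])) == 2.5

    def test_poisson_corpus_chi2_near_one(self, default_pmfs):
        """At the true order on interior proportions every bin is live and
        chi2/dof is an ordinary Poisson residual statistic, so ~1."""
        corpus, _ = generate_corpus(
            default_pmfs, proportions=np.linspace(0.3, 0.7, 9),
            replicates=10, seed=8,
        )
        model = train_best(corpus, K=3, restarts=3, seed=9)
        assert 0.9 <= model.chi2_per_dof <= 1.1

    def test_overparameterised_dof_raises(self, disjoint_pair):
        model = self.make_model(list(disjoint_pair), 4)
        h = hist([1, 2, 3, 4])
        fits = fit_corpus(model, [h])
        with pytest.raises(ValueError):
            chi2_per_dof([h], model, fits)  # dof = 4 - (2*3 + 2) < 0


class TestModelOrder:
    def test_plateau_rule_on_synthetic_curve(self):
        """Direct application of the plateau rule to a precomputed curve."""
        curve = [(1, 10.0), (2, 3.0), (3, 1.05), (4, 1.02), (5, 1.01)]
        best = min(c for _, c in curve)
        k_star = next(k for k, c in curve if c <= best * 1.05)
        assert k_star == 3

    def test_selects_one_component(self):
        """A study-sized corpus (88 spectra, ~100 retained peaks — the bin
        counts real preprocessed spectra carry) drawn from one sub-spectrum
        reaches the chi-squared plateau at K = 1."""
        rng = np.random.default_rng(10)
        p = rng.dirichlet(np.full(100, 5.0))
        corpus = [
            hist(rng.poisson(rng.uniform(2000, 20000) * p)) for _ in range(88)
        ]
        res = select_model_order(corpus, range(1, 4), restarts=3, seed=11)
        assert res.k_star == 1

    def test_selects_two_components(self, default_pmfs):
        corpus, _ = generate_corpus(
            default_pmfs, contamination_level=0.0, replicates=4, seed=13
        )
        res = select_model_order(corpus, range(1, 4), restarts=3, seed=14)
        assert res.k_star == 2
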