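"""Shared fixtures: small synthetic corpora and hand-built components."""

import numpy as np
import pytest

from lpica.lpm import ComponentPMF, train_best, fit_corpus
from lpica.maxsep import max_sep
from lpica.synthetic import generate_corpus, make_class_pmfs


@pytest.fixture(scope="session")
def disjoint_pair():
    """Two PMFs on disjoint 4-bin supports."""
    a = ComponentPMF(np.array([0.6, 0.4, 0.0, 0.0]), "a")
    b = ComponentPMF(np.array([0.0, 0.0, 0.3, 0.7]), "b")
    return a, b


@pytest.fixture(scope="session")
def default_pmfs():
    """Class/contamination PMFs under the default study conditions."""
    return make_class_pmfs(seed=1)


@pytest.fixture(scope="session")
def default_corpus(default_pmfs):
    """The 11 proportions x 8 replicates design: gain 1, overlap 0.3,
    efficiency_B 0.5, contamination 0.05."""
    return generate_corpus(default_pmfs, seed=2)


@pytest.fixture(scope="session")
def twoclass_gain5_corpus(default_pmfs):
    """Scaled-Poisson two-class corpus (gain 5, no contamination)."""
    return generate_corpus(
        default_pmfs, gain=5.0, contamination_level=0.0, seed=12
    )


@pytest.fixture(scope="session")
def twoclass_gain5_model(twoclass_gain5_corpus):
    """Best-of-5 K=2 model for the gain-5 corpus, MAX SEP applied, refitted."""
    corpus, _ = twoclass_gain5_corpus
    model = train_best(corpus, 2, restarts=5, seed=13)
    fits = fit_corpus(model, corpus)
    totals = np.stack([f.weights for f in fits]).sum(axis=0)
    model.components = max_sep(model.components, weights=totals)
    fits = fit_corpus(model, corpus)
    return model, fits
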