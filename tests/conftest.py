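"""Shared fixtures: synthetic cohorts and trained fold models.

The heavier fixtures are session-scoped so that the planted-signal
cross-validation (the most expensive artifact) is trained once and shared
by the evaluation, attribution and acceptance tests.
"""

import numpy as np
import pytest

import stfingerprint as sf

#: Study conditions for the planted-signal cohort: 100 subjects at 4:1
#: imbalance, 30 regions with 5 planted, effect size 2.0, 3 sites.
PLANTED_SYNTH = dict(n_class0=80, n_class1=20, n_regions=30,
                     planted_regions=(0, 1, 2, 3, 4), n_sites=3,
                     effect_size=2.0, seed=1)

#: Training setup used throughout the tests: a deliberately compact
#: architecture that trains in seconds on one CPU while retaining the
#: two-conv-block structure.
MODEL_KW = dict(conv_channels=(32, 16), kernel_sizes=(7, 5), epochs=30,
                seed=2)


@pytest.fixture(scope="session")
def planted_config():
    return sf.SynthConfig(**PLANTED_SYNTH)


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return sf.zscore_normalize(sf.generate_cohort(planted_config))


@pytest.fixture(scope="session")
def planted_cv(planted_cohort):
    """Fivefold CV on the planted-signal cohort (5 trained models)."""
    folds = sf.make_folds(planted_cohort.labels, planted_cohort.sites,
                          k=5, seed=3)
    cfg = sf.StDNNConfig(n_regions=planted_cohort.n_regions, **MODEL_KW)
    return sf.crossvalidate(planted_cohort, cfg, folds)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small trained network on a 10-region cohort, for attribution
    tests that need a genuinely nonlinear fitted model."""
    cfg = sf.SynthConfig(n_class0=40, n_class1=20, n_regions=10,
                         planted_regions=(0, 1, 2), nt_range=(48, 64),
                         n_sites=2, seed=7)
    cohort = sf.zscore_normalize(sf.generate_cohort(cfg))
    model_cfg = sf.StDNNConfig(n_regions=10, conv_channels=(16, 8),
                               epochs=20, seed=8)
    model = sf.train(cohort, np.arange(len(cohort)), model_cfg)
    return model, cohort
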