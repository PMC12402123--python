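import numpy as np
import pytest

import trajsubtype as ts
from trajsubtype.model import GuidedTemporalVAE, ModelConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 synthetic patients with moderate missingness, plus ground truth."""
    cohort, truth = ts.generate_cohort(ts.SimConfig(n_patients=30, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_encoded(tiny_cohort):
    cohort, _ = tiny_cohort
    filtered, _ = ts.apply_inclusion_filters(cohort)
    plan = ts.make_split(filtered.ids(), seed=0)
    stats = ts.fit_normalization(filtered.subset(plan.train_ids))
    return ts.encode(filtered, stats), plan


@pytest.fixture(scope="session")
def untrained_model(tiny_encoded):
    enc, _ = tiny_encoded
    model = GuidedTemporalVAE(enc.layout, ModelConfig(seed=3), enc.stats)
    # non-degenerate Gaussian heads so perturbation tests exercise real paths
    rng = np.random.default_rng(11)
    for head in (model.posterior_head, model.prior_init, model.prior_trans):
        head.layers[-1].W.data[:] = rng.normal(0, 0.05,
                                               head.layers[-1].W.data.shape)
    return model


@pytest.fixture(scope="session")
def small_trained(tiny_encoded):
    """A briefly trained model for smoke-level behavioural tests."""
    enc, plan = tiny_encoded
    cfg = ModelConfig(epochs=5, seed=0)
    model = ts.train(enc.subset(plan.train_ids), cfg)
    return model, enc, plan
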