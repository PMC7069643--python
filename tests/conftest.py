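import numpy as np
import pytest

import ionodiag as io
from ionodiag.pipeline import add_compositions, discretize_yield


def random_compositions(rng, n, d=6):
    """Logistic-normal random compositions as an n×d array of unit-sum rows."""
    z = rng.normal(scale=1.0, size=(n, d))
    raw = np.exp(z)
    return raw / raw.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def signal_survey():
    """Default-condition synthetic survey (signal mode), processed and labelled."""
    cfg = io.GeneratorConfig(seed=11)
    params = io.sample_cultivar_params(cfg)
    df, truth = io.generate_dataset(params, cfg)
    labelled, _ = add_compositions(df)
    labelled, cutoffs = discretize_yield(labelled)
    labelled = labelled.dropna(subset=["yield_class"])
    return labelled, truth, cfg


@pytest.fixture(scope="session")
def knn_model(signal_survey):
    """A tuned kNN model and its cultivar-stratified split."""
    labelled, _, cfg = signal_survey
    train, test = io.split_by_cultivar(labelled, seed=cfg.seed)
    model = io.train_classifier(train, "knn", seed=cfg.seed)
    return model, train, test
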