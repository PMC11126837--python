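import pytest

from odormon import classify, features, quantify, simulate


@pytest.fixture(scope="session")
def campaign():
    """Default-condition training campaign (seed 3): samples, frames."""
    params = simulate.fenceline_params(seed=3)
    samples, frames = simulate.simulate_training_campaign(params, seed=3)
    return params, samples, frames


@pytest.fixture(scope="session")
def training_set(campaign):
    params, samples, frames = campaign
    fvs = [
        features.extract_features(f, sample_id=s.sample_id)
        for s, f in zip(samples, frames)
    ]
    return features.build_training_set(samples, fvs)


@pytest.fixture(scope="session")
def fitted_models(training_set):
    """k-NN classifier plus double-step (A) and global (B) models."""
    clf = classify.KnnClassifier.fit(training_set, 5)
    model_a = quantify.fit_double_step(training_set, clf, seed=0)
    model_b = quantify.fit_global(training_set, seed=0)
    return clf, model_a, model_b
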