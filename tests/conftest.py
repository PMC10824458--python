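"""Shared fixtures: synthetic benchmarks, preprocessed features, fold runs.

The heavy benchmark fixtures are session-scoped so the feature matrices are
computed once and shared across end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sleephmm as sh

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def featurize(benchmark, config):
    """(Recording, StateAnnotation) pairs -> (FeatureMatrix, dense labels)."""
    datasets = []
    for rec, ann in benchmark:
        X = sh.preprocess_recording(rec, config)
        y = ann.to_dense(epoch_s=config.epoch_s, n_epochs=X.n_epochs)
        datasets.append((X, y))
    return datasets


def make_train_fn(config):
    def train_fn(train_sets):
        return sh.train_from_features(
            [X for X, _ in train_sets], [y for _, y in train_sets], config
        )

    return train_fn


def make_predict_fn():
    def predict_fn(model, X):
        return sh.predict_from_features(model, X).posterior.viterbi_path

    return predict_fn


@pytest.fixture(scope="session")
def config():
    return sh.PipelineConfig()


@pytest.fixture(scope="session")
def easy_datasets(config):
    """Six 2-h easy recordings, preprocessed."""
    return featurize(sh.generate_benchmark(6, 2.0, "easy", seed=1234), config)


@pytest.fixture(scope="session")
def hard_datasets(config):
    """Six 1-h hard (noisy, brief-awakening) recordings, preprocessed."""
    return featurize(sh.generate_benchmark(6, 1.0, "hard", seed=4321), config)


@pytest.fixture(scope="session")
def small_easy_datasets(config):
    """Four 1-h easy recordings for the permutation-robustness experiment."""
    return featurize(sh.generate_benchmark(4, 1.0, "easy", seed=99), config)


@pytest.fixture(scope="session")
def easy_holdout_reports(easy_datasets, config):
    return sh.holdout_harness(easy_datasets, make_train_fn(config), make_predict_fn())


@pytest.fixture(scope="session")
def hard_holdout(hard_datasets, config):
    """Per-fold hold-one-out decodes on the hard benchmark, with baselines."""
    train_fn = make_train_fn(config)
    folds = []
    for k in range(len(hard_datasets)):
        train_sets = [d for i, d in enumerate(hard_datasets) if i != k]
        model = train_fn(train_sets)
        X, y = hard_datasets[k]
        result = sh.predict_from_features(model, X)
        Z = sh.project(model.projection, X)
        folds.append(
            {
                "truth": y,
                "hmm": result.posterior.viterbi_path,
                "certainty": result.posterior.certainty(),
                "naive_bayes": sh.naive_bayes_decode(
                    model.emissions, model.transitions.initial, Z
                ),
                "lda": sh.lda_classify(model.projection, X),
                "model": model,
            }
        )
    return folds


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Two 15-min easy recordings for fast I/O and contract tests."""
    return sh.generate_benchmark(2, 0.25, "easy", seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_benchmark, config):
    return sh.train([r for r, _ in tiny_benchmark], [a for _, a in tiny_benchmark], config)
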