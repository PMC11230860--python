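"""Shared fixtures: a reduced synthetic study and models fitted on it.

The reduced study keeps the full statistical structure (three motifs,
active/decoy separation, imbalanced screen) at 15% of the reference sizes
so the suite stays fast; the acceptance tests use the full-size study.
"""

import numpy as np
import pytest

import molscreen as ms


@pytest.fixture(scope="session")
def small_spec() -> ms.SyntheticSpec:
    return ms.SyntheticSpec(seed=7).scaled(0.15)


@pytest.fixture(scope="session")
def small_study(small_spec) -> ms.SyntheticStudy:
    return ms.generate_study(small_spec)


@pytest.fixture(scope="session")
def tiny_model_config() -> ms.ModelConfig:
    # small head/message dims: enough capacity for the motif signal,
    # fast enough to refit several times in the suite
    return ms.ModelConfig(epochs=15, hidden_layers=(128, 64), mp_hidden=32, seed=5)


@pytest.fixture(scope="session")
def fitted_models(small_study, tiny_model_config) -> dict[str, ms.AffinityResults]:
    models = {}
    for target, ds in small_study.training.items():
        train, valid, _ = ms.split_dataset(ds, ms.SplitConfig(seed=3))
        models[target] = ms.AffinityModel(train, valid, tiny_model_config).fit()
    return models


@pytest.fixture(scope="session")
def screen_table(fitted_models, small_study):
    table, rejects = ms.EnsembleScreener(fitted_models).screen(small_study.screen)
    assert not rejects
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240626)
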