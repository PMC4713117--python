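"""Shared fixtures: small synthetic datasets and cached model stores."""

import numpy as np
import pytest

from gaeoc.dataio import Dataset
from gaeoc.folds_models import default_pool, make_cv_folds, train_fold_models
from gaeoc.synthetic import gen_imbalanced_gaussian


@pytest.fixture(scope="session")
def separable_dataset() -> Dataset:
    """Balanced, strongly separated two-class Gaussian table (n = 80)."""
    return gen_imbalanced_gaussian(40, 40, 5, separation=6.0, seed=11)


@pytest.fixture(scope="session")
def imbalanced_dataset() -> Dataset:
    """90 minority vs 360 majority, moderate separation (the 1:4 shape)."""
    return gen_imbalanced_gaussian(90, 360, 6, separation=3.0, seed=7)


@pytest.fixture(scope="session")
def small_store(separable_dataset):
    """Default 20-learner pool trained on 10 folds of the separable table."""
    pool = default_pool()
    folds = make_cv_folds(separable_dataset, 10, seed=5)
    store = train_fold_models(separable_dataset, folds, pool, seed=5,
                              keep_models=False)
    return pool, folds, store, separable_dataset
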