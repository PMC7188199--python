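import numpy as np
import pandas as pd
import pytest

import nldrkit as nk
from nldrkit.registry import PREDICTOR_NAMES, TARGET


@pytest.fixture(scope="session")
def default_cohort() -> nk.Cohort:
    """A study-shaped synthetic cohort (n=128, default generator)."""
    return nk.generate(nk.GeneratorConfig(n=128, seed=1))


@pytest.fixture(scope="session")
def labeled(default_cohort) -> nk.LabeledCohort:
    return nk.dichotomize(default_cohort, 210.0)


@pytest.fixture(scope="session")
def small_cohort() -> nk.Cohort:
    """A 60-donor cohort for cheap fits."""
    return nk.generate(nk.GeneratorConfig(n=60, seed=7))


def make_cohort(x: np.ndarray, time: np.ndarray, columns=None,
                fill_rng_seed: int = 0) -> nk.Cohort:
    """Build a full-registry cohort from an (n, k) feature block.

    The block occupies the named columns; remaining registry predictors are
    filled with independent noise so the frame is schema-complete.
    """
    n, k = np.atleast_2d(x).shape
    columns = list(columns or PREDICTOR_NAMES[:k])
    rng = np.random.default_rng(fill_rng_seed)
    df = pd.DataFrame(np.atleast_2d(x), columns=columns)
    for name in PREDICTOR_NAMES:
        if name not in df.columns:
            df[name] = rng.normal(size=n)
    df[TARGET.name] = np.asarray(time, dtype=float)
    return nk.Cohort(df=df[[TARGET.name, *PREDICTOR_NAMES]].copy())


@pytest.fixture
def two_gaussian_cohort():
    """Two 3-variable Gaussian classes (120 easy / 80 difficult), labeled."""
    rng = np.random.default_rng(42)
    x = np.vstack([
        rng.multivariate_normal([0, 0, 0], np.eye(3), 120),
        rng.multivariate_normal([1.2, 0.5, -0.3], np.eye(3), 80),
    ])
    time = np.r_[np.full(120, 100.0), np.full(80, 300.0)]
    cohort = make_cohort(x, time, columns=["age", "body_weight", "body_height"])
    return nk.dichotomize(cohort, 210.0), x
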