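import numpy as np
import pytest

import ferroflux as ff


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort():
    spec = ff.CohortSpec(n_samples=60, seed=7, confounding=[("age", 0.4), ("bmi", 0.3)])
    return ff.generate_cohort(spec)


@pytest.fixture()
def counts_block(small_cohort):
    spec = ff.BlockSpec(
        name="taxa",
        kind="counts",
        n_features=30,
        planted_effects=[(0, 1.5), (1, -1.5)],
        dispersion=50.0,
    )
    return ff.generate_block(small_cohort, spec)
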