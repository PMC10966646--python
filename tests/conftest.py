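"""Shared fixtures: small synthetic pools and stub surrogates."""

import numpy as np
import pytest

from albench.synthetic import SyntheticScenario, generate_library, scenario_preset


class OracleSurrogate:
    """Perfect surrogate stub: predicts the true potency of every compound.

    Looks queries up by fingerprint bytes, so the pool's fingerprints must be
    unique (asserted by the fixtures that use it). Variance is zero.
    """

    def __init__(self, pool):
        self._truth = {
            row.tobytes(): p for row, p in zip(pool.fingerprints, pool.potency)
        }

    def fit(self, X, y):
        return self

    def predict(self, X):
        mean = np.array([self._truth[row.tobytes()] for row in np.asarray(X, dtype=np.uint8)])
        return mean, np.zeros(len(mean))


@pytest.fixture(scope="session")
def small_pool():
    """A 200-compound congeneric-style pool with unique fingerprints."""
    scenario = SyntheticScenario(
        n_compounds=200,
        n_clusters=5,
        core_bits_per_cluster=30,
        substituent_bits=30,
        fingerprint_length=512,
        cluster_effect_sd=1.0,
        substituent_effect_sd=0.25,
        residual_sd=0.2,
        seed=42,
    )
    pool = generate_library(scenario)
    assert len(np.unique(pool.fingerprints, axis=0)) == len(pool)
    return pool


@pytest.fixture(scope="session")
def congeneric_pool():
    """The default congeneric preset pool (n=2000)."""
    return generate_library(scenario_preset("congeneric"))


@pytest.fixture
def oracle_surrogate_factory(small_pool):
    return lambda: OracleSurrogate(small_pool)
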