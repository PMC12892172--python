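"""Shared fixtures: one synthetic desk-scale world and one full MCMC fit.

The fit fixture is session-scoped so parameter-recovery, diagnostics and
prediction tests share a single (minutes-long) MCMC run.
"""

import numpy as np
import pytest

import occabund as oa

SEED = 1


@pytest.fixture(scope="session")
def desk_dataset():
    cfg = oa.preset("desk_small")
    captures, tubes, registry, truth = oa.simulate(cfg, seed=SEED)
    return captures, tubes, registry, truth


@pytest.fixture(scope="session")
def desk_model(desk_dataset):
    captures, tubes, registry, _ = desk_dataset
    return oa.IntegratedAbundanceModel.from_raw(
        captures, tubes, registry, timescale="short")


@pytest.fixture(scope="session")
def desk_fit(desk_model):
    return desk_model.fit(chains=3, iterations=5000, seed=SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
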