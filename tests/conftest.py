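"""Shared synthetic fixtures; everything is generated at test time."""

import numpy as np
import pytest

from convenc import simulate as sim


@pytest.fixture(scope="session")
def small_schedule():
    return sim.generate_schedule(n_sessions=2, runs_per_session=2, n_tr=120, seed=11)


@pytest.fixture(scope="session")
def small_store(small_schedule):
    return sim.generate_embeddings(
        small_schedule, dim=8, context_lengths=(1, 2, 4), shared_dims=4, seed=11
    )


@pytest.fixture(scope="session")
def small_truth():
    return sim.generate_ground_truth(
        n_voxels=40,
        dim=8,
        shared_dims=4,
        rho=0.7,
        class_mix={"production": 0.25, "comprehension": 0.25, "bimodal": 0.25, "null": 0.25},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bold(small_store, small_truth):
    return sim.simulate_bold(small_store, small_truth, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
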