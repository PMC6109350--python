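"""Shared fixtures: toy generative models and a small enumerable random model."""

import numpy as np
import pytest

from tcrpreimmune import generative_model as gm
from tcrpreimmune import synthetic_data as sd


@pytest.fixture(scope="session")
def model_a():
    return sd.toy_model_a()


@pytest.fixture(scope="session")
def model_b():
    return sd.toy_model_b()


@pytest.fixture(scope="session")
def model_c():
    return sd.toy_model_c()


@pytest.fixture(scope="session")
def model_d():
    return sd.toy_model_d()


SMALL_SPEC = sd.ToyModelSpec(
    n_v=2, n_d=2, n_j=2, v_len=9, d_len=5, j_len=9,
    max_del_v=2, max_del_j=2, max_del_d=1, ins_lengths=(0, 1, 2),
)


@pytest.fixture(scope="session")
def small_model():
    """Random model with ~1.3e5 scenarios: enumerable in a couple of seconds."""
    return sd.make_toy_model(SMALL_SPEC, seed=3)


@pytest.fixture(scope="session")
def small_nt_table(small_model):
    return gm.pgen_nt_table(small_model)


@pytest.fixture(scope="session")
def small_db(small_model, small_nt_table):
    db, truth = sd.make_synthetic_db(
        small_model, n_epitopes=4, tcrs_per_epitope=10, seed=1, nt_table=small_nt_table
    )
    return db, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
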