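"""Shared fixtures: one small simulated cohort and one trained model, reused
across test modules to keep the suite fast."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("repro")

from jointmm import training
from jointmm.model import JointTransformer
from jointmm.pipeline import prepare_cohort
from jointmm.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(n_patients=200, n_periods=10, seed=7))


@pytest.fixture(scope="session")
def prep(small_cohort):
    return prepare_cohort(small_cohort)


@pytest.fixture(scope="session")
def trained_model(prep):
    model = JointTransformer(hidden_dim=16, dropout=0.1, rollout_window=1,
                             random_state=0)
    training.pretrain(model, prep.inputs, epochs=40, seed=0)
    training.finetune_heads(model, prep.inputs, prep.outcomes["pfs"], "pfs",
                            epochs=150, lr=1e-2, seed=0)
    return model


@pytest.fixture()
def tiny_model():
    """Small randomly-initialized encoder for contract/oracle tests."""
    model = JointTransformer(hidden_dim=4, n_layers=2, n_heads=1, tau=2,
                             dropout=0.0, rollout_window=1, nonlinear_head=True,
                             head_hidden=3, t_max=8.0, random_state=5)
    model.build(d_base=2, n_vars=1, d_treat=1, n_periods=5)
    return model


@pytest.fixture()
def tiny_inputs():
    rng = np.random.default_rng(11)
    n, T = 3, 4
    return (rng.normal(size=(n, 2)), rng.normal(size=(n, T, 1)),
            np.ones((n, T, 1)), rng.normal(size=(n, T, 1)))
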