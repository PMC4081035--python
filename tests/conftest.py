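import numpy as np
import pytest

import satlba as s

# Generating truths for the two synthetic subjects used throughout the
# suite (posterior-mean estimates reported for the original monkeys).
SUBJECT_Q = dict(
    t0=0.10, p=0.08, b_acc=0.24, v_t_acc=0.66, v_d_acc=0.40,
    v_t_spd=2.30, v_d_spd=1.41, s_acc=0.10,
)
SUBJECT_S = dict(
    t0=0.09, p=0.12, b_acc=0.42, v_t_acc=1.16, v_d_acc=0.81,
    v_t_spd=2.78, v_d_spd=2.11, s_acc=0.28,
)


@pytest.fixture(scope="session")
def monkey_q():
    return s.SatParameters(**SUBJECT_Q)


@pytest.fixture(scope="session")
def monkey_s():
    return s.SatParameters(**SUBJECT_S)


@pytest.fixture(scope="session")
def q_dataset(monkey_q):
    """Default-scale synthetic dataset at the Q truth (2000/400/2000)."""
    return s.generate_dataset(s.GeneratorConfig(monkey_q, seed=11))


@pytest.fixture(scope="session")
def small_q_trials(monkey_q):
    """A quick 300-trial table for likelihood/sampler unit tests."""
    ds = s.generate_dataset(
        s.GeneratorConfig(monkey_q, n_speed=120, n_neutral=60, n_accuracy=120, seed=7)
    )
    return ds.trials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
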