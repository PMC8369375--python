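import numpy as np
import pytest

from pttbp.pipeline import RunConfig, run_participant
from pttbp.simulate import NoiseModel, compact_schedule, default_law, simulate_session


@pytest.fixture(scope="session")
def zero_noise_run():
    """One noise-free synthetic participant pushed through the full chain."""
    law = default_law()
    session, record = simulate_session(
        law, NoiseModel.zero(), schedule=compact_schedule(20.0), seed=11
    )
    result = run_participant(session, RunConfig())
    return law, session, record, result


@pytest.fixture(scope="session")
def small_session():
    """A short noise-free session (3 tasks) for I/O and alignment tests."""
    law = default_law()
    session, record = simulate_session(
        law,
        NoiseModel.zero(),
        schedule=compact_schedule(15.0, tasks=("sit_baseline", "stand_baseline", "rest")),
        seed=5,
    )
    return session, record


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
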