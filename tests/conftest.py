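import numpy as np
import pytest

from graphreplay import decoding, synthetic_data as sd
from graphreplay.task_graph import build_task_graph


@pytest.fixture(scope="session")
def graph():
    return build_task_graph()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Cheap configuration for unit tests: few sensors, one localizer run."""
    return sd.SimulationConfig(n_participants=2, n_sensors=32,
                               localizer_runs=1, localizer_reps=5, seed=99)


@pytest.fixture(scope="session")
def small_localizer(small_cfg):
    rng = np.random.default_rng(7)
    pats = sd.make_stimulus_patterns(small_cfg.n_sensors, 10, rng)
    order = sd.generate_localizer_sequence(10, small_cfg.localizer_reps, rng)
    return sd.generate_localizer_trials(pats, order, small_cfg, rng), pats


@pytest.fixture(scope="session")
def decoded_clustered(graph):
    """One small clustered-reactivation participant, decoded end to end."""
    rng = np.random.default_rng(21)
    cfg = sd.SimulationConfig(n_participants=1, n_sensors=64,
                              localizer_runs=1, localizer_reps=8,
                              replay_mode="clustered", seed=5)
    _, (part,) = sd.simulate_cohort(cfg, graph)
    dec = decoding.train_final_decoders(part.localizer, rng=rng)
    probs = decoding.apply_decoders(dec, part.retrieval)
    return probs, part
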