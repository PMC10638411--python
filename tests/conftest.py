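import numpy as np
import pytest

from semdem.config import PROFILES
from semdem.dynamics import DynamicsParams
from semdem.netarch import ArchitectureConfig, build_network
from semdem.plasticity import PlasticityRule
from semdem.protocol import TrainingSchedule, generate_word_patterns, train
from semdem import experiment as sde


@pytest.fixture(scope="session")
def default_net():
    """A freshly built default 12-area network (do not mutate: copy first)."""
    return build_network(ArchitectureConfig(), seed=1)


@pytest.fixture()
def net(default_net):
    return default_net.copy()


@pytest.fixture(scope="session")
def mini_trained():
    """A briefly trained network (1 object + 1 action word, 60 trials each):
    enough for perisylvian assemblies to form; used by assay/io tests."""
    netw = build_network(ArchitectureConfig(), seed=2)
    rng = np.random.default_rng(20)
    words = generate_word_patterns(1, 1, 625, 19, rng)
    sched = TrainingSchedule(trials_per_word=60)
    train(netw, words, sched, DynamicsParams(), PlasticityRule(), rng)
    return netw, words


@pytest.fixture(scope="session")
def scaled_result():
    """The full scaled-profile experiment: 5 instances trained on 6 object +
    6 action words for 300 trials each, lesioned (GM and WM at 30/60/90%) and
    assayed.  Shared by the learning-property and lesion-ordering tests."""
    cfg = PROFILES["scaled"]()
    return sde.run_experiment(cfg, seed=11)
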