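import numpy as np
import pytest
from hypothesis import settings

from facedyn import io_preprocess as iop
from facedyn import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gt3():
    """Default rank-3, 18-AU, 100-bin ground truth."""
    return syn.make_ground_truth(3, 18, 100, seed=7)


@pytest.fixture(scope="session")
def small_dataset(gt3):
    """12 trials: 2 subjects x 3 emotions x 2 conditions."""
    return syn.make_dataset(gt3, n_subjects=2, trials_per_cell=1, seed=3)


@pytest.fixture(scope="session")
def stacked_train(gt3):
    """Binned + stacked expression-only dataset (12 trials, 1200 x 18)."""
    trials = syn.make_dataset(gt3, n_subjects=4, trials_per_cell=1, seed=5,
                              conditions=("expression_only",))
    binned = iop.preprocess_trials(trials)
    return iop.stack_trials(binned, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
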