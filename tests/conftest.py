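import numpy as np
import pytest

from cwqsar.attributes import DescriptorConfig
from cwqsar.optimizer import OptimizerConfig, optimize
from cwqsar.simulate import make_dataset, make_splits

#: the dichlorobenzoic-acid worked example used throughout
WORKED_SMILES = "Clc1cc(Cl)ccc1C(O)=O"


@pytest.fixture(scope="session")
def synthetic_noiseless():
    """Default harness dataset without noise, split 0.8/0.2."""
    dataset, planted = make_dataset(n=250, seed=7, noise_frac=0.0)
    assignment = make_splits(dataset, "random", (0.8, 0.2), seed=7)
    parts = dataset.split(assignment)
    return dataset, planted, parts["training"], parts["validation"]


@pytest.fixture(scope="session")
def recovery_runs(synthetic_noiseless):
    """Three N=50 optimizations of the noiseless harness (seeds 1-3)."""
    _, _, training, validation = synthetic_noiseless
    dconf = DescriptorConfig(threshold=1, epochs=50)
    runs = {
        seed: optimize(training, dconf, OptimizerConfig(seed=seed))
        for seed in (1, 2, 3)
    }
    return runs, training, validation


@pytest.fixture(scope="session")
def small_training():
    """A quick 60-molecule training set with 5% noise."""
    dataset, planted = make_dataset(n=75, seed=11, noise_frac=0.05)
    assignment = make_splits(dataset, "random", (0.8, 0.2), seed=11)
    parts = dataset.split(assignment)
    return parts["training"], parts["validation"], planted


def rsquared(observed, predicted) -> float:
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)
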